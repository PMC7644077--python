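"""Phase-based Eulerian video magnification.

Each frame is decomposed on a complex steerable pyramid — an overcomplete
multi-scale, multi-orientation filter bank whose coefficient *phases* shift
approximately linearly under small spatial translations. The local phase of
every band is band-pass filtered in time around the frequency of interest,
multiplied by the amplification factor α, and added back before
reconstruction, so in-band sub-pixel displacements of amplitude a emerge
with amplitude (1+α)·a while amplitude noise is left largely untouched.

The pyramid here is the frequency-domain construction: radial octave bands
with raised-cosine (in log frequency) transitions and cos^(B−1) angular
windows, normalized so that the squared analysis masks tile the frequency
plane exactly — reconstruction of an unmodified decomposition is exact to
floating-point. No spatial downsampling is used; memory is traded for
simplicity and exactness on the small fields of view this tool targets.
Processing is offline over the whole clip (first-order / small-phase
accuracy only).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import ndimage

from .videoio import VideoSequence

__all__ = [
    "MagnificationParams",
    "SteerablePyramid",
    "PyramidDecomposition",
    "build_pyramid",
    "reconstruct",
    "magnify",
]


@dataclass(frozen=True)
class MagnificationParams:
    """User-facing magnification controls.

    ``alpha`` is the amplification factor; the temporal pass band is
    ``center_freq_hz ± half_band_hz``. ``half_band_hz=None`` selects
    ``max(0.1·center_freq, one frequency bin)`` at run time.
    """

    alpha: float
    center_freq_hz: float
    half_band_hz: float | None = None
    levels: int = 4
    orientations: int = 4
    spatial_smooth_sigma: float = 2.0  # 0 disables amplitude-weighted smoothing

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.center_freq_hz <= 0:
            raise ValueError("center_freq_hz must be positive")
        if self.levels < 1 or self.orientations < 1:
            raise ValueError("levels and orientations must be ≥ 1")
        if self.half_band_hz is not None and \
                self.center_freq_hz - self.half_band_hz <= 0:
            raise ValueError("band must lie strictly above 0 Hz")

    def resolve_band(self, frame_rate_hz: float, n_frames: int) -> tuple[float, float]:
        hb = self.half_band_hz
        if hb is None:
            hb = max(0.1 * self.center_freq_hz, frame_rate_hz / n_frames)
        lo = self.center_freq_hz - hb
        hi = self.center_freq_hz + hb
        if lo <= 0 or hi > frame_rate_hz / 2.0:
            raise ValueError(
                f"pass band [{lo:.4g}, {hi:.4g}] Hz outside (0, Nyquist="
                f"{frame_rate_hz / 2.0:.4g}] for frame rate {frame_rate_hz}")
        return lo, hi


def _radial_transition(log_rad: np.ndarray, cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """Power-complementary (hi, lo) masks with a one-octave raised-cosine
    transition ending at ``cutoff`` (log2 of radius/Nyquist)."""
    t = np.clip(log_rad - cutoff, -1.0, 0.0)
    hi = np.cos(np.pi / 2.0 * t)          # 1 above cutoff, 0 below cutoff−1
    lo = np.sin(np.pi / 2.0 * -t)         # 0 above cutoff, 1 below cutoff−1
    return hi, lo


class SteerablePyramid:
    """Reusable frequency-domain filter bank for one image shape.

    ``masks`` holds the real radial×angular analysis windows M_{k,b}; the
    complex band coefficients are ``ifft2(fft2(img) · M · D_b)`` with
    ``D_b`` the doubling indicator of the half-plane aligned with the band's
    orientation (the analytic-signal step that makes phases meaningful).
    Squared masks tile: hi² + lo² + Σ effective(M²) = 1, giving exact
    reconstruction from the real parts of the bands plus the residuals.
    """

    def __init__(self, shape: tuple[int, int], levels: int = 4,
                 orientations: int = 4):
        h, w = shape
        if h < 2 ** levels or w < 2 ** levels:
            feasible = int(np.floor(np.log2(min(h, w))))
            raise ValueError(
                f"image {h}×{w} too small for {levels} pyramid levels; "
                f"maximum feasible depth is {feasible}")
        self.shape = (h, w)
        self.levels = levels
        self.orientations = orientations
        fy = np.fft.fftfreq(h)[:, None]
        fx = np.fft.fftfreq(w)[None, :]
        rad = np.hypot(fy, fx)
        rad[0, 0] = 1.0  # placeholder; the DC bin is pinned below
        log_rad = np.log2(rad / 0.5)
        log_rad[0, 0] = -(levels + 2.0)  # DC always lands in the lowpass
        angle = np.arctan2(fy, fx)

        order = orientations - 1
        # Σ_b cos^{2·order}(θ−θ_b) over 2B lobes is the constant below;
        # β makes the symmetrized squared angular windows sum to 1.
        const = 2.0 * orientations * comb(2 * order, order) / (4.0 ** order)
        beta = np.sqrt(2.0 / const)

        hi0, lo = _radial_transition(log_rad, 0.0)
        self.hi_mask = hi0
        self.band_masks: list[list[np.ndarray]] = []
        self.half_plane: list[np.ndarray] = []
        for k in range(levels):
            hi_k, lo_k = _radial_transition(log_rad, -(k + 1))
            ring = lo * hi_k
            level_masks = []
            for b in range(orientations):
                theta_b = np.pi * b / orientations
                ca = np.cos(angle - theta_b)
                level_masks.append(beta * ring * ca ** order)
            self.band_masks.append(level_masks)
            lo = lo * lo_k
        self.lo_mask = lo
        for b in range(orientations):
            theta_b = np.pi * b / orientations
            ca = np.cos(angle - theta_b)
            # weight 1 on the boundary so D(ω)+D(−ω)=2 everywhere
            on_edge = np.abs(ca) <= 1e-9
            self.half_plane.append(2.0 * (ca > 1e-9) + 1.0 * on_edge)

    def decompose(self, image: np.ndarray) -> "PyramidDecomposition":
        f = np.fft.fft2(image)
        hi = np.fft.ifft2(f * self.hi_mask).real
        lo = np.fft.ifft2(f * self.lo_mask).real
        bands = [[np.fft.ifft2(f * m * d) for m, d in
                  zip(level, self.half_plane)] for level in self.band_masks]
        return PyramidDecomposition(self, bands, lo, hi)

    def band_coefficients(self, image: np.ndarray, level: int,
                          orientation: int) -> np.ndarray:
        """Complex coefficients of a single band (memory-light path)."""
        f = np.fft.fft2(image)
        return np.fft.ifft2(f * self.band_masks[level][orientation]
                            * self.half_plane[orientation])

    def reconstruct(self, decomp: "PyramidDecomposition") -> np.ndarray:
        f = np.fft.fft2(decomp.highpass) * self.hi_mask + \
            np.fft.fft2(decomp.lowpass) * self.lo_mask
        for level, masks in zip(decomp.bands, self.band_masks):
            for band, m in zip(level, masks):
                f = f + np.fft.fft2(band) * m
        return np.fft.ifft2(f).real


@dataclass
class PyramidDecomposition:
    """Complex band coefficients plus low/high-pass residuals of one frame."""

    pyramid: SteerablePyramid
    bands: list[list[np.ndarray]]  # [level][orientation] complex H×W
    lowpass: np.ndarray
    highpass: np.ndarray

    @property
    def amplitudes(self) -> list[list[np.ndarray]]:
        return [[np.abs(b) for b in level] for level in self.bands]

    @property
    def phases(self) -> list[list[np.ndarray]]:
        return [[np.angle(b) for b in level] for level in self.bands]


def build_pyramid(frame: np.ndarray, levels: int = 4,
                  orientations: int = 4) -> PyramidDecomposition:
    """Decompose a single-channel image; see :class:`SteerablePyramid`."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("build_pyramid expects a single-channel H×W image")
    return SteerablePyramid(frame.shape, levels, orientations).decompose(frame)


def reconstruct(decomp: PyramidDecomposition) -> np.ndarray:
    return decomp.pyramid.reconstruct(decomp)


def _wrap_phase(p: np.ndarray) -> np.ndarray:
    """Wrap to (−π, π]."""
    return np.angle(np.exp(1j * p))


def _temporal_bandpass(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    """Zero-phase FFT band-pass along axis 0: flat over [lo, hi] with
    raised-cosine edges half a band wide. For offline whole-clip processing
    this avoids the startup transients a recursive filter would ring into
    short clips; out-of-band frequencies are rejected exactly."""
    n = x.shape[0]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    roll = 0.5 * (hi - lo)
    mask = np.zeros_like(freqs)
    inside = (freqs >= lo) & (freqs <= hi)
    mask[inside] = 1.0
    lo_edge = (freqs >= lo - roll) & (freqs < lo)
    mask[lo_edge] = 0.5 * (1 + np.cos(np.pi * (lo - freqs[lo_edge]) / roll))
    hi_edge = (freqs > hi) & (freqs <= hi + roll)
    mask[hi_edge] = 0.5 * (1 + np.cos(np.pi * (freqs[hi_edge] - hi) / roll))
    mask[freqs == 0] = 0.0
    shape = (len(freqs),) + (1,) * (x.ndim - 1)
    return np.fft.irfft(np.fft.rfft(x, axis=0) * mask.reshape(shape),
                        n=n, axis=0)


def magnify(video: VideoSequence, params: MagnificationParams) -> VideoSequence:
    """Amplify sub-pixel periodic motion near ``params.center_freq_hz``.

    Local band phases are temporally unwrapped (frame-to-frame differences
    wrapped to (−π, π] and cumulatively summed), band-pass filtered,
    optionally smoothed spatially with amplitude-squared weights (σ =
    ``spatial_smooth_sigma``), scaled by α and added back. Channels are
    processed independently; output intensities are clipped to [0, 1].
    With α = 0 the output equals the input up to reconstruction error.
    """
    lo, hi = params.resolve_band(video.frame_rate_hz, video.n_frames)
    t, h, w, c = video.shape
    pyr = SteerablePyramid((h, w), params.levels, params.orientations)
    out = np.empty_like(video.frames)
    for ch in range(c):
        frames = video.frames[:, :, :, ch]
        ffts = np.fft.fft2(frames, axes=(1, 2))
        recon_f = ffts * (pyr.hi_mask ** 2 + pyr.lo_mask ** 2)
        for level in range(params.levels):
            for b in range(params.orientations):
                m = pyr.band_masks[level][b] * pyr.half_plane[b]
                coeffs = np.fft.ifft2(ffts * m, axes=(1, 2)).astype(np.complex64)
                if params.alpha > 0:
                    phase = np.angle(coeffs)
                    dphase = _wrap_phase(np.diff(phase, axis=0))
                    unwrapped = np.concatenate(
                        [phase[:1], phase[:1] + np.cumsum(dphase, axis=0)])
                    filtered = _temporal_bandpass(
                        unwrapped, video.frame_rate_hz, lo, hi)
                    if params.spatial_smooth_sigma > 0:
                        w2 = np.abs(coeffs) ** 2
                        sig = (0, params.spatial_smooth_sigma,
                               params.spatial_smooth_sigma)
                        num = ndimage.gaussian_filter(filtered * w2, sig)
                        den = ndimage.gaussian_filter(w2, sig) + 1e-12
                        filtered = num / den
                    coeffs = coeffs * np.exp(
                        1j * params.alpha * filtered).astype(np.complex64)
                recon_f += np.fft.fft2(coeffs, axes=(1, 2)) * \
                    pyr.band_masks[level][b]
        out[:, :, :, ch] = np.fft.ifft2(recon_f, axes=(1, 2)).real
    return video.with_frames(np.clip(out, 0.0, 1.0), video.channel_names)
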