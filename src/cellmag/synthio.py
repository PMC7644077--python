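"""Synthetic fixture videos with known ground truth.

Every downstream stage is tested against these generators rather than real
microscope data: a ring whose radius oscillates harmonically, a band-limited
texture translating sinusoidally with sub-pixel amplitude (the analog of a
cyclically stretched fluorescent gel imaged at 2.77 µm/pixel, where a 1 µm
stretch is 0.36 px), a constant-velocity drifting field for stabilization
tests, and a static noisy field as the noise control. Sub-pixel translation
uses Fourier-shift interpolation, which is exact for band-limited images, so
the injected displacement is unambiguous ground truth.

Identical spec + seed always yields a bit-identical video.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .videoio import VideoSequence

__all__ = [
    "FixtureSpec",
    "make_ring",
    "make_oscillating_texture",
    "make_static",
    "make_drift",
    "make_fixture",
    "band_limited_texture",
    "fourier_shift_image",
]

Kind = Literal["ring", "oscillating_texture", "drift", "static"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture.

    ``direction_deg`` is measured from the image vertical (Y) axis, matching
    the four-direction convention of the motion module: 0° moves along +y,
    90° along +x.
    """

    kind: Kind
    size: tuple[int, int] = (128, 128)
    n_frames: int = 480
    frame_rate_hz: float = 24.0
    motion_freq_hz: float = 1.0
    amplitude_px: float = 0.36
    direction_deg: float = 90.0
    noise_sigma: float = 0.01
    seed: int = 0
    ring_radius_px: float | None = None
    ring_width_px: float = 2.0
    drift_px_per_frame: float = 0.5
    texture_cutoff: float = 0.2  # cycles/px low-pass cutoff of the texture
    allow_alias: bool = False
    poisson_noise: bool = False

    def __post_init__(self) -> None:
        h, w = self.size
        if h < 8 or w < 8 or self.n_frames < 2:
            raise ValueError("fixture must be at least 8×8×2")
        if self.amplitude_px < 0:
            raise ValueError("amplitude_px must be nonnegative")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.kind in ("ring", "oscillating_texture"):
            nyq = self.frame_rate_hz / 2.0
            if self.motion_freq_hz >= nyq and not self.allow_alias:
                raise ValueError(
                    f"motion_freq_hz {self.motion_freq_hz} ≥ Nyquist {nyq}; "
                    "set allow_alias=True to deliberately test aliasing")
            if self.motion_freq_hz >= nyq and self.allow_alias:
                fs = self.frame_rate_hz
                f_alias = abs(self.motion_freq_hz - fs * round(self.motion_freq_hz / fs))
                warnings.warn(
                    f"motion at {self.motion_freq_hz} Hz exceeds the Nyquist "
                    f"frequency {nyq} Hz and will alias to {f_alias:.6g} Hz",
                    UserWarning, stacklevel=2)


def band_limited_texture(shape: tuple[int, int], rng: np.random.Generator,
                         cutoff: float = 0.2,
                         lo: float = 0.2, hi: float = 0.8) -> np.ndarray:
    """Random texture whose spectrum is confined below ``cutoff`` cycles/px,
    rescaled to the [lo, hi] intensity range. Band limitation makes Fourier
    shifting alias-free."""
    h, w = shape
    white = rng.standard_normal((h, w))
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    keep = np.hypot(fy, fx) <= cutoff
    tex = np.fft.ifft2(np.fft.fft2(white) * keep).real
    tmin, tmax = tex.min(), tex.max()
    if tmax - tmin < 1e-12:
        return np.full(shape, (lo + hi) / 2.0)
    return lo + (hi - lo) * (tex - tmin) / (tmax - tmin)


def fourier_shift_image(image: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Translate by (dy, dx) pixels with spectral interpolation (periodic
    boundary). Exact for band-limited images; a shift of exactly 1.0 px
    equals an integer roll."""
    shifted = ndimage.fourier_shift(np.fft.fft2(image), (dy, dx))
    return np.fft.ifft2(shifted).real


def _apply_noise(frames: np.ndarray, spec: FixtureSpec,
                 rng: np.random.Generator) -> np.ndarray:
    if spec.poisson_noise:
        # shot noise: treat intensity as expected photon count / 1000
        photons = rng.poisson(np.clip(frames, 0, 1) * 1000.0) / 1000.0
        frames = photons
    if spec.noise_sigma > 0:
        frames = frames + rng.normal(0.0, spec.noise_sigma, frames.shape)
    return np.clip(frames, 0.0, 1.0)


def _displacement_series(spec: FixtureSpec) -> np.ndarray:
    t = np.arange(spec.n_frames) / spec.frame_rate_hz
    return spec.amplitude_px * np.sin(2.0 * np.pi * spec.motion_freq_hz * t)


def _as_video(frames: np.ndarray, spec: FixtureSpec) -> VideoSequence:
    return VideoSequence(frames[..., None], spec.frame_rate_hz)


def make_ring(spec: FixtureSpec) -> tuple[VideoSequence, np.ndarray]:
    """Bright ring on dark background, radius r(t) = r0 + a·sin(2π f t).

    Returns the video and the ground-truth radius series. The ring profile
    is a Gaussian of the radial distance (anti-aliased by construction).
    """
    if spec.kind != "ring":
        raise ValueError(f"spec.kind must be 'ring', got {spec.kind!r}")
    h, w = spec.size
    r0 = spec.ring_radius_px if spec.ring_radius_px is not None else min(h, w) / 4.0
    radii = r0 + _displacement_series(spec)
    if radii.max() + 3 * spec.ring_width_px >= min(h, w) / 2.0:
        raise ValueError(
            f"ring (max radius {radii.max():.1f} px + width) leaves the "
            f"{h}×{w} frame at maximum extension")
    if radii.min() <= 0:
        raise ValueError("ring radius collapses below zero at minimum")
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(yy - (h - 1) / 2.0, xx - (w - 1) / 2.0)
    rng = np.random.default_rng(spec.seed)
    frames = np.stack([
        0.9 * np.exp(-((dist - r) ** 2) / (2.0 * spec.ring_width_px ** 2))
        for r in radii
    ])
    return _as_video(_apply_noise(frames, spec, rng), spec), radii


def make_oscillating_texture(spec: FixtureSpec) -> tuple[VideoSequence, np.ndarray]:
    """Band-limited texture translating as d(t) = a·sin(2π f t) along
    ``direction_deg`` (from the vertical axis). Returns the video and the
    ground-truth signed displacement series in pixels."""
    if spec.kind != "oscillating_texture":
        raise ValueError(f"spec.kind must be 'oscillating_texture', got {spec.kind!r}")
    rng = np.random.default_rng(spec.seed)
    tex = band_limited_texture(spec.size, rng, spec.texture_cutoff)
    disp = _displacement_series(spec)
    theta = np.deg2rad(spec.direction_deg)
    uy, ux = np.cos(theta), np.sin(theta)  # 0° = +y, 90° = +x
    frames = np.stack([fourier_shift_image(tex, d * uy, d * ux) for d in disp])
    return _as_video(_apply_noise(frames, spec, rng), spec), disp


def make_static(spec: FixtureSpec) -> VideoSequence:
    """Static texture plus per-frame iid noise: the noise-floor control."""
    if spec.kind != "static":
        raise ValueError(f"spec.kind must be 'static', got {spec.kind!r}")
    rng = np.random.default_rng(spec.seed)
    tex = band_limited_texture(spec.size, rng, spec.texture_cutoff)
    frames = np.broadcast_to(tex, (spec.n_frames, *spec.size)).copy()
    return _as_video(_apply_noise(frames, spec, rng), spec)


def make_drift(spec: FixtureSpec) -> tuple[VideoSequence, np.ndarray]:
    """Texture drifting at constant velocity along ``direction_deg``.

    Returns the video and the per-frame cumulative ground-truth displacement
    (pixels); frame t is the texture shifted by ``drift_px_per_frame * t``."""
    if spec.kind != "drift":
        raise ValueError(f"spec.kind must be 'drift', got {spec.kind!r}")
    rng = np.random.default_rng(spec.seed)
    tex = band_limited_texture(spec.size, rng, spec.texture_cutoff)
    disp = spec.drift_px_per_frame * np.arange(spec.n_frames, dtype=float)
    theta = np.deg2rad(spec.direction_deg)
    uy, ux = np.cos(theta), np.sin(theta)
    frames = np.stack([fourier_shift_image(tex, d * uy, d * ux) for d in disp])
    return _as_video(_apply_noise(frames, spec, rng), spec), disp


def make_fixture(spec: FixtureSpec):
    """Dispatch on ``spec.kind``; returns what the specific maker returns."""
    maker = {
        "ring": make_ring,
        "oscillating_texture": make_oscillating_texture,
        "static": make_static,
        "drift": make_drift,
    }[spec.kind]
    return maker(spec)
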