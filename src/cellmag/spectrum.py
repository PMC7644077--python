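"""Motion power-spectrum estimation over edge pixels.

Each edge pixel's intensity trace is treated as one realization of a random
process. Per pixel the biased sample autocorrelation

    r[τ] = (1/N) Σ_t x̃[t]·x̃[t+τ],   τ = 0..L−1

(with the temporal mean removed, x̃ = x − x̄) is transformed by a length-L
DFT, and the resulting periodograms are averaged over the M edge pixels —
the Blackman–Tukey estimator with a rectangular lag window, whose variance
shrinks as M grows because distinct pixel traces are close to uncorrelated.
An optional Bartlett lag taper (classical Blackman–Tukey practice) is off by
default. The dominant oscillation frequency is the argmax of the averaged
spectrum excluding the DC bin; its prominence is reported as the percentage
by which the dominant peak exceeds the mean non-DC power, the statistic that
separates live-cell from fixed-cell (noise-only) spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .edges import EdgeMask
from .videoio import VideoSequence

__all__ = [
    "PixelSeries",
    "PowerSpectrum",
    "autocorrelation",
    "estimate_spectrum",
    "dominant_peak_prominence",
    "aliased_frequency",
]


@dataclass(frozen=True)
class PixelSeries:
    """Intensity trace of a single edge pixel."""

    series: np.ndarray
    pixel: tuple[int, int] = (0, 0)  # (y, x)
    channel: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "series",
                           np.asarray(self.series, dtype=np.float64).ravel())


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided averaged motion power spectrum.

    ``freqs_hz[k] = k·frame_rate/L`` for k = 0..⌊L/2⌋; ``power`` is clipped
    to be nonnegative (rectangular lag truncation can produce small negative
    estimates). ``dominant_freq_hz`` excludes the DC bin.
    """

    freqs_hz: np.ndarray
    power: np.ndarray
    L: int
    M: int
    frame_rate_hz: float

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs_hz, dtype=float)
        power = np.asarray(self.power, dtype=float)
        if freqs.shape != power.shape:
            raise ValueError("freqs_hz and power must have the same length")
        if freqs[0] != 0.0:
            raise ValueError("spectrum must start at DC")
        object.__setattr__(self, "freqs_hz", freqs)
        object.__setattr__(self, "power", np.clip(power, 0.0, None))

    @property
    def bin_width_hz(self) -> float:
        return self.frame_rate_hz / self.L

    @property
    def dominant_index(self) -> int:
        if len(self.power) < 2:
            raise ValueError("spectrum has no non-DC bins")
        return 1 + int(np.argmax(self.power[1:]))

    @property
    def dominant_freq_hz(self) -> float:
        """Frequency of the global maximum, DC excluded."""
        return float(self.freqs_hz[self.dominant_index])

    @property
    def dominant_period_s(self) -> float:
        """Oscillation period 1/f of the dominant peak, in seconds."""
        return 1.0 / self.dominant_freq_hz

    @property
    def dominant_prominence_pct(self) -> float:
        return dominant_peak_prominence(self)

    def has_dominant_peak(self, factor: float = 3.0) -> bool:
        """True if some non-DC bin exceeds ``factor`` times the mean non-DC
        power — the operational reading of 'presents a dominant frequency'."""
        non_dc = self.power[1:]
        mean = non_dc.mean()
        if mean <= 0:
            return False
        return bool(non_dc.max() > factor * mean)


def autocorrelation(series: PixelSeries | np.ndarray, L: int) -> np.ndarray:
    """Biased sample autocorrelation of one pixel trace at lags 0..L−1.

    The temporal mean is removed first, so ``r[0]`` is the biased sample
    variance and a constant series gives zeros at every lag.
    """
    x = series.series if isinstance(series, PixelSeries) else \
        np.asarray(series, dtype=np.float64).ravel()
    n = x.size
    if not (1 <= L <= n):
        raise ValueError(f"lag length L={L} must be in [1, N={n}]")
    return _autocorrelation_block(x[None, :], L)[0]


def _autocorrelation_block(x: np.ndarray, L: int) -> np.ndarray:
    """Biased mean-removed autocorrelation of each row of an (M, N) array,
    lags 0..L−1, via zero-padded FFT (O(M N log N))."""
    m, n = x.shape
    xt = x - x.mean(axis=1, keepdims=True)
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    spec = np.fft.rfft(xt, n=nfft, axis=1)
    acf_full = np.fft.irfft(spec * np.conj(spec), n=nfft, axis=1)[:, :n]
    return acf_full[:, :L] / n


def estimate_spectrum(video: VideoSequence, edge_mask: EdgeMask,
                      L: int | None = None, channel: int = 0,
                      window: tuple[int, int] | None = None,
                      taper: str = "none") -> PowerSpectrum:
    """Averaged edge-pixel power spectrum of one channel.

    Parameters
    ----------
    L
        Lag/subseries length; defaults to the (windowed) frame count N.
        Shorter L trades frequency resolution for robustness when the cell
        changes its motion frequency during the video.
    channel
        Channel analyzed; channels are analyzed independently.
    window
        Frame sub-range ``[t0, t1)`` to analyze; whole video if None.
    taper
        ``"none"`` (rectangular truncation, default) or ``"bartlett"``.
    """
    if taper not in ("none", "bartlett"):
        raise ValueError(f"unknown taper {taper!r}")
    t0, t1 = window if window is not None else (0, video.n_frames)
    frames = video.frames[t0:t1, :, :, channel]
    n = frames.shape[0]
    mask = edge_mask.mask
    m = int(mask.sum())
    if m < 1:
        raise ValueError("no edge pixels; lower gth")
    if L is None:
        L = n
    if not (1 <= L <= n):
        raise ValueError(f"lag length L={L} must be in [1, N={n}]")
    series = np.ascontiguousarray(frames[:, mask].T)  # (M, N)
    # averaging the per-pixel periodograms commutes with the DFT of the
    # autocorrelation, so average in the FFT domain and invert once:
    # mean_j r_j = irfft(mean_j |X_j|²)/N, identical to the per-pixel path
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    xt = series - series.mean(axis=1, keepdims=True)
    power_fft = np.abs(np.fft.rfft(xt, n=nfft, axis=1)) ** 2
    acf = np.fft.irfft(power_fft.mean(axis=0), n=nfft)[:L] / n
    if taper == "bartlett":
        acf = acf * (1.0 - np.arange(L) / L)
    # length-L DFT of the one-sided lag sequence; real part
    spec = np.fft.fft(acf, n=L).real
    k = np.arange(L // 2 + 1)
    freqs = k * video.frame_rate_hz / L
    return PowerSpectrum(freqs_hz=freqs, power=spec[: L // 2 + 1],
                         L=L, M=m, frame_rate_hz=video.frame_rate_hz)


def dominant_peak_prominence(spec: PowerSpectrum) -> float:
    """Dominant-peak height as a percentage above the mean non-DC power:
    ``100·(P_dom − P̄)/P̄``. Flat equal-power spectra give 0."""
    non_dc = spec.power[1:]
    if non_dc.size < 3:
        raise ValueError("need at least 3 non-DC bins")
    mean = non_dc.mean()
    if mean <= 0:
        raise ValueError("degenerate flat spectrum (zero mean power)")
    return float(100.0 * (non_dc.max() - mean) / mean)


def aliased_frequency(f0: float, frame_rate_hz: float) -> float:
    """Apparent frequency of a motion at ``f0`` sampled at ``frame_rate_hz``.

    Motions above the Nyquist frequency fold back: the reported frequency is
    ``|f0 − frame_rate·round(f0/frame_rate)|``. A warning is emitted when
    folding actually occurs, since an under-sampled video silently
    misrepresents fast motion as slow.
    """
    fa = abs(f0 - frame_rate_hz * round(f0 / frame_rate_hz))
    if f0 > frame_rate_hz / 2.0:
        warnings.warn(
            f"motion frequency {f0} Hz exceeds Nyquist "
            f"({frame_rate_hz / 2.0} Hz); it aliases to {fa:.6g} Hz",
            UserWarning, stacklevel=2)
    return fa
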