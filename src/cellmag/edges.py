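"""Edge-pixel selection on the temporal-mean image.

Cells perform their periodic motion mostly at their boundary, so spectral
analysis is restricted to 'edge pixels': pixels of the time-averaged image
whose spatial gradient magnitude exceeds a threshold ``gth`` (expressed on
normalized [0,1] intensities, hence bit-depth independent). For gradient
operators (Sobel/Prewitt/Roberts) the mask is a plain magnitude threshold;
Canny, Laplacian-of-Gaussian and zero-cross embed their own thresholding and
return their native binary maps, with ``gth`` passed through as the
operator's threshold parameter. Multi-channel masks are intersected: a pixel
is an edge pixel only if the condition holds in every analyzed channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature, filters

from .videoio import VideoSequence

__all__ = ["EdgeMask", "temporal_mean", "detect_edges", "EDGE_METHODS"]

EDGE_METHODS = ("sobel", "prewitt", "roberts", "log", "zerocross", "canny")


@dataclass(frozen=True)
class EdgeMask:
    """Boolean edge mask plus the temporal-mean image it came from."""

    mask: np.ndarray          # H×W bool
    mean_image: np.ndarray    # H×W×C float
    gth: float
    method: str
    window: tuple[int, int]   # [t_start, t_end) frames averaged

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def n_edge_pixels(self) -> int:
        """M, the number of edge pixels averaged in the spectrum estimator."""
        return int(self.mask.sum())

    @property
    def coordinates(self) -> np.ndarray:
        """(M, 2) array of (y, x) edge-pixel coordinates."""
        return np.argwhere(self.mask)


def temporal_mean(video: VideoSequence,
                  window: tuple[int, int] | None = None) -> np.ndarray:
    """Pixelwise mean over the frame window ``[t0, t1)``, per channel.

    The window defaults to the whole video."""
    t = video.n_frames
    t0, t1 = window if window is not None else (0, t)
    if not (0 <= t0 < t1 <= t):
        raise ValueError(f"empty or out-of-range window ({t0}, {t1}) for T={t}")
    return video.frames[t0:t1].mean(axis=0)


def _gradient_magnitude(image: np.ndarray, method: str) -> np.ndarray:
    if method == "sobel":
        return filters.sobel(image)
    if method == "prewitt":
        return filters.prewitt(image)
    if method == "roberts":
        return filters.roberts(image)
    raise ValueError(f"{method} is not a gradient-magnitude operator")


def _binary_edges(image: np.ndarray, method: str, gth: float,
                  sigma: float) -> np.ndarray:
    if method == "canny":
        # single-threshold convention: hysteresis (low, high) = (0.4·gth, gth)
        return feature.canny(image, sigma=sigma,
                             low_threshold=0.4 * gth, high_threshold=gth)
    if method in ("log", "zerocross"):
        # zero crossings of a (Laplacian-of-)Gaussian response whose local
        # slope exceeds gth; 'zerocross' uses a lighter smoothing
        s = sigma if method == "log" else max(sigma / 2.0, 0.5)
        resp = ndimage.gaussian_laplace(image, sigma=s)
        sign = resp > 0
        crossing = np.zeros_like(sign)
        crossing[:-1, :] |= sign[:-1, :] != sign[1:, :]
        crossing[:, :-1] |= sign[:, :-1] != sign[:, 1:]
        slope = np.maximum(
            np.abs(np.diff(resp, axis=0, append=resp[-1:, :])),
            np.abs(np.diff(resp, axis=1, append=resp[:, -1:])))
        return crossing & (slope > gth)
    raise ValueError(f"unknown binary edge method {method!r}")


def detect_edges(video: VideoSequence, gth: float = 0.1,
                 method: str = "sobel",
                 window: tuple[int, int] | None = None,
                 sigma: float = 2.0) -> EdgeMask:
    """Select edge pixels of the temporal-mean image.

    Parameters
    ----------
    gth
        Gradient threshold on normalized intensities (magnitude operators)
        or the operator's own threshold (canny/log/zerocross).
    method
        One of ``sobel`` (default), ``prewitt``, ``roberts``, ``log``,
        ``zerocross``, ``canny``.
    window
        Frame range ``[t0, t1)`` for the temporal mean; whole video if None.
    sigma
        Gaussian scale for canny / log.
    """
    method = method.lower()
    if method not in EDGE_METHODS:
        raise ValueError(f"unknown edge method {method!r}; "
                         f"choose from {EDGE_METHODS}")
    if gth < 0:
        raise ValueError("gth must be nonnegative")
    mean_img = temporal_mean(video, window)
    t = video.n_frames
    win = window if window is not None else (0, t)
    masks = []
    for c in range(mean_img.shape[-1]):
        chan = mean_img[..., c]
        if method in ("sobel", "prewitt", "roberts"):
            masks.append(_gradient_magnitude(chan, method) > gth)
        else:
            masks.append(_binary_edges(chan, method, gth, sigma))
    mask = np.logical_and.reduce(masks)
    return EdgeMask(mask=mask, mean_image=mean_img, gth=float(gth),
                    method=method, window=tuple(win))
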