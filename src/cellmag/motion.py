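"""Motion localization, direction assignment and kymograph phase labels.

Instead of a dense optical-flow field, motion is located on a sparse grid of
one-pixel-wide line segments of odd length l. A segment "contains motion"
when the summed absolute frame-to-frame intensity differences over its
pixels exceed a threshold MTH (chosen empirically, or automatically as a
percentile of a static control region). For each triggered segment, four
probe lines 45° apart — angles measured from the image vertical (Y) axis —
are centered on the segment's geometric center; the gray-level
center of mass along each probe is tracked over time and the direction with
the largest rms center-of-mass excursion is assigned as the direction of
movement. Finally, the center-of-mass track along the chosen probe can be
phase-annotated on a kymograph: the sign of the temporal derivative of a
locally fitted 5th-degree polynomial labels each frame as expansion or
contraction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import draw

from .videoio import VideoSequence

__all__ = [
    "MotionGrid",
    "GridSegment",
    "MotionDirector",
    "PhasedKymograph",
    "build_grid",
    "detect_moving_segments",
    "segment_motion_sum",
    "assign_direction",
    "probe_line_pixels",
    "center_of_mass_track",
    "phase_annotate",
    "render_directors",
    "auto_mth",
    "DIRECTIONS_DEG",
]

logger = logging.getLogger(__name__)

#: the four assignable directions, degrees from the image vertical (Y) axis
DIRECTIONS_DEG = (0.0, 45.0, 90.0, 135.0)


@dataclass(frozen=True)
class GridSegment:
    """One-pixel-wide lattice segment with its pixel set and center."""

    pixels: tuple[tuple[int, int], ...]  # (y, x) pairs
    center: tuple[int, int]              # (y, x) geometric (mid-length) pixel
    orientation: str                     # "h" or "v"


@dataclass(frozen=True)
class MotionGrid:
    """All lattice segments of length parameter l inside an H×W frame.

    Horizontal segments live on rows y = l·n with x strictly between l·m and
    l·(m+1); vertical segments on columns x = l·m with y strictly between
    l·n and l·(n+1). The strict inequalities leave the lattice corner pixels
    (x = l·m and y = l·n simultaneously) unassigned, so each segment holds
    l−1 interior pixels; the geometric center is the mid-length pixel.
    """

    l: int
    shape: tuple[int, int]
    segments: tuple[GridSegment, ...] = field(default=())
    mth: float | None = None


def build_grid(shape: tuple[int, int], l: int) -> MotionGrid:
    """Enumerate the lattice segments fully inside an H×W frame."""
    h, w = shape
    if l % 2 == 0:
        raise ValueError(f"segment length l must be odd, got {l}")
    if not (3 <= l <= min(h, w)):
        raise ValueError(f"l={l} must be in [3, min(H, W)={min(h, w)}]")
    segments: list[GridSegment] = []
    half = l // 2
    # horizontal: y = l·n, l·m < x < l·(m+1)
    for n in range(0, (h - 1) // l + 1):
        y = l * n
        for m in range(0, (w - 1) // l + 1):
            xs = range(l * m + 1, l * (m + 1))
            if xs and xs[-1] < w:
                pixels = tuple((y, x) for x in xs)
                segments.append(GridSegment(pixels, (y, l * m + half), "h"))
    # vertical: x = l·m, l·n < y < l·(n+1)
    for m in range(0, (w - 1) // l + 1):
        x = l * m
        for n in range(0, (h - 1) // l + 1):
            ys = range(l * n + 1, l * (n + 1))
            if ys and ys[-1] < h:
                pixels = tuple((y, x) for y in ys)
                segments.append(GridSegment(pixels, (l * n + half, x), "v"))
    return MotionGrid(l=l, shape=(h, w), segments=tuple(segments))


def segment_motion_sum(video: VideoSequence, segment: GridSegment,
                       channel: int = 0) -> float:
    """Σ over frame pairs and segment pixels of |I[t] − I[t+1]|."""
    ys = [p[0] for p in segment.pixels]
    xs = [p[1] for p in segment.pixels]
    series = video.frames[:, ys, xs, channel]
    return float(np.abs(np.diff(series, axis=0)).sum())


def detect_moving_segments(video: VideoSequence, grid: MotionGrid,
                           mth: float, channel: int = 0
                           ) -> list[tuple[GridSegment, float]]:
    """Segments whose motion statistic strictly exceeds ``mth``.

    Intended to run on the magnified video; accepts any single channel."""
    if mth < 0:
        raise ValueError("mth must be nonnegative")
    diffs = np.abs(np.diff(video.frames[:, :, :, channel], axis=0)).sum(axis=0)
    hits = []
    for seg in grid.segments:
        ys = [p[0] for p in seg.pixels]
        xs = [p[1] for p in seg.pixels]
        s = float(diffs[ys, xs].sum())
        if s > mth:
            hits.append((seg, s))
    return hits


def auto_mth(video: VideoSequence, grid: MotionGrid, channel: int = 0,
             percentile: float = 95.0) -> float:
    """Reproducible MTH default: the given percentile of the motion
    statistic over all segments of a (static control) video."""
    diffs = np.abs(np.diff(video.frames[:, :, :, channel], axis=0)).sum(axis=0)
    sums = [float(diffs[[p[0] for p in s.pixels],
                        [p[1] for p in s.pixels]].sum())
            for s in grid.segments]
    return float(np.percentile(sums, percentile))


def probe_line_pixels(center: tuple[int, int], l: int,
                      theta_deg: float) -> np.ndarray:
    """(l, 2) array of (y, x) pixels of the probe line through ``center``
    along ``theta_deg`` (from the vertical axis), indexed by
    h = −(l−1)/2 .. +(l−1)/2. Diagonal probes are 8-connected chains."""
    half = (l - 1) // 2
    hs = np.arange(-half, half + 1)
    yc, xc = center
    steps = {0.0: (1, 0), 45.0: (1, 1), 90.0: (0, 1), 135.0: (-1, 1)}
    if theta_deg not in steps:
        raise ValueError(f"theta must be one of {DIRECTIONS_DEG}")
    dy, dx = steps[theta_deg]
    return np.stack([yc + hs * dy, xc + hs * dx], axis=1)


def center_of_mass_track(video: VideoSequence, center: tuple[int, int],
                         l: int, theta_deg: float,
                         channel: int = 0) -> np.ndarray:
    """Gray-level center of mass along one probe line, per frame.

    CM(t) = Σ_h h·I[h, t] / Σ_h I[h, t]; a symmetric profile gives 0.
    If the summed intensity along the line is below 1e-12 the CM is defined
    as 0 (line center)."""
    pix = probe_line_pixels(center, l, theta_deg)
    h, w = video.shape[1:3]
    if pix[:, 0].min() < 0 or pix[:, 0].max() >= h or \
            pix[:, 1].min() < 0 or pix[:, 1].max() >= w:
        raise ValueError(f"probe line at {center} (θ={theta_deg}°) leaves frame")
    half = (l - 1) // 2
    hs = np.arange(-half, half + 1, dtype=float)
    intens = video.frames[:, pix[:, 0], pix[:, 1], channel]  # (T, l)
    tot = intens.sum(axis=1)
    cm = np.zeros(video.n_frames)
    ok = tot >= 1e-12
    cm[ok] = (intens[ok] * hs).sum(axis=1) / tot[ok]
    return cm


@dataclass(frozen=True)
class MotionDirector:
    """A triggered grid segment with its assigned direction of movement."""

    center: tuple[int, int]              # (y, x)
    theta_d: float                       # degrees from the vertical axis
    scores: dict[float, float]           # rms CM excursion per direction
    motion_sum: float

    def __post_init__(self) -> None:
        best = max(sorted(self.scores), key=lambda th: (self.scores[th], -th))
        if best != self.theta_d:
            raise ValueError("theta_d must be the argmax of scores")


def assign_direction(video: VideoSequence, segment: GridSegment, l: int,
                     motion_sum: float | None = None, channel: int = 0,
                     rms_floor: float = 1e-6) -> MotionDirector | None:
    """Assign the dominant movement direction to a triggered segment.

    The rms is taken of the center-of-mass track minus its temporal mean,
    per direction; the direction with the largest excursion wins, ties
    broken toward the lowest angle. Returns None (with a warning) when a
    probe leaves the frame, or silently when every direction's rms is below
    ``rms_floor`` (a static segment)."""
    scores: dict[float, float] = {}
    try:
        for theta in DIRECTIONS_DEG:
            cm = center_of_mass_track(video, segment.center, l, theta, channel)
            # rms in index (h) units; for boundary features the oblique
            # apparent-motion gain (1/cosψ) cancels the longer diagonal
            # pixel step, so the literal index convention discriminates
            scores[theta] = float(np.sqrt(np.mean((cm - cm.mean()) ** 2)))
    except ValueError as exc:
        warnings.warn(f"segment at {segment.center} skipped: {exc}",
                      UserWarning, stacklevel=2)
        return None
    if max(scores.values()) < rms_floor:
        return None
    theta_d = max(sorted(scores), key=lambda th: (scores[th], -th))
    if motion_sum is None:
        motion_sum = segment_motion_sum(video, segment, channel)
    return MotionDirector(center=segment.center, theta_d=theta_d,
                          scores=scores, motion_sum=float(motion_sum))


@dataclass(frozen=True)
class PhasedKymograph:
    """y–t kymograph of one probe line with phase-of-movement labels.

    ``phase_sign[t]`` is +1 where the smoothed center-of-mass derivative is
    positive (expansion by the default color convention, drawn red) and −1
    where negative (contraction, blue). The derivative comes from a
    degree-5 polynomial least-squares fitted over the 2·n_fit+1 frames
    around t; the first/last n_fit frames reuse the nearest full window.
    The red/blue ↔ expansion/contraction mapping is configurable because
    conventions differ between uses; only the sign-flip timing is contract.
    """

    image: np.ndarray       # (l, T) intensities along the line over time
    cm_track: np.ndarray    # (T,) center-of-mass position per frame
    phase_sign: np.ndarray  # (T,) in {−1, 0, +1}
    n_fit: int
    theta_deg: float
    center: tuple[int, int]


def _fitted_derivative(cm: np.ndarray, n_fit: int, degree: int = 5) -> np.ndarray:
    t = len(cm)
    win = 2 * n_fit + 1
    deriv = np.empty(t)
    for i in range(t):
        lo = min(max(i - n_fit, 0), t - win)  # nearest full window at ends
        ts = np.arange(lo, lo + win, dtype=float)
        coeffs = np.polynomial.polynomial.polyfit(ts - ts.mean(), cm[lo:lo + win],
                                                  degree)
        dcoeffs = np.polynomial.polynomial.polyder(coeffs)
        deriv[i] = np.polynomial.polynomial.polyval(i - ts.mean(), dcoeffs)
    return deriv


def phase_annotate(video: VideoSequence, center: tuple[int, int], l: int,
                   theta_deg: float, n_fit: int = 5,
                   channel: int = 0) -> PhasedKymograph:
    """Build the phase-labeled kymograph for one probe line."""
    if n_fit < 3:
        raise ValueError("n_fit must be ≥ 3 (degree-5 fit needs ≥ 6 points)")
    if video.n_frames < 2 * n_fit + 1:
        raise ValueError(
            f"need at least 2·n_fit+1={2 * n_fit + 1} frames, "
            f"got {video.n_frames}")
    cm = center_of_mass_track(video, center, l, theta_deg, channel)
    pix = probe_line_pixels(center, l, theta_deg)
    image = video.frames[:, pix[:, 0], pix[:, 1], channel].T  # (l, T)
    deriv = _fitted_derivative(cm, n_fit)
    return PhasedKymograph(image=image, cm_track=cm,
                           phase_sign=np.sign(deriv).astype(int),
                           n_fit=n_fit, theta_deg=theta_deg, center=center)


def _arrow_pixels(center: tuple[int, int], theta_deg: float,
                  length: float, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a double-headed arrow glyph along θ (from vertical)."""
    yc, xc = center
    theta = np.deg2rad(theta_deg)
    dy, dx = np.cos(theta), np.sin(theta)
    half = max(2, int(round(length)))
    y0, x0 = int(round(yc - dy * half)), int(round(xc - dx * half))
    y1, x1 = int(round(yc + dy * half)), int(round(xc + dx * half))
    h, w = shape
    y0, x0 = np.clip(y0, 0, h - 1), np.clip(x0, 0, w - 1)
    y1, x1 = np.clip(y1, 0, h - 1), np.clip(x1, 0, w - 1)
    return draw.line(y0, x0, y1, x1)


def render_directors(video: VideoSequence, directors: list[MotionDirector],
                     scale: float = 10.0) -> VideoSequence:
    """Burn an arrow glyph per director into every frame, oriented along
    θ_d with length proportional to its best rms score. Returns a new
    sequence; an empty director list returns the input frames unchanged."""
    frames = video.frames.copy()
    shape = video.shape[1:3]
    for d in directors:
        length = max(2.0, scale * d.scores[d.theta_d] * 10.0)
        rr, cc = _arrow_pixels(d.center, d.theta_d, length, shape)
        frames[:, rr, cc, :] = 1.0
    return video.with_frames(frames, video.channel_names)
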