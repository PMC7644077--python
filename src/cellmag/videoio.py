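"""Video/stack I/O, ROI and channel selection.

All pipeline stages exchange :class:`VideoSequence` objects: a ``T×H×W×C``
array of floating-point intensities in ``[0, 1]`` plus the acquisition
metadata (frame rate, optional pixel size) that frequency analysis needs.
Supported containers are multi-page TIFF / OME-TIFF (lossless, preferred)
and AVI/MP4 (preview-quality, requires an ffmpeg-capable imageio plugin).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile


__all__ = [
    "VideoSequence",
    "RectROI",
    "read_video",
    "write_video",
    "crop_roi",
    "select_channels",
]


@dataclass(frozen=True)
class VideoSequence:
    """A time-lapse sequence with acquisition metadata.

    Parameters
    ----------
    frames
        ``T×H×W×C`` float array, intensities in ``[0, 1]``.
    frame_rate_hz
        Acquisition frame rate in frames per second. Required: the whole
        spectral pipeline is meaningless without it.
    pixel_size_um
        Microns per pixel; metadata only, never used in computation.
    channel_names
        ``C`` labels, defaulting to ``ch0..ch{C-1}``.
    """

    frames: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float | None = None
    channel_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim == 3:  # T,H,W -> T,H,W,1
            frames = frames[..., None]
        if frames.ndim != 4:
            raise ValueError(f"frames must be T×H×W×C, got shape {frames.shape}")
        t, h, w, c = frames.shape
        if t < 2:
            raise ValueError(f"need at least 2 frames, got {t}")
        if h < 8 or w < 8:
            raise ValueError(f"frames must be at least 8×8 pixels, got {h}×{w}")
        if c < 1:
            raise ValueError("need at least one channel")
        if not np.isfinite(self.frame_rate_hz) or self.frame_rate_hz <= 0:
            raise ValueError(f"frame_rate_hz must be positive, got {self.frame_rate_hz}")
        names = tuple(self.channel_names) or tuple(f"ch{i}" for i in range(c))
        if len(names) != c:
            raise ValueError(f"{len(names)} channel names for {c} channels")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "channel_names", names)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.frames.shape

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def nyquist_hz(self) -> float:
        return self.frame_rate_hz / 2.0

    def with_frames(self, frames: np.ndarray,
                    channel_names: Sequence[str] | None = None) -> "VideoSequence":
        """New sequence with the same metadata but different pixel data."""
        names = tuple(channel_names) if channel_names is not None else ()
        if channel_names is None and np.ndim(frames) == 4 and \
                np.shape(frames)[-1] == len(self.channel_names):
            names = self.channel_names
        return VideoSequence(np.asarray(frames), self.frame_rate_hz,
                             self.pixel_size_um, names)


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangle, 0-based, half-open: pixels x0..x1-1, y0..y1-1."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (0 <= self.x0 < self.x1 and 0 <= self.y0 < self.y1):
            raise ValueError(f"degenerate ROI {self}")

    @classmethod
    def parse(cls, text: str) -> "RectROI":
        """Parse ``'x0,y0,x1,y1'``."""
        parts = [int(p) for p in re.split(r"[,:x ]+", text.strip()) if p]
        if len(parts) != 4:
            raise ValueError(f"ROI must be x0,y0,x1,y1, got {text!r}")
        return cls(*parts)


def _normalize(frames: np.ndarray) -> np.ndarray:
    """Map raw pixel data to float64 in [0, 1]: integer dtypes by their
    dtype max, floats by their own max if they exceed 1."""
    if np.issubdtype(frames.dtype, np.integer):
        scale = float(np.iinfo(frames.dtype).max)
        return frames.astype(np.float64) / scale
    out = frames.astype(np.float64)
    top = out.max(initial=0.0)
    if top > 1.0:
        out = out / top
    return np.clip(out, 0.0, 1.0)


_TIFF_SUFFIXES = {".tif", ".tiff", ".ome.tif", ".ome.tiff"}
_MOVIE_SUFFIXES = {".avi", ".mp4", ".mov", ".mkv"}


def _is_tiff(path: Path) -> bool:
    return path.suffix.lower() in {".tif", ".tiff"}


def _ome_frame_interval_s(tif: "tifffile.TiffFile") -> float | None:
    """TimeIncrement (seconds/frame) from OME-XML or our own ImageJ/JSON tag."""
    try:
        if tif.ome_metadata:
            m = re.search(r'TimeIncrement="([0-9.eE+-]+)"', tif.ome_metadata)
            if m:
                return float(m.group(1))
    except Exception:
        pass
    try:
        meta = tif.imagej_metadata or {}
        if "finterval" in meta and meta["finterval"]:
            return float(meta["finterval"])
        if "fps" in meta and meta["fps"]:
            return 1.0 / float(meta["fps"])
    except Exception:
        pass
    # our own sidecar tag written by write_video
    try:
        desc = tif.pages[0].description
        if desc and desc.lstrip().startswith("{"):
            meta = json.loads(desc)
            if "frame_rate_hz" in meta:
                return 1.0 / float(meta["frame_rate_hz"])
    except Exception:
        pass
    return None


def _read_tiff(path: Path, z_index: int | None) -> tuple[np.ndarray, float | None,
                                                         float | None, tuple[str, ...]]:
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        axes = tif.series[0].axes if tif.series else ""
        interval = _ome_frame_interval_s(tif)
        pixel_um = None
        names: tuple[str, ...] = ()
        try:
            desc = tif.pages[0].description
            if desc and desc.lstrip().startswith("{"):
                meta = json.loads(desc)
                pixel_um = meta.get("pixel_size_um")
                if meta.get("channel_names"):
                    names = tuple(meta["channel_names"])
        except Exception:
            pass

    data = np.asarray(data)
    axes = (axes or "").upper()
    if axes and len(axes) == data.ndim:
        # bring to T(Z)YX(C/S) order, select one z plane if present
        order = [ax for ax in axes]
        if "Z" in order:
            zi = 0 if z_index is None else int(z_index)
            data = np.take(data, zi, axis=order.index("Z"))
            order.remove("Z")
        if "S" in order and "C" not in order:
            order[order.index("S")] = "C"
        want = [ax for ax in "TYXC" if ax in order]
        if set(order) <= set("TYXC") and len(order) == data.ndim:
            data = np.moveaxis(data, [order.index(ax) for ax in want],
                               range(len(want)))
            if "T" not in want:
                data = data[None]
            if "C" not in want:
                data = data[..., None]
            return data, interval, pixel_um, names
    # fall back on shape heuristics: 3-D stacks are T,H,W; 4-D are T,H,W,C
    if data.ndim == 2:
        data = data[None, :, :, None]
    elif data.ndim == 3:
        data = data[..., None]
    elif data.ndim != 4:
        raise IOError(f"cannot interpret TIFF of shape {data.shape} as a video")
    return data, interval, pixel_um, names


def read_video(path: str | Path, frame_rate_override: float | None = None,
               z_index: int | None = None) -> VideoSequence:
    """Read a TIFF/OME-TIFF stack or an AVI/MP4 movie into a VideoSequence.

    The frame rate comes from container metadata (OME ``TimeIncrement``,
    ImageJ ``fps``/``finterval``, movie header) unless ``frame_rate_override``
    is given. A missing rate with no override is an error — without it the
    frequency axis of every later stage is undefined.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"video file not found: {path}")
    pixel_um = None
    names: tuple[str, ...] = ()
    if _is_tiff(path):
        try:
            data, interval, pixel_um, names = _read_tiff(path, z_index)
        except Exception as exc:  # corrupt container
            raise IOError(f"cannot read TIFF file {path}: {exc}") from exc
        rate = frame_rate_override
        if rate is None and interval:
            rate = 1.0 / interval
    elif path.suffix.lower() in _MOVIE_SUFFIXES:
        try:
            import imageio.v3 as iio
            data = np.stack(list(iio.imiter(str(path))))
            meta = iio.immeta(str(path), exclude_applied=False)
        except Exception as exc:
            raise IOError(
                f"cannot read movie file {path} (is an ffmpeg imageio plugin "
                f"installed?): {exc}") from exc
        if data.ndim == 3:
            data = data[..., None]
        rate = frame_rate_override if frame_rate_override is not None \
            else meta.get("fps")
    else:
        raise IOError(f"unsupported video format: {path.suffix!r} ({path})")
    if rate is None:
        raise ValueError(
            f"{path} carries no frame-rate metadata; pass frame_rate_override "
            "(frequency analysis is meaningless without a frame rate)")
    return VideoSequence(_normalize(data), float(rate), pixel_um, names)


def write_video(video: VideoSequence, path: str | Path,
                format: str | None = None) -> None:
    """Write a sequence to disk.

    TIFF output is 16-bit and lossless up to quantization (1/65535); the
    frame rate, pixel size and channel names ride along in a JSON page
    description so ``read_video`` round-trips metadata. MP4/AVI outputs are
    lossy previews through imageio.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("tif", "tiff"):
        data = np.clip(video.frames, 0.0, 1.0)
        data16 = np.round(data * 65535.0).astype(np.uint16)
        if data16.shape[-1] == 1:
            data16 = data16[..., 0]
        meta = {
            "frame_rate_hz": video.frame_rate_hz,
            "pixel_size_um": video.pixel_size_um,
            "channel_names": list(video.channel_names),
        }
        try:
            tifffile.imwrite(str(path), data16, description=json.dumps(meta),
                             metadata=None)
        except (OSError, FileNotFoundError) as exc:
            raise IOError(f"cannot write TIFF to {path}: {exc}") from exc
    elif fmt in ("mp4", "avi"):
        try:
            import imageio.v2 as iio
            data8 = np.round(np.clip(video.frames, 0, 1) * 255).astype(np.uint8)
            if data8.shape[-1] == 1:
                data8 = np.repeat(data8, 3, axis=-1)
            writer = iio.get_writer(str(path), fps=video.frame_rate_hz)
            for frame in data8:
                writer.append_data(frame)
            writer.close()
        except IOError:
            raise
        except Exception as exc:
            raise IOError(
                f"cannot write {fmt} to {path} (is an ffmpeg imageio plugin "
                f"installed?): {exc}") from exc
    else:
        raise IOError(f"unsupported output format {fmt!r}")


def crop_roi(video: VideoSequence, roi: RectROI) -> VideoSequence:
    """Extract a rectangular ROI from every frame; metadata preserved."""
    _, h, w, _ = video.shape
    if roi.x1 > w or roi.y1 > h:
        raise ValueError(f"ROI {roi} exceeds frame bounds {h}×{w}")
    return video.with_frames(video.frames[:, roi.y0:roi.y1, roi.x0:roi.x1, :],
                             video.channel_names)


def select_channels(video: VideoSequence,
                    channels: Sequence[int | str]) -> VideoSequence:
    """Keep only the requested channels (by index or name), in request order."""
    idx: list[int] = []
    for ch in channels:
        if isinstance(ch, str):
            if ch not in video.channel_names:
                raise ValueError(
                    f"unknown channel {ch!r}; available: {list(video.channel_names)}")
            idx.append(video.channel_names.index(ch))
        else:
            if not (0 <= ch < video.shape[3]):
                raise ValueError(
                    f"channel index {ch} out of range; available: "
                    f"{list(range(video.shape[3]))}")
            idx.append(int(ch))
    if not idx:
        raise ValueError("no channels requested")
    names = [video.channel_names[i] for i in idx]
    return video.with_frames(video.frames[..., idx], names)
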