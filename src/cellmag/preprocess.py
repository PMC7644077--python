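"""Optional visibility-improvement steps.

Two opt-in preprocessing stages run before any spectral analysis:

* **Deconvolution** reverses the blur of the microscope's point spread
  function with Richardson–Lucy iterations. If no PSF is supplied, a blind
  mode estimates one from the first frame (alternating image/PSF RL
  updates from a flat initial guess) and applies it to all frames.
* **Stabilization** removes rigid shake/drift between the camera and the
  sample: ORB salient points are detected in every frame, matched to a
  reference frame, a similarity transform (translation, rotation, scale)
  is estimated robustly with RANSAC, its translation refined to sub-pixel
  precision by phase correlation, the transform sequence smoothed with a
  local-linear (Savitzky–Golay) filter, and the frames warped onto the
  reference with bilinear interpolation (out-of-frame pixels take the
  frame's median intensity, so no spurious borders feed edge detection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal
from skimage import feature, measure, registration, restoration, transform

from .videoio import VideoSequence

__all__ = [
    "PSFModel",
    "StabilizationResult",
    "deconvolve",
    "stabilize",
    "blind_estimate_psf",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PSFModel:
    """Normalized odd-sized point-spread-function kernel."""

    kernel: np.ndarray
    provenance: str = "user-supplied"  # or "blind-estimated"

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=np.float64)
        if k.ndim != 2 or k.shape[0] != k.shape[1] or k.shape[0] % 2 == 0:
            raise ValueError(f"PSF kernel must be square with odd size, "
                             f"got {k.shape}")
        if (k < 0).any():
            raise ValueError("PSF kernel entries must be nonnegative")
        total = k.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            if total <= 0:
                raise ValueError("PSF kernel sums to zero")
            k = k / total
        object.__setattr__(self, "kernel", k)


def _rl_image_step(img: np.ndarray, est: np.ndarray, psf: np.ndarray) -> np.ndarray:
    conv = signal.fftconvolve(est, psf, mode="same")
    ratio = img / np.clip(conv, 1e-12, None)
    return est * signal.fftconvolve(ratio, psf[::-1, ::-1], mode="same")


def blind_estimate_psf(frame: np.ndarray, size: int = 7,
                       iterations: int = 10) -> PSFModel:
    """Blind PSF estimate from one frame: alternating Richardson–Lucy
    updates of the image and the kernel, starting from a flat guess."""
    if size % 2 == 0:
        raise ValueError("PSF size must be odd")
    frame = np.clip(np.asarray(frame, dtype=np.float64), 1e-9, None)
    psf = np.full((size, size), 1.0 / size ** 2)
    est = frame.copy()
    for _ in range(iterations):
        est = np.clip(_rl_image_step(frame, est, psf), 0, None)
        # RL update of the kernel, holding the image estimate fixed
        conv = signal.fftconvolve(est, psf, mode="same")
        ratio = frame / np.clip(conv, 1e-12, None)
        corr = signal.fftconvolve(ratio, est[::-1, ::-1], mode="same")
        ch, cw = corr.shape[0] // 2, corr.shape[1] // 2
        half = size // 2
        patch = corr[ch - half:ch + half + 1, cw - half:cw + half + 1]
        psf = np.clip(psf * patch, 0, None)
        total = psf.sum()
        psf = np.full_like(psf, 1.0 / size ** 2) if total <= 0 else psf / total
    return PSFModel(kernel=psf, provenance="blind-estimated")


def deconvolve(video: VideoSequence, psf: PSFModel | None = None,
               iterations: int = 10, blind_psf_size: int = 7) -> VideoSequence:
    """Richardson–Lucy deconvolution of every frame, per channel.

    With ``psf=None`` the PSF is blind-estimated from the first frame
    (channel 0) and then applied to all frames. Output is clipped to
    [0, 1]; intensities can never go negative.
    """
    if iterations < 1:
        raise ValueError("iterations must be ≥ 1")
    t, h, w, c = video.shape
    if psf is not None and (psf.kernel.shape[0] >= h or psf.kernel.shape[1] >= w):
        raise ValueError(
            f"PSF {psf.kernel.shape} must be smaller than the frame {h}×{w}")
    if psf is None:
        psf = blind_estimate_psf(video.frames[0, :, :, 0], blind_psf_size,
                                 iterations)
        logger.info("blind-estimated %dx%d PSF from first frame",
                    *psf.kernel.shape)
    out = np.empty_like(video.frames)
    pad = psf.kernel.shape[0]  # reflect-pad to suppress FFT edge ringing
    for ti in range(t):
        for ci in range(c):
            frame = np.pad(video.frames[ti, :, :, ci], pad, mode="reflect")
            dec = restoration.richardson_lucy(frame, psf.kernel,
                                              num_iter=iterations, clip=False)
            out[ti, :, :, ci] = dec[pad:-pad, pad:-pad]
    return video.with_frames(np.clip(out, 0.0, 1.0), video.channel_names)


@dataclass(frozen=True)
class StabilizationResult:
    """Stabilized video plus the per-frame similarity parameters
    (dx, dy, rotation_deg, scale) that map each frame onto the reference."""

    video: VideoSequence
    transforms: np.ndarray       # (T, 4): dx, dy, rot_deg, scale
    reference_index: int
    residual_translation_px: np.ndarray  # (T-1,) |shift| between consecutive
                                         # stabilized frames

    def __post_init__(self) -> None:
        if self.transforms.shape != (self.video.n_frames, 4):
            raise ValueError("need one transform per frame")


def _frame_gray(video: VideoSequence, t: int) -> np.ndarray:
    return video.frames[t].mean(axis=-1)


def _estimate_similarity(src_img: np.ndarray, ref_img: np.ndarray,
                         orb: "feature.ORB", ref_kp: np.ndarray,
                         ref_desc: np.ndarray,
                         min_matches: int) -> np.ndarray | None:
    """(dx, dy, rot_deg, scale) mapping src onto ref, or None."""
    try:
        orb.detect_and_extract(src_img)
    except RuntimeError:
        return None
    kp, desc = orb.keypoints, orb.descriptors
    if desc is None or len(kp) < min_matches:
        return None
    matches = feature.match_descriptors(ref_desc, desc, cross_check=True)
    if len(matches) < min_matches:
        return None
    src = kp[matches[:, 1]][:, ::-1]   # (x, y)
    dst = ref_kp[matches[:, 0]][:, ::-1]
    model, inliers = measure.ransac(
        (src, dst), transform.SimilarityTransform, min_samples=2,
        residual_threshold=1.0, max_trials=300, rng=0)
    if model is None or inliers is None or inliers.sum() < min_matches:
        return None
    # sub-pixel translation refinement by phase correlation on the
    # rotation/scale-corrected frame
    partial = transform.SimilarityTransform(
        rotation=model.rotation, scale=model.scale)
    warped = transform.warp(src_img, partial.inverse, order=1,
                            cval=float(np.median(src_img)))
    shift = registration.phase_cross_correlation(
        ref_img, warped, upsample_factor=50, normalization=None)[0]
    candidate_sim = np.array([shift[1], shift[0],
                              np.rad2deg(model.rotation), model.scale])
    # keypoint quantization can fake small rotations/scales; also score a
    # pure-translation candidate and keep whichever registers better
    shift_t = registration.phase_cross_correlation(
        ref_img, src_img, upsample_factor=50, normalization=None)[0]
    candidate_tr = np.array([shift_t[1], shift_t[0], 0.0, 1.0])
    best, best_err = None, np.inf
    for cand in (candidate_sim, candidate_tr):
        tf = transform.SimilarityTransform(
            rotation=np.deg2rad(cand[2]), scale=cand[3],
            translation=(cand[0], cand[1]))
        w = transform.warp(src_img, tf.inverse, order=1,
                           cval=float(np.median(src_img)))
        err = float(np.mean((w - ref_img) ** 2))
        if err < best_err:
            best, best_err = cand, err
    return best


def stabilize(video: VideoSequence, reference_index: int = 0,
              smooth_window: int = 5, min_matches: int = 8,
              n_keypoints: int = 300) -> StabilizationResult:
    """Register every frame onto the reference frame.

    Frames whose feature matching fails (fewer than ``min_matches`` robust
    correspondences) inherit the previous frame's transform with a logged
    warning. ``smooth_window`` (odd, ≥ 3; 1 disables) is the length of the
    local-linear smoothing of the transform sequence.
    """
    t = video.n_frames
    if not (0 <= reference_index < t):
        raise ValueError(f"reference_index {reference_index} out of range")
    ref_img = _frame_gray(video, reference_index)
    orb = feature.ORB(n_keypoints=n_keypoints, fast_threshold=0.02)
    try:
        orb.detect_and_extract(ref_img)
        ref_kp, ref_desc = orb.keypoints, orb.descriptors
    except RuntimeError:
        ref_kp, ref_desc = np.empty((0, 2)), None

    params = np.zeros((t, 4))
    params[:, 3] = 1.0
    prev = np.array([0.0, 0.0, 0.0, 1.0])
    for ti in range(t):
        if ti == reference_index:
            prev = np.array([0.0, 0.0, 0.0, 1.0])
            params[ti] = prev
            continue
        est = None
        if ref_desc is not None:
            est = _estimate_similarity(_frame_gray(video, ti), ref_img, orb,
                                       ref_kp, ref_desc, min_matches)
        if est is None:
            logger.warning("frame %d: too few matched features; keeping the "
                           "previous frame's transform", ti)
            est = prev.copy()
        params[ti] = est
        prev = est

    if smooth_window and smooth_window >= 3 and t >= smooth_window:
        smoothed = params.copy()
        for j in range(4):
            smoothed[:, j] = signal.savgol_filter(
                params[:, j], smooth_window, polyorder=1, mode="interp")
        smoothed[reference_index] = [0.0, 0.0, 0.0, 1.0]
        params = smoothed

    out = np.empty_like(video.frames)
    for ti in range(t):
        dx, dy, rot_deg, scale = params[ti]
        tf = transform.SimilarityTransform(
            rotation=np.deg2rad(rot_deg), scale=scale,
            translation=(dx, dy))
        for ci in range(video.shape[3]):
            frame = video.frames[ti, :, :, ci]
            out[ti, :, :, ci] = transform.warp(
                frame, tf.inverse, order=1, cval=float(np.median(frame)))

    stab = video.with_frames(np.clip(out, 0.0, 1.0), video.channel_names)
    residual = np.empty(t - 1)
    for ti in range(t - 1):
        shift = registration.phase_cross_correlation(
            stab.frames[ti, :, :, 0], stab.frames[ti + 1, :, :, 0],
            upsample_factor=20, normalization=None)[0]
        residual[ti] = float(np.hypot(*shift))
    return StabilizationResult(video=stab, transforms=params,
                               reference_index=reference_index,
                               residual_translation_px=residual)
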