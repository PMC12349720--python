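"""Quantitative ROI features: intensity, enhancement, size, and SD.

All intensity statistics are computed after restricting the image to
the [-150, 1000] HU window.  Enhancement is the pixel-wise difference
of a post-contrast phase from the precontrast phase, computed on
clipped images (clip-before-subtract; the order matters for extreme
values).  Lesion size is automated from the ROI mask as the maximum
Feret diameter plus the perpendicular extent; manual measurements can
be supplied through annotation tables instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .core import HU_CLIP_RANGE, Phase, PhaseImage, StudySet

__all__ = [
    "ROIStats",
    "EnhancementStats",
    "LesionSize",
    "clip_hu",
    "clip_array",
    "roi_intensity_stats",
    "enhancement_image",
    "enhancement_stats",
    "lesion_dimensions",
    "image_sd",
]


@dataclass(frozen=True)
class ROIStats:
    min_hu: float
    mean_hu: float
    max_hu: float
    sd_hu: float
    n_pixels: int


@dataclass(frozen=True)
class EnhancementStats:
    min_enh: float
    mean_enh: float
    max_enh: float
    phase: Phase


@dataclass(frozen=True)
class LesionSize:
    d1: float  # longest dimension, mm
    d2: float  # perpendicular second dimension, mm


def clip_array(pixels: np.ndarray) -> np.ndarray:
    """Restrict HU values to the clip window; idempotent."""
    pixels = np.asarray(pixels, dtype=float)
    if not np.all(np.isfinite(pixels)):
        raise ValueError("pixels must be finite")
    return np.clip(pixels, *HU_CLIP_RANGE)


def clip_hu(image: PhaseImage) -> PhaseImage:
    return image.copy_with(pixels=clip_array(image.pixels))


def _check_roi(roi: np.ndarray, shape) -> np.ndarray:
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != tuple(shape):
        raise ValueError("ROI mask must share the image grid")
    if not roi.any():
        raise ValueError("ROI is empty: unusable annotation")
    return roi


def roi_intensity_stats(image: PhaseImage, roi: np.ndarray) -> ROIStats:
    """Min / mean / max / SD of the clipped HU values inside the ROI."""
    roi = _check_roi(roi, image.shape)
    vals = clip_array(image.pixels)[roi]
    return ROIStats(
        min_hu=float(vals.min()),
        mean_hu=float(vals.mean()),
        max_hu=float(vals.max()),
        sd_hu=float(vals.std()),  # population SD
        n_pixels=int(vals.size),
    )


def enhancement_image(post: PhaseImage, pre: PhaseImage) -> np.ndarray:
    """Pixel-wise enhancement map clip(post) - clip(pre)."""
    if post.phase == Phase.PRECONTRAST:
        raise ValueError("enhancement is undefined for the precontrast phase")
    if pre.phase != Phase.PRECONTRAST:
        raise ValueError("the reference image must be the precontrast phase")
    if post.shape != pre.shape:
        raise ValueError("geometry mismatch between phases")
    return clip_array(post.pixels) - clip_array(pre.pixels)


def enhancement_stats(study: StudySet, phase: Phase | str, roi: np.ndarray | None = None) -> EnhancementStats:
    """Min / mean / max enhancement over the tumor ROI for one post-contrast phase."""
    phase = Phase(phase)
    roi = _check_roi(study.tumor_roi if roi is None else roi, study.shape)
    enh = enhancement_image(study[phase], study[Phase.PRECONTRAST])[roi]
    return EnhancementStats(
        min_enh=float(enh.min()),
        mean_enh=float(enh.mean()),
        max_enh=float(enh.max()),
        phase=phase,
    )


def lesion_dimensions(roi: np.ndarray, spacing: float = 1.0) -> LesionSize:
    """Lesion size from the ROI mask.

    ``d1`` is the maximum pairwise distance between ROI pixel centers
    (maximum Feret diameter) times the spacing; ``d2`` is the extent of
    the pixel centers perpendicular to the d1 axis.  Both are floored
    at one pixel spacing so a single-pixel ROI reports
    ``d1 = d2 = spacing``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    coords = np.argwhere(roi).astype(float)
    if len(coords) == 1:
        return LesionSize(d1=spacing, d2=spacing)
    try:
        hull_pts = coords[ConvexHull(coords).vertices]
    except QhullError:  # collinear pixels
        hull_pts = coords
    diff = hull_pts[:, None, :] - hull_pts[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    d1 = dist[i, j]
    axis = hull_pts[j] - hull_pts[i]
    perp = np.array([-axis[1], axis[0]]) / max(d1, 1e-12)
    proj = coords @ perp
    d2 = proj.max() - proj.min()
    d1 = max(d1, 1.0) * spacing
    d2 = max(d2, 1.0) * spacing
    if d2 > d1:  # guard against discretization on near-isotropic masks
        d1, d2 = d2, d1
    return LesionSize(d1=float(d1), d2=float(d2))


def image_sd(image: PhaseImage, roi: np.ndarray | None = None, region: str = "roi") -> float:
    """Population SD of clipped pixel values over the ROI or full crop."""
    if region not in ("roi", "full_crop"):
        raise ValueError("region must be 'roi' or 'full_crop'")
    vals = clip_array(image.pixels)
    if region == "roi":
        roi = _check_roi(roi, image.shape)
        vals = vals[roi]
    return float(np.asarray(vals).std())
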