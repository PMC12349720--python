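"""Hallucination Index: tumor-histogram Hellinger distance per image pair.

The tumor region of each image is reduced to a normalized histogram of
clipped HU values over bin edges shared between the pair, and the
Hellinger distance

    H(p, q) = sqrt(1 - sum_i sqrt(p_i q_i))

between the two histograms is the pair's Hallucination Index: 0 for
identical distributions (no hallucination), 1 for distributions with
no overlap.  The default binning is 64 uniform bins over the clipped
range [-150, 1000] HU; bin count/range are config-exposed since the
distributional proxy is only meaningful with shared edges.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import HU_CLIP_RANGE, PhaseImage
from .quantify import clip_array

__all__ = [
    "default_bin_edges",
    "roi_histogram",
    "hellinger_distance",
    "hallucination_index",
    "cohort_hallucination",
]

DEFAULT_N_BINS = 64


def default_bin_edges(n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Uniform bin edges over the clipped HU range."""
    return np.linspace(HU_CLIP_RANGE[0], HU_CLIP_RANGE[1], n_bins + 1)


def roi_histogram(image: PhaseImage, roi: np.ndarray, edges: np.ndarray | None = None) -> np.ndarray:
    """Normalized histogram of clipped ROI pixel values."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != image.shape:
        raise ValueError("ROI mask must share the image grid")
    if not roi.any():
        raise ValueError("ROI is empty")
    edges = default_bin_edges() if edges is None else np.asarray(edges, dtype=float)
    if edges[0] > HU_CLIP_RANGE[0] or edges[-1] < HU_CLIP_RANGE[1]:
        raise ValueError("bin edges must cover the clipped HU range")
    vals = clip_array(image.pixels)[roi]
    counts, _ = np.histogram(vals, bins=edges)
    return counts / counts.sum()


def hellinger_distance(p, q, smoothing: float = 0.0, tol: float = 1e-9) -> float:
    """Hellinger distance between two discrete probability vectors.

    Symmetric and bounded in [0, 1] (clamped against rounding).  With
    ``smoothing`` > 0, an additive pseudo-mass is applied to both
    vectors before renormalizing (off by default: empty bins simply
    contribute nothing to the Bhattacharyya sum).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("p and q must be 1-D vectors of equal length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("mass vectors must be non-negative")
    if abs(p.sum() - 1.0) > tol or abs(q.sum() - 1.0) > tol:
        raise ValueError("mass vectors must each sum to 1")
    if smoothing > 0:
        p = (p + smoothing) / (p + smoothing).sum()
        q = (q + smoothing) / (q + smoothing).sum()
    if np.array_equal(p, q):  # identical distributions are exactly 0
        return 0.0
    bc = np.sqrt(p * q).sum()
    return float(np.sqrt(np.clip(1.0 - bc, 0.0, 1.0)))


def hallucination_index(
    gt: PhaseImage,
    imp: PhaseImage,
    roi: np.ndarray,
    edges: np.ndarray | None = None,
    smoothing: float = 0.0,
) -> float:
    """Hellinger distance between the tumor-ROI histograms of a pair."""
    if gt.shape != imp.shape:
        raise ValueError("geometry mismatch between GT and imputed images")
    edges = default_bin_edges() if edges is None else np.asarray(edges, dtype=float)
    p = roi_histogram(gt, roi, edges)
    q = roi_histogram(imp, roi, edges)
    return hellinger_distance(p, q, smoothing=smoothing)


def cohort_hallucination(per_pair: pd.DataFrame, sample_variance: bool = False) -> dict:
    """Summarize per-pair indices: pooled mean/variance and per-phase means.

    ``per_pair`` needs columns (study_id, phase, hallucination_index).
    Variance is the population variance by default.
    """
    if per_pair.empty:
        raise ValueError("no pairs")
    h = per_pair["hallucination_index"].to_numpy(float)
    ddof = 1 if sample_variance else 0
    per_phase = (
        per_pair.groupby("phase", observed=True)["hallucination_index"].mean().to_dict()
    )
    return {
        "n": int(h.size),
        "mean": float(h.mean()),
        "variance": float(h.var(ddof=ddof)) if h.size > ddof else float("nan"),
        "per_phase_mean": per_phase,
    }
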