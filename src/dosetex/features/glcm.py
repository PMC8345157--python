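"""Co-occurrence (GLCM) features: 25 base features x 4 aggregations = 100.

Aggregations:

``2D_avg``   feature per (slice, in-plane direction) matrix, averaged;
``2D_merge`` matrices merged over the 4 in-plane directions per slice,
             feature per slice, averaged over slices;
``3D_avg``   feature per volumetric direction matrix (13 directions), averaged;
``3D_merge`` all 13 direction matrices summed, single feature.

Empty matrices (no valid voxel pair) are skipped from averages; features that
are undefined on a matrix (e.g. correlation of a single-level ROI) propagate
as NaN and are flagged downstream.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Sequence

import numpy as np

from ..preprocessing import DiscretisedRoi
from .matrices import DIRECTIONS_2D, DIRECTIONS_3D, glcm_counts
from .registry import GLCM_AGGREGATIONS

GLCM_NAMES = (
    "joint_maximum",
    "joint_average",
    "joint_variance",
    "joint_entropy",
    "difference_average",
    "difference_variance",
    "difference_entropy",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "angular_second_moment",
    "contrast",
    "dissimilarity",
    "inverse_difference",
    "inverse_difference_normalised",
    "inverse_difference_moment",
    "inverse_difference_moment_normalised",
    "inverse_variance",
    "correlation",
    "autocorrelation",
    "cluster_tendency",
    "cluster_shade",
    "cluster_prominence",
    "information_correlation_1",
    "information_correlation_2",
)

_NAN_ROW = {name: float("nan") for name in GLCM_NAMES}


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def glcm_features_from_counts(counts: np.ndarray, G: int) -> Dict[str, float]:
    """The 25 co-occurrence features of one (symmetrised) count matrix."""
    total = counts.sum()
    if total == 0:
        return dict(_NAN_ROW)
    # restrict to the grey levels present; zero rows contribute nothing
    present = np.flatnonzero((counts.sum(axis=0) + counts.sum(axis=1)) > 0)
    P = counts[np.ix_(present, present)] / total
    i = (present + 1).astype(np.float64)
    ii = i[:, None]
    jj = i[None, :]

    px = P.sum(axis=1)  # symmetric: px == py
    mu = float(np.sum(i * px))
    sigma2 = float(np.sum((i - mu) ** 2 * px))

    diff = np.abs(ii - jj)
    sum_ = ii + jj
    k_diff = np.arange(0, G, dtype=np.float64)
    p_diff = np.zeros(G)
    np.add.at(p_diff, diff.astype(np.int64).ravel(), P.ravel())
    k_sum = np.arange(0, 2 * G + 1, dtype=np.float64)
    p_sum = np.zeros(2 * G + 1)
    np.add.at(p_sum, sum_.astype(np.int64).ravel(), P.ravel())

    diff_avg = float(np.sum(k_diff * p_diff))
    sum_avg = float(np.sum(k_sum * p_sum))
    joint_entropy = _entropy(P.ravel())

    autocorr = float(np.sum(ii * jj * P))
    if sigma2 > 0:
        correlation = (autocorr - mu * mu) / sigma2
    else:
        correlation = float("nan")

    hx = _entropy(px)
    outer = px[:, None] * px[None, :]
    pos = (P > 0) & (outer > 0)
    hxy1 = float(-np.sum(P[pos] * np.log2(outer[pos])))
    hxy2 = _entropy(outer.ravel())
    ic1 = (joint_entropy - hxy1) / hx if hx > 0 else float("nan")
    arg = 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy))
    ic2 = float(np.sqrt(max(arg, 0.0)))

    return {
        "joint_maximum": float(P.max()),
        "joint_average": mu,
        "joint_variance": float(np.sum((ii - mu) ** 2 * P)),
        "joint_entropy": joint_entropy,
        "difference_average": diff_avg,
        "difference_variance": float(np.sum((k_diff - diff_avg) ** 2 * p_diff)),
        "difference_entropy": _entropy(p_diff),
        "sum_average": sum_avg,
        "sum_variance": float(np.sum((k_sum - sum_avg) ** 2 * p_sum)),
        "sum_entropy": _entropy(p_sum),
        "angular_second_moment": float(np.sum(P**2)),
        "contrast": float(np.sum(k_diff**2 * p_diff)),
        "dissimilarity": diff_avg,
        "inverse_difference": float(np.sum(p_diff / (1.0 + k_diff))),
        "inverse_difference_normalised": float(np.sum(p_diff / (1.0 + k_diff / G))),
        "inverse_difference_moment": float(np.sum(p_diff / (1.0 + k_diff**2))),
        "inverse_difference_moment_normalised": float(
            np.sum(p_diff / (1.0 + k_diff**2 / G**2))
        ),
        "inverse_variance": float(np.sum(p_diff[1:] / k_diff[1:] ** 2)),
        "correlation": correlation,
        "autocorrelation": autocorr,
        "cluster_tendency": float(np.sum((sum_ - 2 * mu) ** 2 * P)),
        "cluster_shade": float(np.sum((sum_ - 2 * mu) ** 3 * P)),
        "cluster_prominence": float(np.sum((sum_ - 2 * mu) ** 4 * P)),
        "information_correlation_1": ic1,
        "information_correlation_2": ic2,
    }


def _average_rows(rows: List[Dict[str, float]]) -> Dict[str, float]:
    if not rows:
        return dict(_NAN_ROW)
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        for name in GLCM_NAMES:
            out[name] = float(np.nanmean([r[name] for r in rows]))
    return out


def glcm_features(roi: DiscretisedRoi) -> Dict[str, Dict[str, float]]:
    """All 100 co-occurrence features, keyed ``{aggregation: {name: value}}``."""
    G = roi.G
    levels, mask = roi.levels, roi.mask
    nz = levels.shape[0]

    # per-slice, per-direction counts (reused by both 2D aggregations)
    slice_dir_counts: List[List[np.ndarray]] = []
    for k in range(nz):
        if not mask[k].any():
            continue
        lev_k, mask_k = levels[k][None], mask[k][None]
        slice_dir_counts.append(
            [glcm_counts(lev_k, mask_k, d, G) for d in DIRECTIONS_2D]
        )

    rows_2d_avg = [
        glcm_features_from_counts(c, G)
        for per_dir in slice_dir_counts
        for c in per_dir
        if c.sum() > 0
    ]
    rows_2d_merge = []
    for per_dir in slice_dir_counts:
        merged = sum(per_dir)
        if merged.sum() > 0:
            rows_2d_merge.append(glcm_features_from_counts(merged, G))

    dir_counts = [glcm_counts(levels, mask, d, G) for d in DIRECTIONS_3D]
    rows_3d_avg = [glcm_features_from_counts(c, G) for c in dir_counts if c.sum() > 0]
    merged_3d = sum(dir_counts)

    return {
        "2D_avg": _average_rows(rows_2d_avg),
        "2D_merge": _average_rows(rows_2d_merge),
        "3D_avg": _average_rows(rows_3d_avg),
        "3D_merge": glcm_features_from_counts(merged_3d, G),
    }


assert set(GLCM_AGGREGATIONS) == {"2D_avg", "2D_merge", "3D_avg", "3D_merge"}
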