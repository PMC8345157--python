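"""Run-length (GLRLM) features: 16 base features x 4 aggregations.

Aggregation semantics mirror the co-occurrence family.  ``run_percentage``
divides the number of runs by the number of voxels scanned: for merged
matrices that denominator is multiplied by the number of merged directions.
"""

from __future__ import annotations

import warnings
from typing import Dict, List

import numpy as np

from ..preprocessing import DiscretisedRoi
from .matrices import DIRECTIONS_2D, DIRECTIONS_3D, run_length_counts

GLRLM_NAMES = (
    "short_runs_emphasis",
    "long_runs_emphasis",
    "low_grey_level_run_emphasis",
    "high_grey_level_run_emphasis",
    "short_run_low_grey_level_emphasis",
    "short_run_high_grey_level_emphasis",
    "long_run_low_grey_level_emphasis",
    "long_run_high_grey_level_emphasis",
    "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised",
    "run_length_non_uniformity",
    "run_length_non_uniformity_normalised",
    "run_percentage",
    "grey_level_variance",
    "run_length_variance",
    "run_entropy",
)

_NAN_ROW = {name: float("nan") for name in GLRLM_NAMES}


def glrlm_features_from_counts(counts: np.ndarray, n_voxels: int) -> Dict[str, float]:
    """The 16 run-length features of one count matrix ``R[level-1, len-1]``."""
    ns = counts.sum()
    if ns == 0 or n_voxels == 0:
        return dict(_NAN_ROW)
    G, L = counts.shape
    i = np.arange(1, G + 1, dtype=np.float64)
    l = np.arange(1, L + 1, dtype=np.float64)
    r_i = counts.sum(axis=1)
    r_l = counts.sum(axis=0)
    p = counts / ns
    mu_g = float(np.sum(i * r_i) / ns)
    mu_l = float(np.sum(l * r_l) / ns)
    pos = p > 0

    return {
        "short_runs_emphasis": float(np.sum(r_l / l**2) / ns),
        "long_runs_emphasis": float(np.sum(r_l * l**2) / ns),
        "low_grey_level_run_emphasis": float(np.sum(r_i / i**2) / ns),
        "high_grey_level_run_emphasis": float(np.sum(r_i * i**2) / ns),
        "short_run_low_grey_level_emphasis": float(
            np.sum(counts / (i[:, None] ** 2 * l[None, :] ** 2)) / ns
        ),
        "short_run_high_grey_level_emphasis": float(
            np.sum(counts * i[:, None] ** 2 / l[None, :] ** 2) / ns
        ),
        "long_run_low_grey_level_emphasis": float(
            np.sum(counts * l[None, :] ** 2 / i[:, None] ** 2) / ns
        ),
        "long_run_high_grey_level_emphasis": float(
            np.sum(counts * i[:, None] ** 2 * l[None, :] ** 2) / ns
        ),
        "grey_level_non_uniformity": float(np.sum(r_i**2) / ns),
        "grey_level_non_uniformity_normalised": float(np.sum(r_i**2) / ns**2),
        "run_length_non_uniformity": float(np.sum(r_l**2) / ns),
        "run_length_non_uniformity_normalised": float(np.sum(r_l**2) / ns**2),
        "run_percentage": float(ns / n_voxels),
        "grey_level_variance": float(np.sum((i[:, None] - mu_g) ** 2 * p)),
        "run_length_variance": float(np.sum((l[None, :] - mu_l) ** 2 * p)),
        "run_entropy": float(-np.sum(p[pos] * np.log2(p[pos]))),
    }


def _pad_merge(matrices: List[np.ndarray]) -> np.ndarray:
    G = matrices[0].shape[0]
    L = max(m.shape[1] for m in matrices)
    out = np.zeros((G, L))
    for m in matrices:
        out[:, : m.shape[1]] += m
    return out


def _average_rows(rows: List[Dict[str, float]]) -> Dict[str, float]:
    if not rows:
        return dict(_NAN_ROW)
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        for name in GLRLM_NAMES:
            out[name] = float(np.nanmean([r[name] for r in rows]))
    return out


def runlength_features(roi: DiscretisedRoi) -> Dict[str, Dict[str, float]]:
    """All run-length features, keyed ``{aggregation: {name: value}}``."""
    G = roi.G
    levels, mask = roi.levels, roi.mask
    nz = levels.shape[0]

    slice_dir: List[List[np.ndarray]] = []
    slice_nvox: List[int] = []
    for k in range(nz):
        if not mask[k].any():
            continue
        lev_k, mask_k = levels[k][None], mask[k][None]
        slice_dir.append([run_length_counts(lev_k, mask_k, d, G) for d in DIRECTIONS_2D])
        slice_nvox.append(int(mask[k].sum()))

    rows_2d_avg = [
        glrlm_features_from_counts(m, nv)
        for per_dir, nv in zip(slice_dir, slice_nvox)
        for m in per_dir
        if m.sum() > 0
    ]
    rows_2d_merge = []
    for per_dir, nv in zip(slice_dir, slice_nvox):
        merged = _pad_merge(per_dir)
        if merged.sum() > 0:
            rows_2d_merge.append(glrlm_features_from_counts(merged, nv * len(DIRECTIONS_2D)))

    dir_mats = [run_length_counts(levels, mask, d, G) for d in DIRECTIONS_3D]
    rows_3d_avg = [
        glrlm_features_from_counts(m, roi.n_voxels) for m in dir_mats if m.sum() > 0
    ]
    merged_3d = _pad_merge(dir_mats)

    return {
        "2D_avg": _average_rows(rows_2d_avg),
        "2D_merge": _average_rows(rows_2d_merge),
        "3D_avg": _average_rows(rows_3d_avg),
        "3D_merge": glrlm_features_from_counts(
            merged_3d, roi.n_voxels * len(DIRECTIONS_3D)
        ),
    }
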