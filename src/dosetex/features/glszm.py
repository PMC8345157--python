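"""Size-zone (GLSZM) features: 16 base features x 2 aggregations = 32.

``2D_merge`` labels zones slice-wise with 8-connectivity and merges the
per-slice matrices; ``3D`` labels the whole volume with 26-connectivity.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from ..preprocessing import DiscretisedRoi
from .matrices import size_zone_matrix

GLSZM_NAMES = (
    "small_zone_emphasis",
    "large_zone_emphasis",
    "low_grey_level_zone_emphasis",
    "high_grey_level_zone_emphasis",
    "small_zone_low_grey_level_emphasis",
    "small_zone_high_grey_level_emphasis",
    "large_zone_low_grey_level_emphasis",
    "large_zone_high_grey_level_emphasis",
    "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised",
    "zone_size_non_uniformity",
    "zone_size_non_uniformity_normalised",
    "zone_percentage",
    "grey_level_variance",
    "zone_size_variance",
    "zone_size_entropy",
)

_NAN_ROW = {name: float("nan") for name in GLSZM_NAMES}


def glszm_features_from_counts(counts: np.ndarray, n_voxels: int) -> Dict[str, float]:
    """The 16 size-zone features of one count matrix ``S[level-1, size-1]``."""
    ns = counts.sum()
    if ns == 0 or n_voxels == 0:
        return dict(_NAN_ROW)
    G, S = counts.shape
    i = np.arange(1, G + 1, dtype=np.float64)
    s = np.arange(1, S + 1, dtype=np.float64)
    z_i = counts.sum(axis=1)
    z_s = counts.sum(axis=0)
    p = counts / ns
    mu_g = float(np.sum(i * z_i) / ns)
    mu_s = float(np.sum(s * z_s) / ns)
    pos = p > 0

    return {
        "small_zone_emphasis": float(np.sum(z_s / s**2) / ns),
        "large_zone_emphasis": float(np.sum(z_s * s**2) / ns),
        "low_grey_level_zone_emphasis": float(np.sum(z_i / i**2) / ns),
        "high_grey_level_zone_emphasis": float(np.sum(z_i * i**2) / ns),
        "small_zone_low_grey_level_emphasis": float(
            np.sum(counts / (i[:, None] ** 2 * s[None, :] ** 2)) / ns
        ),
        "small_zone_high_grey_level_emphasis": float(
            np.sum(counts * i[:, None] ** 2 / s[None, :] ** 2) / ns
        ),
        "large_zone_low_grey_level_emphasis": float(
            np.sum(counts * s[None, :] ** 2 / i[:, None] ** 2) / ns
        ),
        "large_zone_high_grey_level_emphasis": float(
            np.sum(counts * i[:, None] ** 2 * s[None, :] ** 2) / ns
        ),
        "grey_level_non_uniformity": float(np.sum(z_i**2) / ns),
        "grey_level_non_uniformity_normalised": float(np.sum(z_i**2) / ns**2),
        "zone_size_non_uniformity": float(np.sum(z_s**2) / ns),
        "zone_size_non_uniformity_normalised": float(np.sum(z_s**2) / ns**2),
        "zone_percentage": float(ns / n_voxels),
        "grey_level_variance": float(np.sum((i[:, None] - mu_g) ** 2 * p)),
        "zone_size_variance": float(np.sum((s[None, :] - mu_s) ** 2 * p)),
        "zone_size_entropy": float(-np.sum(p[pos] * np.log2(p[pos]))),
    }


def sizezone_features(roi: DiscretisedRoi) -> Dict[str, Dict[str, float]]:
    """All 32 size-zone features, keyed ``{aggregation: {name: value}}``."""
    out: Dict[str, Dict[str, float]] = {}
    for agg in ("2D_merge", "3D"):
        tm = size_zone_matrix(roi, mode=agg)
        out[agg] = glszm_features_from_counts(tm.counts, tm.n_voxels)
    return out
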