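"""Intensity-based statistics (STAT family) on raw dose values in Gy.

The 17 statistics follow the IBSI intensity-based family with the population
(biased) variance convention.  Skewness and kurtosis (excess) are undefined
for constant input and are emitted as NaN; everything else is computed.
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np

STAT_NAMES = (
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "median",
    "minimum",
    "percentile_10",
    "percentile_90",
    "maximum",
    "interquartile_range",
    "range",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "median_absolute_deviation",
    "coefficient_of_variation",
    "energy",
    "root_mean_square",
)


def stat_features(values: Sequence[float]) -> Dict[str, float]:
    """Compute the 17 intensity statistics of one ROI's dose values."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 values for intensity statistics")

    mean = float(x.mean())
    var = float(x.var())  # population convention (ddof=0)
    sd = np.sqrt(var)
    if sd > 0:
        skew = float(np.mean((x - mean) ** 3) / sd**3)
        kurt = float(np.mean((x - mean) ** 4) / var**2 - 3.0)
    else:
        skew = float("nan")
        kurt = float("nan")
    p10, p25, p75, p90 = (float(v) for v in np.percentile(x, [10, 25, 75, 90]))
    median = float(np.median(x))
    # robust MAD: mean absolute deviation of the values inside [p10, p90],
    # taken about the mean of that subset
    robust = x[(x >= p10) & (x <= p90)]
    robust_mad = float(np.mean(np.abs(robust - robust.mean()))) if robust.size else float("nan")
    cov = sd / mean if mean != 0 else float("nan")

    return {
        "mean": mean,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "median": median,
        "minimum": float(x.min()),
        "percentile_10": p10,
        "percentile_90": p90,
        "maximum": float(x.max()),
        "interquartile_range": p75 - p25,
        "range": float(x.max() - x.min()),
        "mean_absolute_deviation": float(np.mean(np.abs(x - mean))),
        "robust_mean_absolute_deviation": robust_mad,
        "median_absolute_deviation": float(np.mean(np.abs(x - median))),
        "coefficient_of_variation": cov,
        "energy": float(np.sum(x**2)),
        "root_mean_square": float(np.sqrt(np.mean(x**2))),
    }
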