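"""Cohort-level feature variability: CV, threshold selection, ICC.

The coefficient of variation of one feature across a cohort of plans is
``cv = sigma / |mu|`` with the sample (n-1) standard deviation — cohorts here
are small (4-11 plans), so the unbiased convention is used and recorded in
every report.  Features with ``cv < 0.3`` are classified stable /
reproducible; features with ``cv > 1`` (alternatively ``cv > 0.8``) are
classified sensitive.  Both inequalities are strict, and features with an
undefined cv (zero mean, too few values) belong to neither set but are always
enumerated.

Percentages of selected features are computed against the full registry size
(212 for the default registry), never against the defined-cv subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .features.extract import FeatureVector
from .features.registry import FeatureRegistry

SD_CONVENTION = "sample (n-1)"

FeatureKey = Tuple[str, str, str]  # (family, feature, aggregation)

STUDY_TAGS = ("reproducibility", "stability", "sensitivity_1mm", "sensitivity_2mm")


@dataclass
class FeatureTable:
    """(feature x plan) value matrix of one ROI in one study."""

    roi: str
    data: pd.DataFrame  # rows: (family, feature, aggregation); cols: plan labels
    study_tag: str = ""

    @classmethod
    def from_vectors(
        cls, roi: str, vectors: Mapping[str, FeatureVector], study_tag: str = ""
    ) -> "FeatureTable":
        data = pd.DataFrame({label: vec.to_series() for label, vec in vectors.items()})
        return cls(roi=roi, data=data, study_tag=study_tag)

    @property
    def n_plans(self) -> int:
        return self.data.shape[1]

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_values(self) -> int:
        return int(self.data.size)


# --------------------------------------------------------------------------
# Coefficient of variation
# --------------------------------------------------------------------------

@dataclass
class CvStats:
    mean: float
    sd: float
    cv: Optional[float]
    n_used: int
    flags: List[str] = field(default_factory=list)


def cv(values: Sequence[float]) -> CvStats:
    """CV of one feature across plans; missing (NaN) values are dropped."""
    x = np.asarray(values, dtype=np.float64)
    x = x[np.isfinite(x)]
    n = int(x.size)
    if n < 2:
        return CvStats(
            mean=float(x.mean()) if n else float("nan"),
            sd=float("nan"),
            cv=None,
            n_used=n,
            flags=["insufficient_n"],
        )
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if mean == 0.0:
        return CvStats(mean=mean, sd=sd, cv=None, n_used=n, flags=["undefined_mean_zero"])
    return CvStats(mean=mean, sd=sd, cv=sd / abs(mean), n_used=n, flags=[])


def feature_cv_table(table: FeatureTable) -> pd.DataFrame:
    """One CV record per registry feature of one ROI/study table.

    Columns: family, feature, aggregation, mean, sd, cv, n_used, flags;
    missing cells are dropped pairwise with ``n_used`` recording the count.
    """
    records = []
    for key, row in table.data.iterrows():
        stats = cv(row.to_numpy())
        records.append(
            {
                "roi": table.roi,
                "study": table.study_tag,
                "family": key[0],
                "feature": key[1],
                "aggregation": key[2],
                "mean": stats.mean,
                "sd": stats.sd,
                "cv": np.nan if stats.cv is None else stats.cv,
                "n_used": stats.n_used,
                "flags": ";".join(stats.flags),
                "sd_convention": SD_CONVENTION,
            }
        )
    return pd.DataFrame.from_records(records)


# --------------------------------------------------------------------------
# Threshold selection and set intersection
# --------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Stable / sensitive feature sets of one ROI in one study."""

    roi: str
    study: str
    registry_size: int
    stable_th: float
    stable: Set[FeatureKey]
    sensitive: Dict[float, Set[FeatureKey]]
    n_defined_cv: int

    def stable_percentage(self) -> float:
        return round(100.0 * len(self.stable) / self.registry_size, 1)

    def sensitive_percentage(self, th: float) -> float:
        return round(100.0 * len(self.sensitive[th]) / self.registry_size, 1)


def _keys(frame: pd.DataFrame) -> Set[FeatureKey]:
    return set(zip(frame["family"], frame["feature"], frame["aggregation"]))


def select_features(
    records: pd.DataFrame,
    stable_th: float = 0.3,
    sensitive_ths: Sequence[float] = (1.0, 0.8),
    registry_size: Optional[int] = None,
) -> SelectionResult:
    """Classify features by strict CV thresholds (cv < stable, cv > sensitive).

    Features with an undefined cv belong to no set.
    """
    if stable_th <= 0 or any(th <= 0 for th in sensitive_ths):
        raise ValueError("thresholds must be positive")
    defined = records[np.isfinite(records["cv"])]
    size = registry_size if registry_size is not None else len(records)
    return SelectionResult(
        roi=str(records["roi"].iloc[0]) if len(records) else "",
        study=str(records["study"].iloc[0]) if len(records) else "",
        registry_size=size,
        stable_th=stable_th,
        stable=_keys(defined[defined["cv"] < stable_th]),
        sensitive={th: _keys(defined[defined["cv"] > th]) for th in sensitive_ths},
        n_defined_cv=int(len(defined)),
    )


def common_features(
    set_a: Iterable[FeatureKey], set_b: Iterable[FeatureKey], registry_size: int
) -> Tuple[Set[FeatureKey], float]:
    """Intersection of two selection sets and its registry percentage."""
    common = set(set_a) & set(set_b)
    return common, round(100.0 * len(common) / registry_size, 1)


def intersection_summary(
    selections: Mapping[str, Mapping[str, SelectionResult]],
    sensitive_th: float = 1.0,
) -> pd.DataFrame:
    """Per-ROI percentages of common features between study pairs.

    ``selections`` maps roi -> study tag -> SelectionResult.  The four columns
    mirror the usual reporting layout: stable-set overlap between the
    reproducibility and stability studies, the overlap of the two
    sensitivity resolutions, and stability crossed with each resolution.
    """
    pairs = [
        ("reproducibility", "stable", "stability", "stable"),
        ("sensitivity_1mm", "sensitive", "sensitivity_2mm", "sensitive"),
        ("stability", "stable", "sensitivity_1mm", "sensitive"),
        ("stability", "stable", "sensitivity_2mm", "sensitive"),
    ]
    rows = {}
    for roi, by_study in selections.items():
        row = {}
        for study_a, kind_a, study_b, kind_b in pairs:
            if study_a not in by_study or study_b not in by_study:
                continue
            sel_a, sel_b = by_study[study_a], by_study[study_b]
            a = sel_a.stable if kind_a == "stable" else sel_a.sensitive[sensitive_th]
            b = sel_b.stable if kind_b == "stable" else sel_b.sensitive[sensitive_th]
            _, pct = common_features(a, b, sel_a.registry_size)
            row[f"{study_a}&{study_b}"] = pct
        rows[roi] = row
    return pd.DataFrame.from_dict(rows, orient="index")


# --------------------------------------------------------------------------
# Family summaries
# --------------------------------------------------------------------------

def family_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-family mean CV and box-plot statistics (Tukey 1.5 IQR whiskers).

    Undefined cvs are excluded from all statistics; their count is reported.
    Exports plotting data, not figures.
    """
    rows = []
    for family, group in records.groupby("family"):
        vals = group["cv"].to_numpy()
        defined = vals[np.isfinite(vals)]
        n_undefined = int(len(vals) - len(defined))
        if defined.size == 0:
            rows.append(
                {"family": family, "n_used": 0, "n_undefined": n_undefined, "empty": True}
            )
            continue
        q1, med, q3 = (float(v) for v in np.percentile(defined, [25, 50, 75]))
        iqr = q3 - q1
        in_lo = defined[defined >= q1 - 1.5 * iqr]
        in_hi = defined[defined <= q3 + 1.5 * iqr]
        rows.append(
            {
                "family": family,
                "mean_cv": float(defined.mean()),
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_low": float(in_lo.min()),
                "whisker_high": float(in_hi.max()),
                "n_used": int(defined.size),
                "n_undefined": n_undefined,
                "empty": False,
            }
        )
    return pd.DataFrame.from_records(rows).set_index("family")


# --------------------------------------------------------------------------
# Intraclass correlation
# --------------------------------------------------------------------------

@dataclass
class IccResult:
    icc: float
    var_subject: float
    var_rater: float
    var_residual: float
    model: str = "two-way random effects, absolute agreement, single rater"
    flags: List[str] = field(default_factory=list)


def icc(matrix: np.ndarray) -> IccResult:
    """ICC(2,1): subject variance over subject + rater + residual variance.

    ``matrix`` is subjects x raters, complete.  Variance components come from
    the two-way ANOVA mean squares; negative moment estimates are truncated
    at zero (flagged).
    """
    x = np.asarray(matrix, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a complete matrix with >= 2 subjects and >= 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("ICC requires a complete matrix")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        return IccResult(float("nan"), 0.0, 0.0, 0.0, flags=["zero_total_variance"])
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))

    flags = []
    var_subject = (msr - mse) / k
    var_rater = (msc - mse) / n
    if var_subject < 0 or var_rater < 0:
        flags.append("negative_component_truncated")
    var_subject = max(var_subject, 0.0)
    var_rater = max(var_rater, 0.0)
    total = var_subject + var_rater + mse
    value = var_subject / total if total > 0 else float("nan")
    return IccResult(float(value), float(var_subject), float(var_rater), float(mse), flags=flags)


# --------------------------------------------------------------------------
# Extraction comparison (software reproducibility)
# --------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    max_abs_diff: float
    n_compared: int
    per_feature: pd.Series
    mismatched: List[FeatureKey] = field(default_factory=list)  # NaN on one side only


def compare_extractions(table_a: FeatureTable, table_b: FeatureTable) -> ComparisonReport:
    """Elementwise differences between two extraction runs on the same cohort.

    The headline is the maximum absolute difference; cells undefined in both
    runs count as zero difference, cells undefined on one side only are
    reported as mismatches.
    """
    if not table_a.data.index.equals(table_b.data.index):
        raise ValueError("feature registries of the two tables differ")
    if list(table_a.data.columns) != list(table_b.data.columns):
        raise ValueError("plan columns of the two tables differ")
    a, b = table_a.data, table_b.data
    diff = (a - b).abs()
    both_nan = a.isna() & b.isna()
    diff = diff.mask(both_nan, 0.0)
    one_nan = a.isna() ^ b.isna()
    mismatched = [tuple(idx) for idx in diff.index[one_nan.any(axis=1)]]
    per_feature = diff.max(axis=1)
    max_abs = float(np.nanmax(per_feature.to_numpy())) if len(per_feature) else 0.0
    return ComparisonReport(
        max_abs_diff=max_abs,
        n_compared=int(a.size),
        per_feature=per_feature,
        mismatched=mismatched,
    )
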