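"""CV records, threshold selection, family summaries, ICC and comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dosetex.features import default_registry
from dosetex.features.extract import FeatureVector
from dosetex.variability import (
    FeatureTable,
    common_features,
    compare_extractions,
    cv,
    family_summary,
    feature_cv_table,
    icc,
    select_features,
)


class TestCv:
    def test_zero_spread(self):
        s = cv([5.0, 5.0, 5.0, 5.0])
        assert s.cv == 0.0
        assert s.n_used == 4

    def test_sample_sd_convention(self):
        s = cv([1.0, 2.0, 3.0, 4.0])
        assert s.mean == pytest.approx(2.5)
        assert s.sd == pytest.approx(np.sqrt(5.0 / 3.0))
        assert s.cv == pytest.approx(np.sqrt(5.0 / 3.0) / 2.5)  # ~0.5164
        assert s.cv == pytest.approx(0.5164, abs=5e-5)

    def test_zero_mean_flagged(self):
        s = cv([-2.0, 2.0])
        assert s.cv is None
        assert "undefined_mean_zero" in s.flags

    def test_insufficient_values_flagged(self):
        s = cv([3.0])
        assert s.cv is None
        assert "insufficient_n" in s.flags

    def test_missing_values_dropped_pairwise(self):
        s = cv([1.0, np.nan, 3.0, np.nan])
        assert s.n_used == 2
        assert s.mean == pytest.approx(2.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        c=st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False),
    )
    def test_scale_invariance(self, seed, c):
        rng = np.random.default_rng(seed)
        x = rng.uniform(1.0, 10.0, size=6)
        assert cv(c * x).cv == pytest.approx(cv(x).cv, rel=1e-9)


def _table(values_by_plan, roi="PTV", tag="stability"):
    reg = default_registry()
    vectors = {
        plan: FeatureVector(values=dict(zip(reg.feature_ids, vals)))
        for plan, vals in values_by_plan.items()
    }
    return FeatureTable.from_vectors(roi, vectors, study_tag=tag)


class TestFeatureCvTable:
    def test_one_record_per_registry_feature(self, small_structs, small_plan):
        from dosetex.features import extract_all
        from dosetex.synthetic import PlanSimSpec, simulate_plan

        vectors = {}
        for seed in (1, 2, 3, 4):
            plan = simulate_plan(small_structs, PlanSimSpec(seed=seed, noise_lattice_mm=3.0))
            vectors[f"P{seed}"] = extract_all(plan, small_structs, rois=("PTV",)).features["PTV"]
        table = FeatureTable.from_vectors("PTV", vectors, "reproducibility")
        records = feature_cv_table(table)
        assert len(records) == 212
        assert (records["n_used"] <= 4).all()

    def test_constant_feature_is_stable(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 5, 212)
        table = _table({f"P{k}": base for k in range(4)})
        records = feature_cv_table(table)
        assert (records["cv"] == 0.0).all()
        sel = select_features(records, registry_size=212)
        assert len(sel.stable) == 212

    def test_duplicating_columns_matches_exact_recomputation(self):
        rng = np.random.default_rng(1)
        vals = {f"P{k}": rng.uniform(1, 5, 212) for k in range(3)}
        table = _table(vals)
        dup = _table({**vals, **{f"Q{k}": v for k, v in enumerate(vals.values())}})
        rec, rec_dup = feature_cv_table(table), feature_cv_table(dup)
        # oracle: exact recomputation with numpy on the duplicated sample
        for row, row_dup in zip(rec.itertuples(), rec_dup.itertuples()):
            x = np.array([vals[f"P{k}"][row.Index] for k in range(3)] * 2)
            assert row_dup.cv == pytest.approx(x.std(ddof=1) / abs(x.mean()), rel=1e-12)
            assert row_dup.mean == pytest.approx(row.mean, rel=1e-12)


class TestSelection:
    def _records(self, cvs):
        return pd.DataFrame(
            {
                "roi": "PTV",
                "study": "stability",
                "family": "STAT",
                "feature": [f"f{k}" for k in range(len(cvs))],
                "aggregation": "none",
                "cv": cvs,
            }
        )

    def test_strict_thresholds(self):
        records = self._records([0.2, 0.3, 0.31, 1.0, 1.01])
        sel = select_features(records, stable_th=0.3, sensitive_ths=(1.0,), registry_size=5)
        names = {k[1] for k in sel.stable}
        assert names == {"f0"}  # cv = 0.3 is not < 0.3
        assert {k[1] for k in sel.sensitive[1.0]} == {"f4"}  # cv = 1.0 is not > 1.0

    def test_undefined_cv_in_neither_set(self):
        records = self._records([0.1, np.nan, 2.0])
        sel = select_features(records, registry_size=3)
        assert sel.n_defined_cv == 2
        all_selected = sel.stable | sel.sensitive[1.0]
        assert ("STAT", "f1", "none") not in all_selected

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        records = self._records(rng.uniform(0, 2, 100))
        lo = select_features(records, stable_th=0.2, sensitive_ths=(0.8,), registry_size=100)
        hi = select_features(records, stable_th=0.5, sensitive_ths=(1.2,), registry_size=100)
        assert lo.stable <= hi.stable
        assert hi.sensitive[1.2] <= lo.sensitive[0.8]

    def test_percentage_uses_registry_denominator(self):
        a = {("STAT", f"f{k}", "none") for k in range(200)}
        b = {("STAT", f"f{k}", "none") for k in range(66, 300)}
        common, pct = common_features(a, b, registry_size=212)
        assert len(common) == 134
        assert pct == 63.2  # 134/212, one decimal

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            select_features(self._records([0.1]), stable_th=0.0)


class TestFamilySummary:
    def test_single_family_mean(self):
        records = pd.DataFrame(
            {"family": ["STAT", "STAT"], "cv": [0.1, 0.3]}
        )
        fs = family_summary(records)
        assert fs.loc["STAT", "mean_cv"] == pytest.approx(0.2)
        assert fs.loc["STAT", "n_used"] == 2

    def test_median_matches_sorted_middle_oracle(self):
        rng = np.random.default_rng(2)
        cvs = rng.uniform(0, 2, 31)
        records = pd.DataFrame({"family": "GLCM", "cv": cvs})
        fs = family_summary(records)
        assert fs.loc["GLCM", "median"] == sorted(cvs)[15]

    def test_undefined_cvs_excluded_but_counted(self):
        records = pd.DataFrame({"family": "GLRLM", "cv": [0.5, np.nan, np.nan]})
        fs = family_summary(records)
        assert fs.loc["GLRLM", "mean_cv"] == pytest.approx(0.5)
        assert fs.loc["GLRLM", "n_undefined"] == 2

    def test_all_undefined_family_flagged_empty(self):
        records = pd.DataFrame({"family": "GLSZM", "cv": [np.nan, np.nan]})
        fs = family_summary(records)
        assert bool(fs.loc["GLSZM", "empty"])


class TestIcc:
    def test_identical_raters_perfect_agreement(self):
        res = icc(np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]))
        assert res.icc == pytest.approx(1.0)
        assert res.var_rater == pytest.approx(0.0)
        assert res.var_residual == pytest.approx(0.0)

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(10, 3, size=(4, 3)) + rng.normal(0, 1, size=(4, 1))
        res = icc(x)
        # independent oracle: explicit two-way ANOVA decomposition
        n, k = x.shape
        gm = x.mean()
        msr = k * ((x.mean(1) - gm) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(0) - gm) ** 2).sum() / (k - 1)
        sse = ((x - x.mean(1, keepdims=True) - x.mean(0, keepdims=True) + gm) ** 2).sum()
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert res.icc == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin_icc2(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        subject_effect = rng.normal(0, 5, size=(6, 1))
        x = 20 + subject_effect + rng.normal(0, 1, size=(6, 4))
        res = icc(x)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(6), 4),
                "rater": np.tile(np.arange(4), 6),
                "score": x.ravel(),
            }
        )
        table = pg.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="score"
        )
        # two-way random, absolute agreement, single rater: ICC2 / ICC(A,1)
        types = table.set_index("Type")["ICC"]
        icc2 = float(types.get("ICC2", types.get("ICC(A,1)")))
        assert res.icc == pytest.approx(icc2, abs=1e-10)

    def test_zero_total_variance_flagged(self):
        res = icc(np.full((3, 3), 4.0))
        assert np.isnan(res.icc)
        assert "zero_total_variance" in res.flags

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            icc(np.array([[1.0, 2.0]]))
        with pytest.raises(ValueError):
            icc(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestCompareExtractions:
    def _tables(self):
        rng = np.random.default_rng(3)
        vals = {f"P{k}": rng.uniform(0, 10, 212) for k in range(4)}
        return _table(vals), vals

    def test_identical_tables_zero_difference(self):
        a, vals = self._tables()
        b = _table(vals)
        report = compare_extractions(a, b)
        assert report.max_abs_diff == 0.0
        assert report.n_compared == 212 * 4

    def test_single_perturbed_cell_localised(self):
        a, vals = self._tables()
        vals2 = {k: v.copy() for k, v in vals.items()}
        vals2["P2"][17] += 0.5
        b = _table(vals2)
        report = compare_extractions(a, b)
        assert report.max_abs_diff == pytest.approx(0.5)
        nonzero = report.per_feature[report.per_feature > 0]
        assert len(nonzero) == 1
        assert nonzero.index[0] == a.data.index[17]

    def test_mismatched_registries_rejected(self):
        a, vals = self._tables()
        smaller = default_registry().feature_ids[:100]
        b_vec = {
            plan: FeatureVector(values=dict(zip(smaller, v[:100])))
            for plan, v in vals.items()
        }
        b = FeatureTable.from_vectors("PTV", b_vec, "stability")
        with pytest.raises(ValueError, match="registries"):
            compare_extractions(a, b)
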