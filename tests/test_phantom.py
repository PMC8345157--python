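"""Phantom geometry, ring/PRV expansions, plan simulation and DVH QA."""

import numpy as np
import pytest
from scipy import ndimage

from dosetex.core import Grid, DoseGrid, RoiMask, STRUCTURE_NAMES
from dosetex.synthetic import (
    GeometryError,
    PhantomSpec,
    PlanSimSpec,
    build_phantom,
    check_constraints,
    generate_cohort,
    make_ring,
    simulate_plan,
)

from conftest import SMALL_SPEC


class TestBuildPhantom:
    def test_structure_set_is_complete_and_consistent(self, default_structs):
        assert set(default_structs.names) == set(STRUCTURE_NAMES)
        shape = default_structs.reference_grid.shape
        for name in default_structs.names:
            roi = default_structs[name]
            assert roi.mask.shape == shape
            assert roi.n_voxels >= 2

    def test_ptv_ring_disjoint_and_prv_superset(self, default_structs):
        assert not np.any(default_structs["PTV"].mask & default_structs["RING"].mask)
        sc = default_structs["spinal_canal"].mask
        prv = default_structs["PRV_SC"].mask
        assert np.all(prv[sc])
        assert prv.sum() > sc.sum()

    def test_prv_is_4mm_euclidean_dilation(self, default_structs):
        # independent oracle: dilation with an explicit Euclidean ball (<= 4 mm
        # at 2 mm isotropic spacing = 2 voxels along the axes)
        sc = default_structs["spinal_canal"].mask
        spacing = default_structs.reference_grid.spacing_mm
        r = 4.0
        half = [int(np.floor(r / s)) for s in spacing]
        zz, yy, xx = np.mgrid[
            -half[0] : half[0] + 1, -half[1] : half[1] + 1, -half[2] : half[2] + 1
        ]
        ball = (
            (zz * spacing[0]) ** 2 + (yy * spacing[1]) ** 2 + (xx * spacing[2]) ** 2
        ) <= r**2
        expected = ndimage.binary_dilation(sc, structure=ball)
        np.testing.assert_array_equal(default_structs["PRV_SC"].mask, expected)

    def test_too_coarse_spacing_rejected(self):
        with pytest.raises(GeometryError):
            build_phantom(PhantomSpec(scale_factor=0.2, voxel_spacing_mm=(12.0, 12.0, 12.0)))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(scale_factor=0.0)
        with pytest.raises(ValueError):
            PhantomSpec(insert_densities={"lung": 0.25})


class TestMakeRing:
    def _single_voxel_ptv(self, n=9):
        mask = np.zeros((n, n, n), dtype=bool)
        mask[n // 2, n // 2, n // 2] = True
        grid = Grid(shape=(n, n, n), spacing_mm=(1.0, 1.0, 1.0))
        return RoiMask(mask=mask, roi_name="PTV", grid=grid)

    def test_single_voxel_ring_is_euclidean_shell(self):
        ptv = self._single_voxel_ptv()
        ring = make_ring(ptv, expansion_mm=2.0, crop_mm=0.0)
        c = 4
        zz, yy, xx = np.mgrid[-c : c + 1, -c : c + 1, -c : c + 1]
        expected = (zz**2 + yy**2 + xx**2 <= 4.0) & ~(
            (zz == 0) & (yy == 0) & (xx == 0)
        )
        np.testing.assert_array_equal(ring.mask, expected)
        assert not np.any(ring.mask & ptv.mask)

    def test_zero_crop_union_identity(self, default_structs):
        from dosetex.synthetic import dilate_mm

        ptv = default_structs["PTV"]
        ring = make_ring(ptv, expansion_mm=10.0, crop_mm=0.0)
        union = ring.mask | ptv.mask
        np.testing.assert_array_equal(
            union, dilate_mm(ptv.mask, 10.0, ptv.grid.spacing_mm)
        )

    def test_ring_lies_in_gradient_region(self, default_structs, default_plan):
        ptv = default_structs["PTV"].mask
        ring = default_structs["RING"].mask
        far = ~ptv & ~ring
        d = default_plan.values
        assert far.sum() > 0
        assert d[far].mean() < d[ring].mean() < d[ptv].mean()

    def test_errors(self, default_structs):
        ptv = default_structs["PTV"]
        empty = RoiMask(np.zeros_like(ptv.mask), "PTV", ptv.grid)
        with pytest.raises(GeometryError):
            make_ring(empty, 10.0, 0.0)
        with pytest.raises(GeometryError):
            make_ring(ptv, 0.5, 0.0)  # below one voxel
        with pytest.raises(ValueError):
            make_ring(ptv, 5.0, 5.0)


class TestSimulatePlan:
    def test_seeded_determinism(self, small_structs):
        spec = PlanSimSpec(seed=11, noise_lattice_mm=3.0)
        a = simulate_plan(small_structs, spec)
        b = simulate_plan(small_structs, spec)
        np.testing.assert_array_equal(a.values, b.values)

    def test_zero_noise_determinism(self, small_structs):
        spec = PlanSimSpec(seed=1, noise_sd_Gy=0.0)
        a = simulate_plan(small_structs, spec)
        b = simulate_plan(small_structs, PlanSimSpec(seed=2, noise_sd_Gy=0.0))
        np.testing.assert_array_equal(a.values, b.values)  # noise-free = seed-free

    def test_ptv_mean_near_prescription(self, default_structs, default_plan):
        mean = default_plan.values[default_structs["PTV"].mask].mean()
        assert abs(mean - 66.0) / 66.0 < 0.02

    def test_doses_finite_nonnegative(self, default_plan):
        assert np.all(np.isfinite(default_plan.values))
        assert np.all(default_plan.values >= 0)

    def test_techniques_differ_in_ring_dose(self, small_structs):
        ring = small_structs["RING"].mask
        a = simulate_plan(small_structs, PlanSimSpec(seed=3, technique_id="IMPT_MC", noise_sd_Gy=0))
        b = simulate_plan(small_structs, PlanSimSpec(seed=3, technique_id="TOMO", noise_sd_Gy=0))
        assert a.values[ring].mean() != pytest.approx(b.values[ring].mean())
        # steeper fall-off => lower dose in the gradient shell
        assert a.values[ring].mean() < b.values[ring].mean()


class TestGenerateCohort:
    def test_cohort_sizes(self):
        repro = generate_cohort(SMALL_SPEC, "reproducibility", base_seed=5)
        stab = generate_cohort(SMALL_SPEC, "stability", base_seed=5)
        sens = generate_cohort(SMALL_SPEC, "sensitivity", base_seed=5)
        assert len(repro.plans) == 4
        assert len(stab.plans) == 8
        assert len(sens.plans) == 22
        assert len({p.label for p in sens.plans}) == 11
        assert len(sens.resolutions) == 2

    def test_reproducibility_is_stability_subset(self):
        repro = generate_cohort(SMALL_SPEC, "reproducibility", base_seed=5)
        stab = generate_cohort(SMALL_SPEC, "stability", base_seed=5)
        for pr, ps in zip(repro.plans, stab.plans[:4]):
            assert pr.label == ps.label
            np.testing.assert_array_equal(pr.dose.values, ps.dose.values)

    def test_sensitivity_uses_multiple_techniques(self):
        sens = generate_cohort(SMALL_SPEC, "sensitivity", base_seed=5)
        assert len({p.technique_id for p in sens.plans}) >= 4

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError, match="unknown design"):
            generate_cohort(SMALL_SPEC, "robustness", base_seed=5)

    def test_generated_plans_pass_qa(self):
        stab = generate_cohort(SMALL_SPEC, "stability", base_seed=5)
        for plan in stab.plans:
            report = check_constraints(plan.dose, stab.structures[plan.resolution_mm])
            assert report.all_pass, [
                (r.structure, r.metric, r.value) for r in report.failures()
            ]


class TestCheckConstraints:
    def test_uniform_prescription_passes_ptv(self, small_structs):
        values = np.zeros(small_structs.reference_grid.shape)
        values[small_structs["PTV"].mask] = 66.0
        dose = DoseGrid(values=values, grid=small_structs.reference_grid)
        report = check_constraints(dose, small_structs, prescription_Gy=66.0)
        by = {(r.structure, r.metric): r for r in report.records}
        assert by[("PTV", "D98%")].value == pytest.approx(66.0)
        assert by[("PTV", "D98%")].passed
        assert by[("PTV", "V105%")].value == 0.0
        assert by[("PTV", "V105%")].passed

    def test_zero_dose_fails_only_ptv_coverage(self, small_structs):
        dose = DoseGrid(
            values=np.zeros(small_structs.reference_grid.shape),
            grid=small_structs.reference_grid,
        )
        report = check_constraints(dose, small_structs)
        for rec in report.records:
            if (rec.structure, rec.metric) == ("PTV", "D98%"):
                assert not rec.passed
            elif rec.metric in ("Dmax", "Dmean", "V105%"):
                assert rec.passed

    @pytest.mark.parametrize("dmax,expected", [(44.9, True), (45.1, False)])
    def test_spinal_canal_dmax_strict_threshold(self, small_structs, dmax, expected):
        values = np.zeros(small_structs.reference_grid.shape)
        sc = small_structs["spinal_canal"].mask
        values[sc] = dmax
        values[small_structs["PTV"].mask] = 66.0
        dose = DoseGrid(values=values, grid=small_structs.reference_grid)
        report = check_constraints(dose, small_structs)
        rec = next(
            r for r in report.records if (r.structure, r.metric) == ("spinal_canal", "Dmax")
        )
        assert rec.value == pytest.approx(dmax)
        assert rec.passed is expected

    def test_empty_roi_yields_error_record(self, small_structs):
        import copy

        structs = copy.deepcopy(small_structs)
        del structs.rois["trachea"]
        dose = DoseGrid(
            values=np.full(structs.reference_grid.shape, 10.0),
            grid=structs.reference_grid,
        )
        report = check_constraints(dose, structs)
        rec = next(r for r in report.records if r.structure == "trachea")
        assert rec.error is not None
        assert not rec.passed
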