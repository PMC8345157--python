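"""Synthetic phantom, structure set and dose-cohort generator.

The module emulates the data-generating conditions of a multicentre
head-and-neck phantom study: a cylindrical phantom with four density inserts,
seven contoured structures (PTV, both parotids, spinal canal, its 4 mm PRV
expansion, trachea and a 3 cm RING around the PTV), and cohorts of dose
distributions prescribed 66 Gy to the PTV.

Dose is modelled as a sum of separable smooth fields — a prescription plateau
inside the PTV, an exponential radial fall-off outside it, multiplicative
organ-at-risk sparing wells and spatially correlated Gaussian noise — rather
than by beam transport.  Only the statistical structure of the dose (plateau,
gradient, correlated texture) matters for feature-variability analysis, and
this model reproduces it at a small fraction of the cost.

Three cohort designs are provided:

``reproducibility``
    4 plans, one technique kernel, identical settings, noise only.
``stability``
    8 plans sharing the delivery-technique family; the first four are exactly
    the reproducibility plans, the other four add per-plan jitter of the
    fall-off scale and sparing strengths (different machine generations).
``sensitivity``
    11 plans drawn from six distinct technique kernels, each rendered at a
    fine and a coarse dose-grid resolution (22 dose grids).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import Grid, DoseGrid, RoiMask, StructureSet, STRUCTURE_NAMES


class GeometryError(ValueError):
    """Raised when the requested phantom geometry cannot be rasterised."""


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------

#: Relative electron densities of the four rectangular phantom inserts.
DEFAULT_INSERT_DENSITIES = {
    "lung": 0.25,
    "bone": 1.60,
    "muscle": 1.05,
    "adipose": 0.92,
}

PMMA_DENSITY = 1.19


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the synthetic cylindrical phantom.

    ``scale_factor`` shrinks the phantom body and the ROI solids uniformly so a
    full cohort runs quickly; clinical margins (``prv_margin_mm``,
    ``ring_expansion_mm``) and the dose-model length scales stay in absolute
    millimetres because margins are absolute quantities, not anatomy.
    """

    cylinder_radius_mm: float = 100.0
    cylinder_length_mm: float = 160.0
    voxel_spacing_mm: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    insert_densities: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INSERT_DENSITIES)
    )
    scale_factor: float = 0.5
    prv_margin_mm: float = 4.0
    ring_expansion_mm: float = 30.0
    ring_crop_mm: float = 0.0
    padding_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.cylinder_radius_mm <= 0 or self.cylinder_length_mm <= 0:
            raise ValueError("cylinder dimensions must be positive")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if not (0.0 < self.scale_factor <= 1.0):
            raise ValueError("scale_factor must be in (0, 1]")
        missing = set(DEFAULT_INSERT_DENSITIES) - set(self.insert_densities)
        if missing:
            raise ValueError(f"missing insert densities: {sorted(missing)}")

    def with_spacing(self, spacing_mm: float | Tuple[float, float, float]) -> "PhantomSpec":
        if np.isscalar(spacing_mm):
            spacing_mm = (float(spacing_mm),) * 3  # type: ignore[assignment]
        return replace(self, voxel_spacing_mm=tuple(spacing_mm))  # type: ignore[arg-type]


# Full-scale ROI geometry in mm, (z, y, x) order; y grows posteriorly, the
# PTV sits laterally (mono-lateral design) abutting the right parotid.
_PTV_CENTRE = (0.0, 0.0, 25.0)
_PTV_SEMI = (40.0, 35.0, 30.0)
_PAROTID_SEMI = (25.0, 20.0, 15.0)
_PAROTID_R_CENTRE = (0.0, 0.0, 75.0)
_PAROTID_L_CENTRE = (0.0, 0.0, -75.0)
_SPINAL_CANAL = {"centre_yx": (55.0, 0.0), "radius": 8.0, "z_fraction": 0.9}
_TRACHEA = {"centre_yx": (-50.0, 0.0), "radius": 10.0, "z_fraction": 0.8}
_INSERT_GEOMETRY = {  # (y, x) centre and (z, y, x) half-size, full scale mm
    "lung": ((-40.0, -40.0), (60.0, 12.0, 12.0)),
    "bone": ((40.0, -40.0), (60.0, 12.0, 12.0)),
    "muscle": ((40.0, 40.0), (60.0, 12.0, 12.0)),
    "adipose": ((-40.0, 40.0), (60.0, 12.0, 12.0)),
}


def _centred_grid(spec: PhantomSpec) -> Grid:
    s = spec.scale_factor
    half = (
        spec.cylinder_length_mm * s / 2 + spec.padding_mm,
        spec.cylinder_radius_mm * s + spec.padding_mm,
        spec.cylinder_radius_mm * s + spec.padding_mm,
    )
    shape = tuple(max(2, int(math.ceil(2 * h / sp))) for h, sp in zip(half, spec.voxel_spacing_mm))
    origin = tuple(-(n - 1) / 2 * sp for n, sp in zip(shape, spec.voxel_spacing_mm))
    return Grid(shape=shape, spacing_mm=tuple(spec.voxel_spacing_mm), origin_mm=origin)


def _ellipsoid(grid: Grid, centre: Sequence[float], semi: Sequence[float]) -> np.ndarray:
    z, y, x = grid.coordinate_arrays()
    return (
        ((z - centre[0]) / semi[0]) ** 2
        + ((y - centre[1]) / semi[1]) ** 2
        + ((x - centre[2]) / semi[2]) ** 2
    ) <= 1.0


def _zcylinder(grid: Grid, centre_yx: Sequence[float], radius: float, half_len: float) -> np.ndarray:
    z, y, x = grid.coordinate_arrays()
    return (
        ((y - centre_yx[0]) ** 2 + (x - centre_yx[1]) ** 2 <= radius**2)
        & (np.abs(z) <= half_len)
    )


def dilate_mm(mask: np.ndarray, distance_mm: float, spacing_mm: Sequence[float]) -> np.ndarray:
    """Isotropic dilation by thresholding the Euclidean distance transform."""
    if distance_mm <= 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing_mm)
    return dist <= distance_mm


def make_ring(ptv: RoiMask, expansion_mm: float, crop_mm: float = 0.0) -> RoiMask:
    """Shell from ``crop_mm`` to ``expansion_mm`` outside the PTV surface.

    With ``crop_mm = 0`` the ring abuts the PTV and contains no PTV voxel, and
    ``ring | ptv == dilate(ptv, expansion_mm)`` exactly.
    """
    if ptv.n_voxels == 0:
        raise GeometryError("cannot build a ring around an empty PTV")
    if not (expansion_mm > crop_mm >= 0):
        raise ValueError("require expansion_mm > crop_mm >= 0")
    if expansion_mm < min(ptv.grid.spacing_mm):
        raise GeometryError(
            f"ring expansion {expansion_mm} mm is smaller than one voxel "
            f"(spacing {ptv.grid.spacing_mm})"
        )
    outer = dilate_mm(ptv.mask, expansion_mm, ptv.grid.spacing_mm)
    inner = dilate_mm(ptv.mask, crop_mm, ptv.grid.spacing_mm)
    return RoiMask(mask=outer & ~inner, roi_name="RING", grid=ptv.grid)


def build_phantom(spec: PhantomSpec = PhantomSpec()) -> Tuple[np.ndarray, StructureSet]:
    """Rasterise the phantom density grid and its seven-structure set."""
    grid = _centred_grid(spec)
    s = spec.scale_factor
    sp = grid.spacing_mm
    z, y, x = grid.coordinate_arrays()

    body = (
        (y**2 + x**2 <= (spec.cylinder_radius_mm * s) ** 2)
        & (np.abs(z) <= spec.cylinder_length_mm * s / 2)
    )
    density = np.where(body, PMMA_DENSITY, 0.0)
    for name, ((cy, cx), (hz, hy, hx)) in _INSERT_GEOMETRY.items():
        box = (
            (np.abs(z) <= hz * s)
            & (np.abs(y - cy * s) <= hy * s)
            & (np.abs(x - cx * s) <= hx * s)
        )
        density = np.where(box & body, spec.insert_densities[name], density)

    def scaled(v: Sequence[float]) -> Tuple[float, ...]:
        return tuple(c * s for c in v)

    rois: Dict[str, RoiMask] = {}
    rois["PTV"] = RoiMask(_ellipsoid(grid, scaled(_PTV_CENTRE), scaled(_PTV_SEMI)), "PTV", grid)
    rois["parotid_R"] = RoiMask(
        _ellipsoid(grid, scaled(_PAROTID_R_CENTRE), scaled(_PAROTID_SEMI)), "parotid_R", grid
    )
    rois["parotid_L"] = RoiMask(
        _ellipsoid(grid, scaled(_PAROTID_L_CENTRE), scaled(_PAROTID_SEMI)), "parotid_L", grid
    )
    sc = _zcylinder(
        grid,
        scaled(_SPINAL_CANAL["centre_yx"]),
        _SPINAL_CANAL["radius"] * s,
        spec.cylinder_length_mm * s / 2 * _SPINAL_CANAL["z_fraction"],
    )
    rois["spinal_canal"] = RoiMask(sc, "spinal_canal", grid)
    rois["PRV_SC"] = RoiMask(dilate_mm(sc, spec.prv_margin_mm, sp), "PRV_SC", grid)
    rois["trachea"] = RoiMask(
        _zcylinder(
            grid,
            scaled(_TRACHEA["centre_yx"]),
            _TRACHEA["radius"] * s,
            spec.cylinder_length_mm * s / 2 * _TRACHEA["z_fraction"],
        ),
        "trachea",
        grid,
    )
    rois["RING"] = make_ring(rois["PTV"], spec.ring_expansion_mm, spec.ring_crop_mm)
    # keep the ring inside the phantom body
    rois["RING"] = RoiMask(rois["RING"].mask & body, "RING", grid)

    for name in STRUCTURE_NAMES:
        if rois[name].n_voxels < 2:
            raise GeometryError(
                f"ROI {name!r} has {rois[name].n_voxels} voxels at spacing {sp}; "
                "refine the grid or increase scale_factor"
            )
    structs = StructureSet(reference_grid=grid, rois=rois)
    structs.validate_synthetic()
    return density, structs


# --------------------------------------------------------------------------
# Plan simulation
# --------------------------------------------------------------------------

#: Technique kernels: fall-off scale, texture correlation length and a global
#: multiplier on the organ-at-risk sparing strengths.  The ids mimic the mix of
#: delivery techniques / dose engines found across centres.
TECHNIQUES: Dict[str, Dict[str, float]] = {
    "IMRT_AAA": {"gradient_scale_mm": 12.0, "texture_corr_len_mm": 8.0, "sparing_scale": 1.00},
    "VMAT_AAA": {"gradient_scale_mm": 10.0, "texture_corr_len_mm": 7.0, "sparing_scale": 1.05},
    "VMAT_Acuros": {"gradient_scale_mm": 11.0, "texture_corr_len_mm": 6.0, "sparing_scale": 0.95},
    "VMAT_CC": {"gradient_scale_mm": 13.0, "texture_corr_len_mm": 9.0, "sparing_scale": 1.10},
    "TOMO": {"gradient_scale_mm": 15.0, "texture_corr_len_mm": 10.0, "sparing_scale": 0.90},
    "IMPT_MC": {"gradient_scale_mm": 7.0, "texture_corr_len_mm": 5.0, "sparing_scale": 1.00},
}

#: Organ-at-risk sparing wells: (strength in [0, 1), Gaussian width in mm).
DEFAULT_SPARING: Dict[str, Tuple[float, float]] = {
    "parotid_R": (0.60, 10.0),
    "parotid_L": (0.30, 10.0),
    "spinal_canal": (0.50, 8.0),
    "trachea": (0.50, 8.0),
}


@dataclass(frozen=True)
class PlanSimSpec:
    """Settings of one simulated plan."""

    prescription_Gy: float = 66.0
    fraction_dose_Gy: float = 2.2
    technique_id: str = "IMRT_AAA"
    gradient_scale_mm: Optional[float] = None  # None -> technique default
    noise_sd_Gy: float = 0.5
    texture_corr_len_mm: Optional[float] = None  # None -> technique default
    grid_resolution_mm: Optional[float] = None  # None -> structure-set grid
    sparing_jitter: Dict[str, float] = field(default_factory=dict)
    noise_lattice_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prescription_Gy <= 0:
            raise ValueError("prescription must be positive")
        if self.noise_sd_Gy < 0:
            raise ValueError("noise_sd_Gy must be non-negative")
        if self.technique_id not in TECHNIQUES:
            raise ValueError(f"unknown technique_id {self.technique_id!r}")

    @property
    def effective_gradient_scale_mm(self) -> float:
        return (
            self.gradient_scale_mm
            if self.gradient_scale_mm is not None
            else TECHNIQUES[self.technique_id]["gradient_scale_mm"]
        )

    @property
    def effective_corr_len_mm(self) -> float:
        return (
            self.texture_corr_len_mm
            if self.texture_corr_len_mm is not None
            else TECHNIQUES[self.technique_id]["texture_corr_len_mm"]
        )


def _correlated_noise(grid: Grid, spec: PlanSimSpec) -> np.ndarray:
    """Correlated Gaussian noise sampled from a canonical fine lattice.

    The white-noise draw lives on a fixed lattice (``noise_lattice_mm``) so the
    same plan rendered at different grid resolutions sees one underlying
    perturbation, sampled rather than redrawn.
    """
    if spec.noise_sd_Gy == 0:
        return np.zeros(grid.shape)
    lat = spec.noise_lattice_mm
    # lattice covering the grid extent, anchored at the grid origin
    extent = [o + (n - 1) * s for o, n, s in zip(grid.origin_mm, grid.shape, grid.spacing_mm)]
    shape = [int(math.floor((e - o) / lat)) + 2 for o, e in zip(grid.origin_mm, extent)]
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal(shape)
    sigma_vox = spec.effective_corr_len_mm / lat
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(grid.shape)
    smooth *= spec.noise_sd_Gy / sd
    # trilinear sampling of the lattice at the grid voxel centres
    coords = np.meshgrid(
        *[(grid.voxel_centres(a) - grid.origin_mm[a]) / lat for a in range(3)],
        indexing="ij",
    )
    return ndimage.map_coordinates(smooth, coords, order=1, mode="nearest")


def simulate_plan(structs: StructureSet, spec: PlanSimSpec) -> DoseGrid:
    """Render one synthetic dose distribution on the structure-set grid.

    Deterministic in ``spec.seed``; all doses are finite and >= 0.
    """
    grid = structs.reference_grid
    sp = grid.spacing_mm
    ptv = structs["PTV"].mask
    g = spec.effective_gradient_scale_mm
    sparing_scale = TECHNIQUES[spec.technique_id]["sparing_scale"]

    dist_out = ndimage.distance_transform_edt(~ptv, sampling=sp)
    dose = spec.prescription_Gy * np.exp(-dist_out / g)

    sparing = np.ones(grid.shape)
    for oar, (strength, width) in DEFAULT_SPARING.items():
        if oar not in structs:
            continue
        a = strength * sparing_scale * (1.0 + spec.sparing_jitter.get(oar, 0.0))
        a = min(max(a, 0.0), 0.95)
        d_oar = ndimage.distance_transform_edt(~structs[oar].mask, sampling=sp)
        sparing *= 1.0 - a * np.exp(-(d_oar**2) / (2.0 * width**2))
    dose = np.where(ptv, spec.prescription_Gy, dose * sparing)

    dose = dose + _correlated_noise(grid, spec)
    np.clip(dose, 0.0, None, out=dose)
    return DoseGrid(values=dose, grid=grid)


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

DESIGNS = ("reproducibility", "stability", "sensitivity")

#: Technique assignment of the 11 sensitivity plans (6 distinct kernels).
SENSITIVITY_TECHNIQUES = (
    "IMRT_AAA",
    "VMAT_AAA",
    "VMAT_Acuros",
    "VMAT_CC",
    "TOMO",
    "IMPT_MC",
    "VMAT_AAA",
    "VMAT_CC",
    "TOMO",
    "IMPT_MC",
    "VMAT_Acuros",
)

REPRODUCIBILITY_NOISE_SD = 0.4
SENSITIVITY_NOISE_SD = 0.8
STABILITY_JITTER = 0.15  # relative jitter of the fall-off scale, plans 5-8
COARSE_FACTOR = 2.0  # coarse resolution = fine spacing x 2


@dataclass
class PlanRecord:
    label: str
    technique_id: str
    resolution_mm: float
    seed: int
    spec: PlanSimSpec
    dose: DoseGrid


@dataclass
class Cohort:
    design: str
    phantom_spec: PhantomSpec
    structures: Dict[float, StructureSet]  # resolution (mm, z-spacing) -> set
    plans: List[PlanRecord]

    def plans_at(self, resolution_mm: float) -> List[PlanRecord]:
        return [p for p in self.plans if p.resolution_mm == resolution_mm]

    @property
    def resolutions(self) -> Tuple[float, ...]:
        return tuple(sorted(self.structures))


def _plan_seed(base_seed: int, plan_index: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(plan_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    phantom: PhantomSpec,
    design: str,
    base_seed: int,
    noise_scale: float = 1.0,
    structs: Optional[StructureSet] = None,
) -> Cohort:
    """Generate one study cohort of synthetic dose distributions.

    ``noise_scale`` multiplies every plan's ``noise_sd_Gy`` (used by
    perturbation-sensitivity checks); 1.0 gives the study conditions.
    A prebuilt ``structs`` may be supplied for the single-resolution designs.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")

    fine = float(phantom.voxel_spacing_mm[0])
    if structs is None:
        _, structs = build_phantom(phantom)
    structures = {fine: structs}
    plans: List[PlanRecord] = []

    if design in ("reproducibility", "stability"):
        n = 4 if design == "reproducibility" else 8
        jitter_rng = np.random.default_rng(np.random.SeedSequence([int(base_seed), 9001]))
        for i in range(8):
            # jitter draws advance for all 8 indices so the first four plans
            # are bit-identical between the two designs
            g_jit = float(jitter_rng.uniform(-STABILITY_JITTER, STABILITY_JITTER))
            s_jit = {
                oar: float(jitter_rng.uniform(-0.10, 0.10)) for oar in DEFAULT_SPARING
            }
            if i >= n:
                continue
            base_g = TECHNIQUES["IMRT_AAA"]["gradient_scale_mm"]
            spec = PlanSimSpec(
                technique_id="IMRT_AAA",
                gradient_scale_mm=base_g * (1.0 + g_jit) if i >= 4 else None,
                sparing_jitter=s_jit if i >= 4 else {},
                noise_sd_Gy=REPRODUCIBILITY_NOISE_SD * noise_scale,
                noise_lattice_mm=fine,
                seed=_plan_seed(base_seed, i),
            )
            dose = simulate_plan(structs, spec)
            plans.append(
                PlanRecord(f"S{i + 1:02d}", spec.technique_id, fine, spec.seed, spec, dose)
            )
    else:  # sensitivity
        coarse = fine * COARSE_FACTOR
        _, structs_coarse = build_phantom(phantom.with_spacing(coarse))
        structures[coarse] = structs_coarse
        for i, tech in enumerate(SENSITIVITY_TECHNIQUES):
            seed = _plan_seed(base_seed, 100 + i)
            for res, ss_res in ((fine, structs), (coarse, structs_coarse)):
                spec = PlanSimSpec(
                    technique_id=tech,
                    noise_sd_Gy=SENSITIVITY_NOISE_SD * noise_scale,
                    grid_resolution_mm=res,
                    noise_lattice_mm=fine,
                    seed=seed,
                )
                dose = simulate_plan(ss_res, spec)
                plans.append(PlanRecord(f"T{i + 1:02d}", tech, res, seed, spec, dose))

    return Cohort(design=design, phantom_spec=phantom, structures=structures, plans=plans)


# --------------------------------------------------------------------------
# DVH-constraint QA
# --------------------------------------------------------------------------

@dataclass
class ConstraintRecord:
    structure: str
    metric: str  # Dmean / Dmax / D98% / V105%
    value: Optional[float]
    limit: float
    direction: str  # ">" or "<"
    passed: bool
    error: Optional[str] = None


@dataclass
class PlanQualityReport:
    records: List[ConstraintRecord]

    @property
    def all_pass(self) -> bool:
        return all(r.passed for r in self.records)

    def failures(self) -> List[ConstraintRecord]:
        return [r for r in self.records if not r.passed]


def _dvh_metric(values: np.ndarray, metric: str, prescription_Gy: float) -> float:
    if metric == "Dmean":
        return float(values.mean())
    if metric == "Dmax":
        return float(values.max())
    if metric == "D98%":
        return float(np.percentile(values, 2))
    if metric == "V105%":
        return float(100.0 * np.mean(values >= 1.05 * prescription_Gy))
    raise ValueError(f"unknown DVH metric {metric!r}")


def check_constraints(
    dose: DoseGrid, structs: StructureSet, prescription_Gy: float = 66.0
) -> PlanQualityReport:
    """Evaluate the planning-protocol DVH constraints on one plan.

    PTV must satisfy D98% > 95% of prescription and V105% < 10%; the spinal
    canal and its PRV stay below Dmax 45 Gy, trachea Dmean below 50 Gy,
    parotids Dmean below 25 Gy and RING Dmax below 95% of prescription.
    All comparisons are strict.
    """
    if not dose.grid.same_geometry(structs.reference_grid):
        from .preprocessing import resample_dose

        dose, _ = resample_dose(dose, structs.reference_grid)

    constraints = [
        ("PTV", "D98%", 0.95 * prescription_Gy, ">"),
        ("PTV", "V105%", 10.0, "<"),
        ("spinal_canal", "Dmax", 45.0, "<"),
        ("PRV_SC", "Dmax", 45.0, "<"),
        ("trachea", "Dmean", 50.0, "<"),
        ("parotid_L", "Dmean", 25.0, "<"),
        ("parotid_R", "Dmean", 25.0, "<"),
        ("RING", "Dmax", 0.95 * prescription_Gy, "<"),
    ]
    records: List[ConstraintRecord] = []
    for name, metric, limit, direction in constraints:
        if name not in structs or structs[name].n_voxels == 0:
            records.append(
                ConstraintRecord(name, metric, None, limit, direction, False,
                                 error=f"ROI {name!r} missing or empty")
            )
            continue
        vals = dose.values[structs[name].mask]
        value = _dvh_metric(vals, metric, prescription_Gy)
        passed = value > limit if direction == ">" else value < limit
        records.append(ConstraintRecord(name, metric, value, limit, direction, bool(passed)))
    return PlanQualityReport(records)
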