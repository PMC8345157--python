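import numpy as np
import pytest

from dosetex.core import Grid, DoseGrid, RoiMask
from dosetex.pipeline import RunConfig, run_study
from dosetex.synthetic import PhantomSpec, PlanSimSpec, build_phantom, simulate_plan

#: reduced-scale phantom used by fast unit tests
SMALL_SPEC = PhantomSpec(scale_factor=0.35, voxel_spacing_mm=(3.0, 3.0, 3.0))


@pytest.fixture(scope="session")
def default_structs():
    _, structs = build_phantom(PhantomSpec())
    return structs


@pytest.fixture(scope="session")
def small_structs():
    _, structs = build_phantom(SMALL_SPEC)
    return structs


@pytest.fixture(scope="session")
def small_plan(small_structs):
    return simulate_plan(small_structs, PlanSimSpec(seed=7, noise_lattice_mm=3.0))


@pytest.fixture(scope="session")
def default_plan(default_structs):
    return simulate_plan(default_structs, PlanSimSpec(seed=7))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default study run (all three designs), shared across tests."""
    out = tmp_path_factory.mktemp("default_run")
    return run_study(RunConfig(seed=1), out)


def make_dose(values, spacing=(1.0, 1.0, 1.0)) -> DoseGrid:
    values = np.asarray(values, dtype=float)
    grid = Grid(shape=values.shape, spacing_mm=spacing)
    return DoseGrid(values=values, grid=grid)


def make_mask(mask, name="roi", spacing=(1.0, 1.0, 1.0)) -> RoiMask:
    mask = np.asarray(mask, dtype=bool)
    grid = Grid(shape=mask.shape, spacing_mm=spacing)
    return RoiMask(mask=mask, roi_name=name, grid=grid)
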