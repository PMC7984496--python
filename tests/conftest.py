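import numpy as np
import pytest

from brachydose import (
    Catheter, DwellSource, ImplantPlan, VoxelGrid,
    unit_test_source, generic_ir192_source,
)


@pytest.fixture(scope="session")
def unit_source():
    return unit_test_source()


@pytest.fixture(scope="session")
def ir_source():
    return generic_ir192_source()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def straight_catheter():
    return Catheter(id="c0", path_mm=np.array([[0.0, -50.0, 10.0],
                                               [0.0, 50.0, 10.0]]))


@pytest.fixture
def two_dwell_plan(straight_catheter):
    """Two-catheter toy plan with a handful of dwells."""
    c2 = Catheter(id="c1", path_mm=np.array([[20.0, -50.0, 10.0],
                                             [20.0, 50.0, 10.0]]))
    return ImplantPlan(catheters=[straight_catheter, c2],
                       dwell_step_mm=25.0, dwell_retraction_mm=0.0,
                       air_kerma_strength_U=1000.0)


@pytest.fixture
def small_grid():
    return VoxelGrid(origin_mm=(-10.0, -10.0, 0.0), spacing_mm=(2.0, 2.0, 2.0),
                     shape=(11, 11, 11))
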