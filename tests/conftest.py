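import numpy as np
import pytest

from opmpipe.config import RunConfig
from opmpipe.forward import (
    SphereHeadModel,
    build_default_array,
    build_default_grid,
    compute_lead_field,
)


@pytest.fixture(scope="session")
def head():
    return SphereHeadModel()


@pytest.fixture(scope="session")
def array(head):
    return build_default_array(head)


@pytest.fixture(scope="session")
def grid(head):
    return build_default_grid(head)


@pytest.fixture(scope="session")
def lead(array, grid, head):
    return compute_lead_field(array, grid, head)


@pytest.fixture(scope="session")
def cohort_result():
    """Full pipeline on the default 12-subject cohort (one fixed seed).

    Shared by the parameter-recovery and acceptance tests; computed once.
    """
    from opmpipe.pipeline import run_full

    return run_full(RunConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
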