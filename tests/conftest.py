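import numpy as np
import pytest

from dllmeopt.design import (
    Condition,
    FactorSpace,
    ModelSpec,
    REDUCED_ETHYL_OCTANOATE_TERMS,
    enumerate_grid,
)
from dllmeopt.synthetic import ETHYL_OCTANOATE_TRUTH


@pytest.fixture(scope="session")
def space() -> FactorSpace:
    return FactorSpace()


@pytest.fixture(scope="session")
def grid(space):
    return enumerate_grid(space)


@pytest.fixture(scope="session")
def eo_truth():
    return ETHYL_OCTANOATE_TRUTH


@pytest.fixture(scope="session")
def reduced_spec():
    return ModelSpec(REDUCED_ETHYL_OCTANOATE_TERMS)


@pytest.fixture(scope="session")
def eo_noiseless(grid, space, eo_truth):
    """Exact linear-predictor responses of the packaged model on the full grid."""
    return eo_truth.linear_predictor(grid, space)


@pytest.fixture
def toy_line_space():
    """One-level categoricals + volume levels 1..4: a pure intercept+slope problem."""
    return FactorSpace(
        extraction_solvent_levels=("solv",),
        extraction_volume_levels=(1, 2, 3, 4),
        disperser_solvent_levels=("disp",),
        disperser_volume_levels=(1,),
        reference_extraction_solvent="solv",
        reference_disperser_solvent="disp",
    )
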