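import numpy as np
import pytest

from helixgraft import (
    AlignmentParams,
    PropensityPredictor,
    average_mass,
    kyte_doolittle,
    make_fitness_function,
)
from helixgraft.synthetic import FixtureSpec, make_template


@pytest.fixture(scope="session")
def hydro_table():
    return kyte_doolittle()


@pytest.fixture(scope="session")
def mw_table():
    return average_mass()


@pytest.fixture(scope="session")
def predictor():
    return PropensityPredictor()


@pytest.fixture(scope="session")
def align_params():
    return AlignmentParams()


@pytest.fixture(scope="session")
def template(predictor, hydro_table, mw_table):
    """Deterministic 56-residue template with 16 fixed positions."""
    return make_template(FixtureSpec(rng_seed=1))


@pytest.fixture(scope="session")
def fitness_fn(template, predictor, align_params, hydro_table, mw_table):
    return make_fitness_function(
        template, predictor, align_params, hydro_table, mw_table
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
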