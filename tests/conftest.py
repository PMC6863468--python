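import numpy as np
import pandas as pd
import pytest

from rdacclim import (
    assemble_parameter_table,
    draw_true_parameters,
    fit_all_individuals,
    make_design,
    simulate_measurements,
)
from rdacclim.synthetic import TrueParameters


@pytest.fixture(scope="session")
def table1_design():
    return make_design("table1", seed=0)


@pytest.fixture(scope="session")
def default_truth():
    return draw_true_parameters(seed=0)


@pytest.fixture(scope="session")
def table1_study(table1_design, default_truth):
    return simulate_measurements(table1_design, default_truth)


@pytest.fixture(scope="session")
def table1_parameter_table(table1_study):
    fits, failures = fit_all_individuals(table1_study.records)
    assert len(failures) == 0
    return assemble_parameter_table(fits)


@pytest.fixture(scope="session")
def noiseless_truth():
    """Every flux exactly on its generating curve; offsets retained."""
    return TrueParameters(noise_sd_log=0.0, top_temp_jitter_sd=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
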