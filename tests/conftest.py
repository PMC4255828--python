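import numpy as np
import pandas as pd
import pytest

from embryoscreen import datasets
from embryoscreen.design import bj_design
from embryoscreen.quantify import CountMatrix
from embryoscreen.synthetic_data import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def design():
    return bj_design()


@pytest.fixture(scope="session")
def marker_expr():
    """Packaged marker panel as a normalised ExpressionMatrix."""
    return datasets.marker_expression()


@pytest.fixture(scope="session")
def marker_panel():
    return datasets.marker_panel()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_counts(rng):
    """A random 12-transcript x 4-sample count matrix for IO/quantify tests."""
    ids = [f"T{i:03d}" for i in range(12)]
    samples = ["S1", "S2", "S3", "S4"]
    counts = pd.DataFrame(
        rng.integers(0, 500, size=(12, 4)), index=ids, columns=samples
    )
    lengths = pd.Series(rng.integers(200, 4000, size=12), index=ids)
    libs = pd.Series([1e6, 2e6, 1.5e6, 2.5e6], index=samples)
    return CountMatrix(counts=counts, lengths=lengths, library_sizes=libs)


@pytest.fixture(scope="session")
def sim_cohort(design):
    """Default-condition simulated cohort, shared across tests (seed 7)."""
    config = SimConfig(seed=7)
    matrix, truth = simulate_counts(config, design)
    return config, matrix, truth
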