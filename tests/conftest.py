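import numpy as np
import pytest

from netsubtype import synthetic
from netsubtype.matrix import ExprMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort with planted subtypes, shared across tests."""
    cfg = synthetic.SimulationConfig(
        n_genes=200, n_pd1=20, n_pd2=25, n_nc=30, n_de_subtype=40,
        n_de_disease=30, lfc_mean=2.0, seed=777,
    )
    return synthetic.simulate_cohort(cfg)


def expr_from_array(values: np.ndarray, prefix: str = "g") -> ExprMatrix:
    g, s = values.shape
    return ExprMatrix(
        [f"{prefix}{i}" for i in range(g)],
        [f"s{i}" for i in range(s)],
        values,
    )
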