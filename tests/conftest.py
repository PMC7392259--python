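import numpy as np
import pandas as pd
import pytest

from segstab.bayes import PriorSpec
from segstab.simulate import SimulationConfig, simulate_trial
from segstab.trial_data import TrialTable, compute_environment_index


def make_table(rows):
    return TrialTable(
        pd.DataFrame(rows, columns=["genotype", "environment", "block", "yield"])
    )


@pytest.fixture
def toy_table():
    """2 genotypes x 2 environments x 2 blocks with hand-chosen integers."""
    rows = [
        ("A", "E1", "B1", 8000), ("A", "E1", "B2", 8200),
        ("A", "E2", "B1", 9000), ("A", "E2", "B2", 9400),
        ("B", "E1", "B1", 7000), ("B", "E1", "B2", 7300),
        ("B", "E2", "B1", 9500), ("B", "E2", "B2", 9100),
    ]
    return make_table(rows)


@pytest.fixture(scope="session")
def small_study():
    """Balanced 5-genotype x 10-environment x 2-block synthetic study."""
    return simulate_trial(
        SimulationConfig(n_genotypes=5, n_environments=10, n_blocks=2, seed=42)
    )


@pytest.fixture(scope="session")
def small_index(small_study):
    return compute_environment_index(small_study.table)


def vague_prior(var: float = 1e10) -> PriorSpec:
    """Coefficient priors flat on the kg/ha scale; Jeffreys-like precision."""
    return PriorSpec(0.0, 0.0, 0.0, var, var, var, 0.001, 0.001)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
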