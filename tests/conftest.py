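import numpy as np
import pandas as pd
import pytest

from hlafinemap.core import CohortCalls
from hlafinemap.simulate import SimConfig, simulate_cohort


def make_calls(rows, ancestry=None):
    """Small helper: rows of (pid, gene, a1, a2, state) -> CohortCalls."""
    df = pd.DataFrame(
        rows, columns=["participant_id", "gene", "allele1", "allele2", "state"]
    )
    pids = df["participant_id"].unique()
    anc = pd.Series(
        [ancestry.get(p, "EUR") if ancestry else "EUR" for p in pids], index=pids
    )
    return CohortCalls(df, anc)


@pytest.fixture(scope="session")
def sim_cohort():
    """Default 5,000-participant multi-ancestry cohort, fully simulated."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_truth(sim_cohort):
    return sim_cohort.truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
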