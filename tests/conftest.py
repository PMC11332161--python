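import numpy as np
import pandas as pd
import pytest

import newsmeta as nm
from newsmeta.sdt import FALSE_NEWS, TRUE_NEWS


@pytest.fixture(scope="session")
def full_set() -> nm.StimulusSet:
    return nm.generate_stimulus_set("full_140")


@pytest.fixture(scope="session")
def equated_set() -> nm.StimulusSet:
    return nm.generate_stimulus_set("equated_64")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230)


def balanced_items(n_per_class: int) -> pd.DataFrame:
    """A veracity-balanced, favorability-free item table for observers."""
    return pd.DataFrame(
        {
            "item_id": [f"t{i}" for i in range(n_per_class)]
            + [f"f{i}" for i in range(n_per_class)],
            "veracity": [TRUE_NEWS] * n_per_class + [FALSE_NEWS] * n_per_class,
            "favorability": "unclassified",
        }
    )


@pytest.fixture(scope="session")
def reduced_mcmc() -> nm.MCMCConfig:
    """Short chains for tests that only need rough posterior means."""
    return nm.MCMCConfig(n_chains=3, n_samples=1500, n_warmup=500, seed=7)
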