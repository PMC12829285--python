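import numpy as np
import pytest

from methmark import SyntheticConfig, simulate_cohort_pair
from methmark.io import cluster_labels


@pytest.fixture(scope="session")
def small_pair():
    """A small strong-signal cohort pair for unit-level tests."""
    cfg = SyntheticConfig(n_cpgs=400, seed=7)
    disc, rep, sheet, truth = simulate_cohort_pair(cfg)
    return cfg, disc, rep, sheet, truth


@pytest.fixture(scope="session")
def small_labels(small_pair):
    _, disc, _, sheet, _ = small_pair
    return cluster_labels(sheet, disc.sample_ids)
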