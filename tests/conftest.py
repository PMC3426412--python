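"""Shared fixtures: synthetic datasets at the sizes the checks need."""

import numpy as np
import pytest

from ecf41 import fixtures
from ecf41.synthetic_data import SimulationConfig, simulate


@pytest.fixture(scope="session")
def dataset_small():
    """Default-sized noiseless dataset (40 loci on two 100 kb replicons)."""
    return simulate(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def dataset_1000():
    """Large noiseless dataset: 1000 loci for exact-recovery checks."""
    cfg = SimulationConfig(
        seed=9, n_replicons=4, replicon_length=1_300_000, n_ecf_loci=1000
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def blich_promoters():
    """The 15 printed B. licheniformis candidate promoter sequences."""
    return fixtures.load_candidate_promoters("Bacillus_licheniformis")


@pytest.fixture(scope="session")
def context_counts():
    """The printed genomic-context count table."""
    return fixtures.load_context_counts()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
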