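"""Shared fixtures: a small synthetic study and its derived objects.

Everything is generated at test time from seeded configs; no stored data.
"""

import numpy as np
import pytest

from cfhydroxy import SimConfig, simulate_dataset
from cfhydroxy.quant import CountMatrix, RegionUniverse, count_matrix, merge_replicates


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A scaled-down six-group design that keeps every code path alive."""
    return SimConfig(
        seed=11,
        genome=(("chr1", 3_000_000), ("chr2", 3_000_000)),
        n_genes=40,
        n_hmrs=400,
        n_planted_per_group=20,
        baseline_mean_count=20.0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_counts(small_dataset) -> CountMatrix:
    uni = RegionUniverse(small_dataset.universe, "merged_hmr", {"source": "fixture"})
    return count_matrix(uni, small_dataset.samples, fragments=small_dataset.fragments)


@pytest.fixture(scope="session")
def small_groups(small_counts):
    return merge_replicates(small_counts)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
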