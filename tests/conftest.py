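"""Shared fixtures: one small synthetic dataset reused across test modules."""

import pandas as pd
import pytest

from bsmeth.core import MethylomeSample
from bsmeth.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=7,
        chrom_lengths={"A01": 120_000, "D01": 120_000},
        genes_per_chrom=8,
        tegs_per_chrom=2,
        tes_per_chrom=12,
    )


@pytest.fixture(scope="session")
def dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def sample_first(dataset):
    return dataset.methylomes[dataset.config.samples[0]]


@pytest.fixture(scope="session")
def sample_last(dataset):
    return dataset.methylomes[dataset.config.samples[-1]]


def make_sample(rows, name="s", rate=0.006) -> MethylomeSample:
    """Build a sample from (chrom, pos, strand, context, m, u) tuples."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "count_m", "count_u"]
    )
    return MethylomeSample(name, df, nonconversion_rate=rate)
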