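import numpy as np
import pytest

from datsscan import (
    PipelineConfig,
    StrandedCounts,
    SyntheticConfig,
    run_pipeline,
    simulate_counts,
    simulate_genome,
)


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic landscape (seed 1): models, truth, counts."""
    config = SyntheticConfig(seed=1)
    models, truth = simulate_genome(config)
    counts = simulate_counts(truth, config)
    return config, models, truth, counts


@pytest.fixture(scope="session")
def default_callset(default_sim):
    _, models, truth, counts = default_sim
    callset = run_pipeline(models, counts)
    return truth, callset


def make_counts(entries, lengths=None, total=None):
    """StrandedCounts from {(chrom, strand, pos): n} literals."""
    counts = StrandedCounts(lengths or {"chrT": 1_000_000}, total_aligned=total)
    for (chrom, strand, pos), n in entries.items():
        counts.add(chrom, strand, pos, n)
    return counts


@pytest.fixture
def toy_config():
    return PipelineConfig(read_threshold=5)
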