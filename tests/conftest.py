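import numpy as np
import pandas as pd
import pytest

from accessmark import SimulationConfig, simulate_genome, simulate_truth, apply_knockdown
from accessmark.core import FragmentSet, Genome


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """A small genome that keeps unit tests fast."""
    return SimulationConfig(
        n_chromosomes=1,
        chromosome_length=10_000_000,
        n_genes=200,
        depth=30_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_config):
    genome, annotation = simulate_genome(tiny_config)
    truth = apply_knockdown(simulate_truth(annotation, tiny_config), tiny_config)
    return genome, annotation, truth


def make_fragments(rows, **meta) -> FragmentSet:
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    frame["start"] = frame["start"].astype(np.int64)
    frame["end"] = frame["end"].astype(np.int64)
    return FragmentSet(frame, **meta)


@pytest.fixture
def toy_genome() -> Genome:
    return Genome({"chr1": 100_000, "chr2": 50_000})
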