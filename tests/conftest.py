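import numpy as np
import pytest

from chromdiff.intervals import GenomicInterval
from chromdiff.simulate import SimulationConfig, generate_study

SMALL_CONFIG = dict(
    seed=7,
    n_chroms=1,
    chrom_length=300_000,
    n_genes=40,
    n_targets=5,
    n_clusters=3,
)


@pytest.fixture(scope="session")
def small_study():
    """A miniature study fixture shared by the slower integration tests."""
    cfg = SimulationConfig(**SMALL_CONFIG)
    return generate_study(cfg)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=500):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(str(rng.choice(chroms)), start, start + length))
    return out
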