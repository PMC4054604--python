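import numpy as np
import pytest

from tircat.core import GenomeModel, GenomicInterval
from tircat.simulate import SimulationConfig, simulate_bundle


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genome():
    return GenomeModel({"chr1": 10_000, "chr2": 8_000})


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic bundle (seed 1), written to disk once per session."""
    outdir = tmp_path_factory.mktemp("bundle")
    return simulate_bundle(SimulationConfig(seed=1), outdir=str(outdir)), str(outdir)


def iv(chrom, start, end, strand=".", name=".", score=0.0):
    return GenomicInterval(chrom, start, end, strand, name, score)
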