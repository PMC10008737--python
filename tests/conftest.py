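import numpy as np
import pytest

from chromoscore.cn_profile import CNProfile, CNSegment
from chromoscore.genome import GenomeBuild


@pytest.fixture
def toy_genome():
    """Two 100 Mb autosomes plus an X chromosome."""
    return GenomeBuild(
        lengths={"chr1": 100_000_000, "chr2": 100_000_000, "chrX": 100_000_000},
        arm_boundaries={"chr1": 40_000_000, "chr2": 40_000_000, "chrX": 40_000_000},
    )


@pytest.fixture
def flat_diploid(toy_genome):
    segs = [
        CNSegment("chr1", 1, 100_000_000, 2),
        CNSegment("chr2", 1, 100_000_000, 2),
    ]
    return CNProfile("flat", segs, toy_genome)


def make_profile(genome, spec, sample_id="T"):
    """Build a profile from {chrom: [(start, end, cn), ...]}."""
    segs = [CNSegment(c, s, e, cn) for c, items in spec.items() for s, e, cn in items]
    return CNProfile(sample_id, segs, genome)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
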