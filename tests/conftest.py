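import numpy as np
import pytest

from hetchrom import BinnedTrack, GenomeDef


@pytest.fixture
def small_genome():
    return GenomeDef((("chrT", 1_000_000), ("chrU", 503_000)))


@pytest.fixture
def one_chrom():
    return GenomeDef((("chrT", 100_000),))


def make_track(genome, bin_width, mark="m", fill=0.0, **per_chrom):
    """Constant-fill track with optional per-chromosome overrides."""
    values = {}
    for chrom in genome.names:
        n = genome.n_bins(chrom, bin_width)
        values[chrom] = per_chrom.get(chrom, np.full(n, float(fill)))
    return BinnedTrack(genome, bin_width, values, mark)
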