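import numpy as np
import pytest

from cobindseq.genome import GenomeIndex, GenomicInterval


@pytest.fixture
def genome_10kb():
    return GenomeIndex([("chr1", 10_000)])


@pytest.fixture
def genome_two_chrom():
    return GenomeIndex([("chr1", 10_000), ("chr2", 5_000)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


def random_peaks(rng, L, n, width_range=(100, 600), chrom="chr1"):
    """Random peak intervals for oracle comparisons."""
    peaks = []
    for _ in range(n):
        w = int(rng.integers(*width_range))
        s = int(rng.integers(0, max(1, L - w)))
        peaks.append(GenomicInterval(chrom, s, s + w))
    return peaks
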