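import pytest

from cnvmap.core import CNVCall, GenomeBuild


@pytest.fixture
def toy_genome():
    """Two 100 kb autosomes plus a sex chromosome."""
    return GenomeBuild(chromosomes=(("1", 100_000), ("2", 100_000), ("X", 50_000)))


@pytest.fixture
def tiny_genome():
    """One 100 kb chromosome for per-base oracle comparisons."""
    return GenomeBuild(chromosomes=(("1", 100_000),))


def make_call(sample="S1", chrom="1", start=0, end=10_000, cn=1, num_snps=5):
    return CNVCall(sample, chrom, start, end, cn=cn, num_snps=num_snps)


@pytest.fixture
def make_calls():
    return make_call
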