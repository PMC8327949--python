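import pytest

from mirmove import (
    MatureAnnotation,
    ReferenceBundle,
    make_amirsul_reference,
    make_reference,
)


@pytest.fixture
def amirsul_ref():
    return make_amirsul_reference(seed=7)


@pytest.fixture
def small_ref():
    """Ten random loci on a 2 kb genome, mixed strands."""
    return make_reference(10, genome_length=2000, seed=11)


@pytest.fixture
def toy_ref():
    """Hand-built single plus-strand locus for exact-value tests."""
    genome = "A" * 30 + "TTAAGTGTCACGGAAATCCCT" + "G" + "C" * 28
    ann = MatureAnnotation("mirX", "chr1", 30, 51, "+", "TTAAGTGTCACGGAAATCCCT")
    bundle = ReferenceBundle(genome, [ann])
    bundle.validate()
    return bundle
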