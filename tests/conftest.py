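import numpy as np
import pytest

from varan.variants import ReferenceSequence


@pytest.fixture
def spec_reference():
    """Tiny contig whose positions 100-109 read GCACACACAT: a dinucleotide
    repeat that makes indel representations ambiguous."""
    prefix = "".join(
        np.random.default_rng(7).choice(list("ACGT"), size=99)
    )
    seq = prefix + "GCACACACAT" + "GGATTC"
    return ReferenceSequence({"chr1": seq})


@pytest.fixture
def small_reference():
    return ReferenceSequence({"chr1": "ACGTACGTTTTTGCGCACACACATTGCAGT"})
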