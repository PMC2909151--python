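import numpy as np
import pytest

from matlink.alignment import AlignedSequence, Alignment


def make_alignment(seqs, locus="test", ids=None, **kwargs):
    ids = ids or [f"s{i}" for i in range(len(seqs))]
    return Alignment(locus, [AlignedSequence(i, s, **kwargs) for i, s in zip(ids, seqs)])


@pytest.fixture
def rng():
    return np.random.default_rng(20100712)


@pytest.fixture
def aln_factory():
    return make_alignment


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
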