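import numpy as np
import pytest

from bsmapper import Genome, convert_reference
from bsmapper.refprep import ReferenceSpace
from bsmapper._dna import encode


def make_genome(seqs) -> Genome:
    if isinstance(seqs, str):
        seqs = {"chr1": seqs}
    return Genome.from_sequences(seqs)


def make_space(seq, space_id="W_CT", name="chr1") -> ReferenceSpace:
    """Wrap a raw string as a reference space (for aligner tests the
    conversion provenance is irrelevant)."""
    conversion = "G_to_A" if space_id.endswith("GA") else "C_to_T"
    return ReferenceSpace(space_id, conversion, (name,), {name: encode(seq)})


def spaces_of(seq) -> dict:
    return {s.space_id: s for s in convert_reference(make_genome(seq))}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
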