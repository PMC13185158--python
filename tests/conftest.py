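import numpy as np
import pytest

from varmine import GeneratorSpec, generate_repository
from varmine.records import NUCLEOTIDE, SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_repo():
    """A small deterministic synthetic repository with ground truth."""
    spec = GeneratorSpec(length_nt=300, n_variants=8, n_mutations=6,
                         silent_fraction=0.5, seed=11)
    return generate_repository(spec)


def make_record(seq: str, rec_id: str = "seq", kind: str = NUCLEOTIDE,
                **kwargs) -> SequenceRecord:
    return SequenceRecord(id=rec_id, seq=seq, kind=kind, **kwargs)
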