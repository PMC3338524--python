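import numpy as np
import pytest

from cladeshift.alignment import AlignmentGroup
from cladeshift.substitution import RateModel, ScoringMatrix


@pytest.fixture(scope="session")
def blosum62() -> ScoringMatrix:
    return ScoringMatrix.blosum62()


@pytest.fixture(scope="session")
def jtt() -> RateModel:
    return RateModel.jtt()


def make_group(seqs, species=None, tags=None, group_id="g"):
    """Build an AlignmentGroup from (id, string) pairs with defaults."""
    ids = [sid for sid, _ in seqs]
    species = species or {sid: f"sp_{sid}" for sid in ids}
    tags = tags or {sid: "J" for sid in ids}
    return AlignmentGroup(
        group_id=group_id, sequences=list(seqs), species_of=species, category_tags=tags
    )


@pytest.fixture
def tiny_group():
    return make_group(
        [("s1", "ACDEFGHIKL"), ("s2", "ACDEFGHIKL"), ("s3", "ACDEFGH-KL")]
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231115)
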