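import numpy as np
import pytest

from amocap.io_core import SeqRecord, rng as make_rng
from amocap.mock_synth import GeneFamilyParams, build_mock, generate_gene_family


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def gene_family():
    """Six mutually diverged clean-ORF genes at the default insert lengths."""
    return generate_gene_family(GeneFamilyParams(seed=7))


@pytest.fixture(scope="session")
def mock_community(gene_family):
    return build_mock(gene_family, seed=7)


@pytest.fixture()
def rng():
    return make_rng(123, "tests")


@pytest.fixture()
def make_record():
    def _make(seq: str, rec_id: str = "r", qual=None):
        return SeqRecord(rec_id, seq, qual=qual)

    return _make
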