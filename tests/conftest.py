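import numpy as np
import pytest

from bicypep.preprocess import AbundanceTable
from bicypep.synthetic import NNK_CODONS_BY_AA


def table_from_aa_counts(counts: dict[str, int]) -> AbundanceTable:
    """Build a table from peptide counts, back-translating via NNK codons."""
    aa_nt = {}
    for aa, count in counts.items():
        nt = "".join(NNK_CODONS_BY_AA[res][0] for res in aa)
        aa_nt[aa] = {nt: count}
    return AbundanceTable.from_counts(aa_nt)


def table_from_nt_counts(nt_counts: dict[str, int]) -> AbundanceTable:
    from bicypep.preprocess import translate_region

    aa_nt: dict[str, dict[str, int]] = {}
    for nt, count in nt_counts.items():
        aa = translate_region(nt)
        assert aa is not None, nt
        aa_nt.setdefault(aa, {})[nt] = count
    return AbundanceTable.from_counts(aa_nt)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_peptides(rng):
    """10^3 random peptides over the 20 amino acids, lengths 8-15."""
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    peptides = []
    for _ in range(1000):
        n = rng.integers(8, 16)
        peptides.append("".join(rng.choice(aas, size=n)))
    return peptides
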