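import numpy as np
import pytest

from barcodekit.msa_io import Alignment, SequenceRecord


def make_alignment(rows, locus="test", species=None, genera=None):
    """Build an Alignment from raw residue strings.

    ``species`` may be a list of binomials (genus inferred as the first
    token); default gives every row its own species.
    """
    records = []
    for i, row in enumerate(rows):
        sp = species[i] if species else f"Genus{i} species{i}"
        gen = genera[i] if genera else sp.split()[0]
        records.append(SequenceRecord(f"R{i:03d}", gen, sp, row))
    return Alignment(locus, tuple(records))


@pytest.fixture
def tiny_alignment():
    # 4 x 16, three variable columns: col 2 {A,A,G,G} (PI),
    # col 7 {C,C,C,T} (singleton), col 11 {A,A,G,G} (PI)
    rows = [
        "ATACGTACGTAAACGT",
        "ATACGTACGTAAACGT",
        "ATGCGTACGTAGACGT",
        "ATGCGTATGTAGACGT",
    ]
    return make_alignment(rows, species=["Aus bus", "Aus bus", "Cus dus", "Cus dus"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_alignment(rng, n, L, alphabet="ACGT"):
    mat = rng.integers(len(alphabet), size=(n, L))
    rows = ["".join(alphabet[i] for i in row) for row in mat]
    return make_alignment(rows)
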