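import numpy as np
import pytest

from pepdca.alignment_io import MSA, LigandSet, PROTEIN_ALPHABET


@pytest.fixture
def toy_msa():
    """4-column, 5-sequence alignment with species labels."""
    seqs = ["ACDE", "ACDE", "ACDF", "GHIK", "GH-K"]
    ids = [f"s{i}" for i in range(5)]
    species = ["Homo sapiens", "Homo sapiens", "Mus musculus", "Mus musculus", "Gallus gallus"]
    return MSA.from_sequences(ids, seqs, species_labels=species)


@pytest.fixture
def random_msa_factory():
    """Random ungapped alignments over a reduced alphabet."""

    def make(n_seq=20, n_col=6, q=4, seed=0, alphabet=None):
        rng = np.random.default_rng(seed)
        if alphabet is None:
            alphabet = PROTEIN_ALPHABET[:q - 1] + "-" if q < 21 else PROTEIN_ALPHABET
        mat = rng.integers(0, len(alphabet) - 1, size=(n_seq, n_col))  # never gap
        return MSA([f"r{i}" for i in range(n_seq)], mat, alphabet)

    return make


@pytest.fixture
def simple_ligands():
    return LigandSet(
        peptides={"s0": ["ACDE", "GHIK"], "s1": ["ACDF"]},
        length=4,
    )


@pytest.fixture
def fasta_file(tmp_path):
    path = tmp_path / "aln.fasta"
    path.write_text(">a\nACDE-\n>b\nACDEF\n>c\nGHIKL\n")
    return path


@pytest.fixture
def stockholm_file(tmp_path):
    path = tmp_path / "aln.sto"
    path.write_text(
        "# STOCKHOLM 1.0\n"
        "a ACDE.\n"
        "b ACDEF\n"
        "c GHIKL\n"
        "//\n"
    )
    return path
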