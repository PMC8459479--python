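import pytest

from seqsonify.fixtures import make_domain_msa, make_repeat_protein
from seqsonify.sequence_io import Alignment, ProteinSequence


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing FASTA text and returning the path."""

    def write(text, name="input.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return write


@pytest.fixture
def small_alignment():
    return Alignment(
        ids=("a", "b", "c"),
        rows=("ACD-F", "ACE-F", "AC--F"),
    )


@pytest.fixture
def task1_protein():
    """Length-253 protein with an 8-residue motif in 4 tandem copies."""
    return make_repeat_protein(total_len=253, motif_len=8, n_repeats=4, seed=11)


@pytest.fixture
def task2_msa():
    """5-sequence alignment with three conserved domains under 50 columns."""
    return make_domain_msa(
        n_seqs=5,
        n_cols=200,
        domains=((20, 40), (80, 40), (150, 30)),
        gap_rate=0.0,
        seed=11,
    )
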