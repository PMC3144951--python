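import numpy as np
import pytest

from ferricnv.seqfeat import NucleotideSequence

# 27-nt iron-responsive element used as a fixed validation input.
IRE_27 = "ctttgctgcgtcagtgaacgtacgagc"


def make_cdna(utr5: int, n_sense_codons: int, utr3: int) -> NucleotideSequence:
    """A cDNA with a single unambiguous ORF: ATG + n sense codons + TAA.

    UTRs are ORF-free (no A/T/G), so the built ORF is the longest by
    construction.  ORF length in nt is 3 * (n_sense_codons + 2).
    """
    residues = "C" * utr5 + "ATG" + "GCT" * n_sense_codons + "TAA" + "C" * utr3
    return NucleotideSequence(id="synthetic_cdna", residues=residues)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ire_sequence():
    return NucleotideSequence(id="ire27", residues=IRE_27)
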