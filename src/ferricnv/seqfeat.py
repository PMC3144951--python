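"""Structural annotation of mRNA/gene sequences.

Covers the features needed to characterise a ferritin-like transcript and
its gene: longest-ORF annotation with UTR partition, polyadenylation-signal
scanning, protein mass / isoelectric point, consensus iron-responsive
element (IRE) stem-loop detection, and exon/intron mapping by spliced
anchoring of a cDNA onto its genomic sequence.

All coordinates are 1-based inclusive.  T and U are treated as equivalent
throughout; matching is case-insensitive.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq

_VALID_RESIDUES = set("ACGTUN")

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

DEFAULT_POLYA_MOTIFS = ("ATTAAA", "AATAAA")

#: Watson-Crick RNA pairs plus G.U wobble
_WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
_WOBBLE_PAIRS = frozenset({("G", "U"), ("U", "G")})

# Average isotopic residue masses (Da): amino acid minus one water.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

# EMBOSS pKa set used for the net-charge / isoelectric-point calculation.
PKA_NTERM = 8.6
PKA_CTERM = 3.6
PKA_POSITIVE = {"K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


@dataclass(frozen=True)
class NucleotideSequence:
    """A DNA or RNA sequence with a validated alphabet.

    ``alphabet`` is inferred when omitted: presence of U implies RNA,
    otherwise DNA.  T and U may not co-occur.
    """

    id: str
    residues: str
    alphabet: str = ""

    def __post_init__(self) -> None:
        seq = self.residues.upper()
        if not seq:
            raise ValueError("empty sequence")
        bad = set(seq) - _VALID_RESIDUES
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in sequence {self.id!r}")
        if "T" in seq and "U" in seq:
            raise ValueError(f"sequence {self.id!r} mixes T and U")
        inferred = "rna" if "U" in seq else "dna"
        alphabet = self.alphabet or inferred
        if alphabet not in ("dna", "rna"):
            raise ValueError(f"alphabet must be 'dna' or 'rna', got {alphabet!r}")
        if alphabet == "dna" and "U" in seq:
            raise ValueError("dna alphabet cannot contain U")
        if alphabet == "rna" and "T" in seq:
            raise ValueError("rna alphabet cannot contain T")
        object.__setattr__(self, "residues", seq)
        object.__setattr__(self, "alphabet", alphabet)

    def __len__(self) -> int:
        return len(self.residues)

    def as_dna(self) -> str:
        return self.residues.replace("U", "T")

    def as_rna(self) -> str:
        return self.residues.replace("T", "U")


@dataclass(frozen=True)
class OrfAnnotation:
    """Longest open reading frame and the implied UTR partition.

    ``start``/``end`` are 1-based inclusive and span start codon through
    stop codon, so ``length_nt`` is divisible by 3 and the encoded protein
    has ``length_nt / 3 - 1`` residues.
    """

    start: int
    end: int
    protein: str
    utr5_length: int
    utr3_length: int

    def __post_init__(self) -> None:
        if self.length_nt % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if len(self.protein) != self.length_nt // 3 - 1:
            raise ValueError("protein length inconsistent with ORF length")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1

    @property
    def total_length(self) -> int:
        """Length of the annotated sequence implied by the partition."""
        return self.utr5_length + self.length_nt + self.utr3_length


@dataclass(frozen=True)
class ProteinStats:
    length_aa: int
    molecular_mass: float  # Da, average isotopic
    isoelectric_point: float


@dataclass(frozen=True)
class IreMatch:
    """A located IRE-like stem-loop (1-based inclusive coordinates).

    ``start``/``end`` span the paired stem extent; ``bulge_pos`` is the
    unpaired C immediately 5' of the upper stem.
    """

    start: int
    end: int
    loop_seq: str
    loop_start: int
    bulge_pos: int
    upper_stem_pairs: int
    lower_stem_pairs: int


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron structure of a gene on its genomic sequence.

    Exons are ordered, non-overlapping ``(start, end)`` pairs; introns carry
    their donor and acceptor dinucleotides (canonically GT / AG).
    """

    exons: tuple[tuple[int, int], ...]
    introns: tuple[tuple[int, int, str, str], ...]
    total_genomic_length: int

    def __post_init__(self) -> None:
        for (s, e) in self.exons:
            if s > e:
                raise ValueError(f"degenerate exon ({s}, {e})")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 >= s2:
                raise ValueError("exons overlap or are unordered")
        for (s, e, _d, _a) in self.introns:
            if e - s + 1 < 4:
                raise ValueError(f"intron ({s}, {e}) shorter than 4 nt")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    @property
    def canonical(self) -> bool:
        return all(d == "GT" and a == "AG" for (_s, _e, d, a) in self.introns)

    def spliced(self, genomic: "NucleotideSequence | str") -> str:
        seq = genomic.as_dna() if isinstance(genomic, NucleotideSequence) else genomic.upper()
        return "".join(seq[s - 1 : e] for s, e in self.exons)


class SpliceMappingError(ValueError):
    """cDNA could not be reconstructed from the genomic sequence."""

    def __init__(self, message: str, furthest_cdna_pos: int):
        super().__init__(message)
        self.furthest_cdna_pos = furthest_cdna_pos


def find_orf(seq: NucleotideSequence) -> OrfAnnotation:
    """Longest ATG-initiated, stop-terminated reading frame (forward strand).

    Among equal-length candidates the 5'-most wins.  Raises ``ValueError``
    when no complete ORF exists.
    """
    dna = seq.as_dna()
    best: Optional[tuple[int, int]] = None  # (start0, end0) inclusive
    for frame in range(3):
        start0: Optional[int] = None
        for pos in range(frame, len(dna) - 2, 3):
            codon = dna[pos : pos + 3]
            if start0 is None:
                if codon == START_CODON:
                    start0 = pos
            elif codon in STOP_CODONS:
                length = pos + 3 - start0
                if best is None or length > best[1] - best[0] + 1 or (
                    length == best[1] - best[0] + 1 and start0 < best[0]
                ):
                    best = (start0, pos + 2)
                start0 = None
        # an ORF without an in-frame stop is incomplete: discarded
    if best is None:
        raise ValueError("no ORF found")
    start0, end0 = best
    coding = dna[start0 : end0 + 1]
    protein = str(Seq(coding).translate(table=1))
    assert protein.endswith("*")
    return OrfAnnotation(
        start=start0 + 1,
        end=end0 + 1,
        protein=protein[:-1],
        utr5_length=start0,
        utr3_length=len(dna) - (end0 + 1),
    )


def scan_polya_signal(
    seq: NucleotideSequence,
    motifs: Sequence[str] = DEFAULT_POLYA_MOTIFS,
) -> list[tuple[str, int, int]]:
    """All (possibly overlapping) occurrences of polyadenylation motifs.

    Returns ``(motif, start, end)`` tuples with 1-based inclusive
    coordinates, ordered by position then motif.
    """
    dna = seq.as_dna()
    hits: list[tuple[str, int, int]] = []
    for motif in motifs:
        pattern = motif.upper().replace("U", "T")
        for m in re.finditer(f"(?={re.escape(pattern)})", dna):
            hits.append((motif, m.start() + 1, m.start() + len(pattern)))
    return sorted(hits, key=lambda h: (h[1], h[0]))


def _net_charge(counts: dict[str, int], n_residues: int, ph: float) -> float:
    charge = 1.0 / (1.0 + 10.0 ** (ph - PKA_NTERM))
    charge -= 1.0 / (1.0 + 10.0 ** (PKA_CTERM - ph))
    for aa, pka in PKA_POSITIVE.items():
        charge += counts.get(aa, 0) / (1.0 + 10.0 ** (ph - pka))
    for aa, pka in PKA_NEGATIVE.items():
        charge -= counts.get(aa, 0) / (1.0 + 10.0 ** (pka - ph))
    return charge


def protein_stats(protein: str) -> ProteinStats:
    """Average-isotopic mass and isoelectric point of a protein sequence.

    Mass is the sum of residue masses plus one water.  The pI is found by
    bisection on the Henderson-Hasselbalch net charge using the EMBOSS pKa
    set (N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1,
    C 8.5, Y 10.1).
    """
    protein = protein.upper().rstrip("*")
    if not protein:
        raise ValueError("empty protein sequence")
    for i, aa in enumerate(protein, start=1):
        if aa not in RESIDUE_MASS:
            raise ValueError(f"unknown amino acid {aa!r} at position {i}")
    mass = sum(RESIDUE_MASS[aa] for aa in protein) + WATER_MASS
    counts: dict[str, int] = {}
    for aa in protein:
        counts[aa] = counts.get(aa, 0) + 1
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-6:
        mid = (lo + hi) / 2.0
        if _net_charge(counts, len(protein), mid) > 0:
            lo = mid
        else:
            hi = mid
    return ProteinStats(
        length_aa=len(protein),
        molecular_mass=mass,
        isoelectric_point=(lo + hi) / 2.0,
    )


def _paired(a: str, b: str, allow_wobble: bool) -> bool:
    if (a, b) in _WC_PAIRS:
        return True
    return allow_wobble and (a, b) in _WOBBLE_PAIRS


def detect_ire(
    seq: NucleotideSequence,
    loop_motif: str = "CAGUGA",
    upper_stem_pairs: int = 5,
    lower_stem_min: int = 3,
    bulge_base: str = "C",
    allow_wobble: bool = True,
) -> list[IreMatch]:
    """Scan for consensus iron-responsive-element stem-loops.

    For every occurrence of ``loop_motif`` the scanner requires, reading
    outward from the loop: ``upper_stem_pairs`` consecutive complementary
    pairs (Watson-Crick, plus G.U wobble unless disabled), a single
    unpaired ``bulge_base`` on the 5' arm immediately below the upper stem,
    and at least ``lower_stem_min`` further consecutive pairs bridging the
    bulge.  ``lower_stem_pairs`` in the result is the maximal consecutive
    run found, which may exceed the minimum.

    Matches are reported 5' to 3' and never overlap; detection is invariant
    under T/U substitution and case.
    """
    rna = seq.as_rna()
    motif = loop_motif.upper().replace("T", "U")
    k = len(motif)
    matches: list[IreMatch] = []
    taken_until = 0  # 0-based exclusive end of the previous match
    for m in re.finditer(f"(?={re.escape(motif)})", rna):
        loop0 = m.start()
        upper5_start = loop0 - upper_stem_pairs
        bulge0 = upper5_start - 1
        if bulge0 - lower_stem_min < 0:
            continue
        if loop0 + k + upper_stem_pairs + lower_stem_min > len(rna):
            continue
        if not all(
            _paired(rna[loop0 - 1 - i], rna[loop0 + k + i], allow_wobble)
            for i in range(upper_stem_pairs)
        ):
            continue
        if rna[bulge0] != bulge_base.upper().replace("T", "U"):
            continue
        # maximal consecutive lower-stem run, bridging the bulged base
        lower = 0
        while (
            bulge0 - 1 - lower >= 0
            and loop0 + k + upper_stem_pairs + lower < len(rna)
            and _paired(
                rna[bulge0 - 1 - lower],
                rna[loop0 + k + upper_stem_pairs + lower],
                allow_wobble,
            )
        ):
            lower += 1
        if lower < lower_stem_min:
            continue
        start0 = bulge0 - lower
        end0 = loop0 + k + upper_stem_pairs + lower - 1
        if start0 < taken_until:
            continue
        matches.append(
            IreMatch(
                start=start0 + 1,
                end=end0 + 1,
                loop_seq=motif,
                loop_start=loop0 + 1,
                bulge_pos=bulge0 + 1,
                upper_stem_pairs=upper_stem_pairs,
                lower_stem_pairs=lower,
            )
        )
        taken_until = end0 + 1
    return matches


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def map_exons(
    cdna: NucleotideSequence,
    genomic: NucleotideSequence,
    min_intron: int = 4,
) -> GeneModel:
    """Infer exon/intron structure by spliced exact anchoring.

    The first exon is anchored at the genomic position where the cDNA
    prefix extends furthest (leftmost on ties); from there the longest
    exact match of the remaining cDNA is extended as the current exon.  At
    each mismatch boundary, candidate splice points are tried in order of
    decreasing exon extension, requiring the intron to begin with GT and
    end with AG, and acceptor sites are preferred by how far they extend
    the next exon.  Backtracking guarantees the first fully reconstructing
    model under that preference order is returned; exon concatenation then
    equals the cDNA byte for byte.

    Raises ``SpliceMappingError`` (carrying the furthest cDNA coordinate
    reached) when no GT/AG-consistent reconstruction exists.
    """
    c = cdna.as_dna()
    g = genomic.as_dna()
    if len(c) > len(g):
        raise ValueError("cDNA longer than genomic sequence")
    furthest = 0

    def search(ci: int, gi: int) -> Optional[list[tuple[int, int]]]:
        nonlocal furthest
        ext = _common_prefix_len(c[ci:], g[gi:])
        furthest = max(furthest, ci + ext)
        if ci + ext == len(c):
            return [(gi, gi + ext - 1)]
        for e in range(ext, 0, -1):
            donor0 = gi + e
            if g[donor0 : donor0 + 2] != "GT":
                continue
            remaining = len(c) - (ci + e)
            candidates: list[tuple[int, int]] = []  # (-next_ext, acceptor_end0)
            j = donor0 + min_intron  # 0-based position just past the intron
            limit = len(g) - remaining
            while j <= limit:
                if g[j - 2 : j] == "AG":
                    nxt = _common_prefix_len(c[ci + e :], g[j:])
                    if nxt > 0:
                        candidates.append((-nxt, j))
                j += 1
            candidates.sort()
            for _neg_ext, j in candidates:
                tail = search(ci + e, j)
                if tail is not None:
                    return [(gi, gi + e - 1)] + tail
        return None

    anchors: list[tuple[int, int]] = []  # (-extension, genomic_pos0)
    for i in range(len(g)):
        if g[i] != c[0]:
            continue
        ext = _common_prefix_len(c, g[i:])
        anchors.append((-ext, i))
    anchors.sort()

    exons0: Optional[list[tuple[int, int]]] = None
    for _neg_ext, i in anchors:
        exons0 = search(0, i)
        if exons0 is not None:
            break
    if exons0 is None:
        raise SpliceMappingError(
            f"cDNA not reconstructable from genomic sequence; matched "
            f"{furthest}/{len(c)} nt",
            furthest_cdna_pos=furthest,
        )
    exons = tuple((s + 1, e + 1) for s, e in exons0)
    introns = tuple(
        (
            e1 + 1,
            s2 - 1,
            g[e1 : e1 + 2],
            g[s2 - 3 : s2 - 1],
        )
        for (_s1, e1), (s2, _e2) in zip(exons, exons[1:])
    )
    model = GeneModel(
        exons=exons,
        introns=introns,
        total_genomic_length=len(g),
    )
    assert model.spliced(g) == c
    return model
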