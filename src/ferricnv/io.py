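"""Readers and writers for the delimited-text and FASTA interchange formats.

Tables are comma- or tab-delimited with a header row; the delimiter is
sniffed.  Sequences use FASTA via Biopython.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO

from ferricnv.assoc import PhenotypeRecord
from ferricnv.qpcr import CtWell, CopyNumberResult, DilutionPoint, results_to_frame
from ferricnv.seqfeat import NucleotideSequence

CT_COLUMNS = ["sample_id", "assay", "replicate", "ct"]
DILUTION_COLUMNS = ["log10_quantity", "replicate", "ct"]
PHENOTYPE_COLUMNS = ["sample_id", "shell_length", "shell_width", "body_weight"]


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return frame


def read_ct_table(path: "str | Path") -> list[CtWell]:
    frame = _read_table(path, CT_COLUMNS)
    return [
        CtWell(
            sample_id=str(r.sample_id),
            assay=str(r.assay),
            replicate=int(r.replicate),
            ct=float(r.ct),
        )
        for r in frame.itertuples()
    ]


def write_ct_table(wells: Sequence[CtWell], path: "str | Path") -> None:
    pd.DataFrame(
        {
            "sample_id": [w.sample_id for w in wells],
            "assay": [w.assay for w in wells],
            "replicate": [w.replicate for w in wells],
            "ct": [w.ct for w in wells],
        }
    ).to_csv(path, sep="\t", index=False)


def read_dilution_table(path: "str | Path") -> list[DilutionPoint]:
    frame = _read_table(path, DILUTION_COLUMNS)
    return [
        DilutionPoint(
            log10_quantity=float(r.log10_quantity),
            ct=float(r.ct),
            replicate=int(r.replicate),
        )
        for r in frame.itertuples()
    ]


def write_dilution_table(points: Sequence[DilutionPoint], path: "str | Path") -> None:
    pd.DataFrame(
        {
            "log10_quantity": [p.log10_quantity for p in points],
            "replicate": [p.replicate for p in points],
            "ct": [p.ct for p in points],
        }
    ).to_csv(path, sep="\t", index=False)


def read_phenotype_table(path: "str | Path") -> list[PhenotypeRecord]:
    frame = _read_table(path, PHENOTYPE_COLUMNS)
    return [
        PhenotypeRecord(
            sample_id=str(r.sample_id),
            shell_length=float(r.shell_length),
            shell_width=float(r.shell_width),
            body_weight=float(r.body_weight),
        )
        for r in frame.itertuples()
    ]


def write_phenotype_table(records: Sequence[PhenotypeRecord], path: "str | Path") -> None:
    pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in records],
            "shell_length": [p.shell_length for p in records],
            "shell_width": [p.shell_width for p in records],
            "body_weight": [p.body_weight for p in records],
        }
    ).to_csv(path, sep="\t", index=False)


def write_genotype_table(results: Sequence[CopyNumberResult], path: "str | Path") -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)


def read_genotype_table(path: "str | Path") -> list[tuple[str, Optional[int]]]:
    """Read a genotype TSV back as (sample_id, call-or-None) pairs."""
    frame = _read_table(path, ["sample_id", "call"])
    calls: list[tuple[str, Optional[int]]] = []
    for r in frame.itertuples():
        call = None if pd.isna(r.call) else int(r.call)
        calls.append((str(r.sample_id), call))
    return calls


def read_fasta(path: "str | Path") -> list[NucleotideSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return [NucleotideSequence(id=r.id, residues=str(r.seq)) for r in records]


def read_single_fasta(path: "str | Path") -> NucleotideSequence:
    records = read_fasta(path)
    if len(records) > 1:
        raise ValueError(f"{path}: expected a single FASTA record, got {len(records)}")
    return records[0]
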