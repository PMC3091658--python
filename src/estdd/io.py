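"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA + phred ``.qual`` pairs and Sanger FASTQ go through Biopython's SeqIO;
tables (membership, mask report, truth, DE) are TSV with one header row.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import MaskReport, Read, SimTruth

_LIB_RE = re.compile(r"library=(\S+)")


def _library_from_description(desc: str, fallback: str) -> str:
    m = _LIB_RE.search(desc)
    return m.group(1) if m else fallback


def read_fasta_qual(
    fasta_path: str | Path, qual_path: str | Path, library: Optional[str] = None
) -> list[Read]:
    """Load paired FASTA/qual files, matching records by ID (order-insensitive)."""
    quals = {r.id: r.letter_annotations["phred_quality"] for r in SeqIO.parse(str(qual_path), "qual")}
    reads = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in quals:
            raise ValueError(f"record {rec.id} present in FASTA but absent from qual file")
        lib = library or _library_from_description(rec.description, "")
        if not lib:
            raise ValueError(f"record {rec.id}: no library label given or found in description")
        reads.append(Read(rec.id, lib, str(rec.seq).upper(), list(quals[rec.id])))
    if len(quals) != len(reads):
        extra = set(quals) - {r.id for r in reads}
        raise ValueError(f"qual records without FASTA partner: {sorted(extra)[:5]}")
    return reads


def read_fastq(path: str | Path, library: Optional[str] = None) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        lib = library or _library_from_description(rec.description, "")
        if not lib:
            raise ValueError(f"record {rec.id}: no library label given or found in description")
        reads.append(Read(rec.id, lib, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]))
    return reads


def _records(reads: Iterable[Read]) -> list[SeqRecord]:
    recs = []
    for r in reads:
        desc = f"library={r.library}"
        if "origin" in r.annotations:
            s, e = r.annotations["origin"]
            desc += f" origin={s}..{e}"
        rec = SeqRecord(Seq(r.bases), id=r.id, description=desc)
        rec.letter_annotations["phred_quality"] = list(r.quals)
        recs.append(rec)
    return recs


def write_fasta_qual(reads: Iterable[Read], fasta_path: str | Path, qual_path: str | Path) -> None:
    recs = _records(reads)
    SeqIO.write(recs, str(fasta_path), "fasta")
    SeqIO.write(recs, str(qual_path), "qual")


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    SeqIO.write(_records(reads), str(path), "fastq")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain FASTA as an id -> sequence mapping (vector files, consensus files)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()], str(path), "fasta"
    )


# --- tables ---------------------------------------------------------------

def write_membership(rows: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    df = pd.DataFrame(rows, columns=["unisequence_id", "read_id", "library"])
    df.to_csv(path, sep="\t", index=False)


def read_membership(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["unisequence_id", "read_id", "library"]
    if list(df.columns) != expected:
        raise ValueError(f"membership file must have columns {expected}, got {list(df.columns)}")
    return df


def write_mask_report(reports: Iterable[MaskReport], path: str | Path) -> None:
    rows = [
        (rep.read_id, cause, start, end)
        for rep in reports
        for start, end, cause in rep.masks
    ]
    pd.DataFrame(rows, columns=["read_id", "cause", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def write_truth(truth: SimTruth, path: str | Path) -> None:
    rows = [
        (
            t,
            truth.abundance_a[t],
            truth.abundance_b[t],
            truth.counts_a.get(t, 0),
            truth.counts_b.get(t, 0),
            int(truth.de_flag(t)),
        )
        for t in sorted(truth.abundance_a)
    ]
    pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            f"abundance_{truth.library_a}",
            f"abundance_{truth.library_b}",
            f"reads_{truth.library_a}",
            f"reads_{truth.library_b}",
            "de_flag",
        ],
    ).to_csv(path, sep="\t", index=False)
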