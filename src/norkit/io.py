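"""File I/O: FASTA, BED and VCF-like variant tables.

Internal coordinates are 1-based inclusive throughout the package; BED export
converts to 0-based half-open and import converts back.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_FASTA_ALPHABET = set("ACGTN")


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercase sequence) pairs.

    Duplicate ids and characters outside A/C/G/T/N raise ValueError, the
    latter naming the record and 1-based offset of the first bad character.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        for i, c in enumerate(seq):
            if c not in _FASTA_ALPHABET:
                raise ValueError(
                    f"record {rec.id!r}: non-IUPAC character {c!r} at position {i + 1}"
                )
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> str:
    """Write (id, sequence) pairs as wrapped FASTA; returns the path."""
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    if not recs:
        raise ValueError("no records to write")
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(recs)
    return os.fspath(path)


def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def from_bed_interval(bed_start: int, bed_end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return bed_start + 1, bed_end


def write_bed(intervals: Sequence[tuple[str, int, int, str]], path: str | os.PathLike) -> str:
    """Write (chrom, start, end, name) with 1-based inclusive coords as BED."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            b0, b1 = to_bed_interval(start, end)
            fh.write(f"{chrom}\t{b0}\t{b1}\t{name}\n")
    return os.fspath(path)


def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int, str]]:
    """Read BED; returns (chrom, start, end, name) with 1-based inclusive coords.

    Malformed lines raise ValueError with their line number.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}")
            try:
                b0, b1 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}") from exc
            if b1 < b0:
                raise ValueError(f"{path}: malformed BED line {lineno}: end < start")
            name = parts[3] if len(parts) > 3 else ""
            start, end = from_bed_interval(b0, b1)
            out.append((parts[0], start, end, name))
    return out


VARIANT_COLUMNS = ["CHROM", "POS", "REF", "ALT", "TYPE", "REGION"]


def write_variant_table(df: pd.DataFrame, path: str | os.PathLike) -> str:
    """Write a VCF-like TSV of variants (CHROM = unit id, POS 1-based)."""
    df.loc[:, VARIANT_COLUMNS].to_csv(path, sep="\t", index=False)
    return os.fspath(path)


def read_variant_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str, "REF": str, "ALT": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing variant columns {missing}")
    return df
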