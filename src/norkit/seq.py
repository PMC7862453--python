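"""Shared sequence utilities: alphabets, IUPAC codes, reverse complement, random DNA."""

from __future__ import annotations

import numpy as np

DNA = "ACGT"

# IUPAC nucleotide codes mapped to the set of concrete bases they stand for.
# 'N' in a *sequence* is never matched by any motif letter (the sets below are
# used for motif letters only; sequence characters must be one of A/C/G/T to match).
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement; accepts IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_iupac_motif(motif: str) -> bool:
    return len(motif) > 0 and all(c in IUPAC for c in motif.upper())


def validate_dna(seq: str, allow_n: bool = True) -> None:
    """Raise ValueError naming the first offending position (1-based)."""
    allowed = set("ACGTN" if allow_n else "ACGT")
    for i, c in enumerate(seq):
        if c not in allowed:
            raise ValueError(f"non-IUPAC character {c!r} at position {i + 1}")


def random_dna(rng: np.random.Generator, length: int, gc_content: float = 0.5) -> str:
    """i.i.d. nucleotides at the given GC fraction."""
    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    idx = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return "".join(DNA[i] for i in idx)


def rotate(seq: str, offset: int) -> str:
    """Rotate a circular sequence so that position ``offset`` (0-based) comes first."""
    if not seq:
        return seq
    offset %= len(seq)
    return seq[offset:] + seq[:offset]
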