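"""Post-assembly finishing of circular clones and contig merging.

A linearized assembly of a circular TAR/BAC clone carries the vector, the
cloned insert, an arbitrary rotation, and often a duplicated terminal segment
(circular overlap). Finishing removes the duplicated terminus, locates and
removes the vector (exactly, or by approximate alignment for consensus
error), re-orients the result to start at the first base after the removed
vector on the input strand, and verifies the targeting hooks are present.

Finished inserts are then merged into larger contigs through their terminal
suffix/prefix overlaps, using exact k-mer seeding so that ~100 kb inserts
merge in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np


def _as_bytes(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _mismatches(a: str, b: str) -> int:
    """Hamming distance of two equal-length strings (vectorized)."""
    if len(a) != len(b):
        raise ValueError("length mismatch")
    if not a:
        return 0
    return int((_as_bytes(a) != _as_bytes(b)).sum())


def trim_circular_overlap(
    sequence: str, min_overlap: int = 100, max_divergence: float = 0.01
) -> tuple[str, int]:
    """Collapse a duplicated terminal segment once; returns (sequence, removed bp).

    The longest suffix matching the prefix at <= ``max_divergence`` mismatch
    rate, with length in [min_overlap, len/2), is removed from the end.
    Idempotent in the absence of further duplication; (sequence, 0) when no
    qualifying overlap exists.
    """
    n = len(sequence)
    for L in range((n - 1) // 2, min_overlap - 1, -1):
        if _mismatches(sequence[:L], sequence[n - L :]) <= max_divergence * L:
            return sequence[: n - L], L
    return sequence, 0


@dataclass
class FinishedClone:
    """A clone assembly after vector removal, trimming and re-orientation."""

    insert: str
    vector_interval_removed: tuple[int, int]  # 1-based inclusive, on the trimmed circle
    circular_overlap_removed: int
    reoriented_offset: int
    hooks_found: dict[str, bool] = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        return all(self.hooks_found.values()) if self.hooks_found else True


class VectorAbsentError(RuntimeError):
    pass


def _locate_vector_circular(
    circle: str, vector: str, min_identity: float = 0.95, min_coverage: float = 0.90
) -> tuple[int, int]:
    """0-based [start, end) of the vector on the circle (may wrap).

    Exact match first; otherwise the best infix alignment, accepted at
    >= ``min_identity`` over >= ``min_coverage`` of the vector length.
    """
    vl = len(vector)
    doubled = circle + circle[: vl + max(50, vl // 10)]
    i = doubled.find(vector)
    if i != -1 and i < len(circle):
        return i, i + vl
    max_edits = int((1.0 - min_identity) * vl)
    res = edlib.align(vector, doubled, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] == -1 or not res["locations"]:
        raise VectorAbsentError("vector absent")
    s, e = res["locations"][0]
    e += 1  # edlib end is inclusive
    if (e - s) < min_coverage * vl:
        raise VectorAbsentError("vector absent")
    if s >= len(circle):
        s -= len(circle)
        e -= len(circle)
    return s, e


def finish_assembly(
    assembly: str,
    vector: str,
    hooks: dict[str, str] | None = None,
    min_overlap: int = 100,
    max_divergence: float = 0.01,
    min_identity: float = 0.95,
    min_coverage: float = 0.90,
) -> FinishedClone:
    """Finish a (rotated, overlap-bearing) linearization of a circular clone.

    After trimming the circular overlap, the sequence is treated as an exact
    circle: the vector is located (exact, or best local alignment at
    >= ``min_identity`` over >= ``min_coverage`` of its length), removed, and
    the insert re-oriented to begin at the first base after the vector on the
    input strand. Hooks, when given, are verified by exact occurrence; a
    missing hook flags the clone invalid (no exception).
    """
    trimmed, removed = trim_circular_overlap(assembly, min_overlap, max_divergence)
    s, e = _locate_vector_circular(trimmed, vector, min_identity, min_coverage)
    n = len(trimmed)
    if e <= n:
        insert = trimmed[e:] + trimmed[:s]
        offset = e
    else:  # vector wraps the linearization point
        insert = trimmed[e - n : s]
        offset = e - n
    hooks_found = {}
    for name, hseq in (hooks or {}).items():
        hooks_found[name] = hseq in insert
    return FinishedClone(
        insert=insert,
        vector_interval_removed=(s + 1, e if e <= n else e - n),
        circular_overlap_removed=removed,
        reoriented_offset=offset,
        hooks_found=hooks_found,
    )


@dataclass
class ContigMerge:
    """Result of merging two inserts through a terminal overlap."""

    contig: str
    overlap_length: int
    mismatches_in_overlap: int
    source_ids: tuple[str, str]
    orientation: str  # e.g. "A+B" (A then B, both forward), "B+A", "A+revcomp(B)" ...

    def check(self, len_a: int, len_b: int) -> None:
        if len(self.contig) != len_a + len_b - self.overlap_length:
            raise AssertionError("contig length != |A| + |B| - overlap")


class MergeError(RuntimeError):
    def __init__(self, message: str, best_candidate: tuple[int, int] | None = None):
        super().__init__(message)
        self.best_candidate = best_candidate  # (overlap length, mismatches)


def _overlap_candidates(a: str, b: str, min_overlap: int, k: int = 31, stride: int = 7) -> list[int]:
    """Candidate suffix(a)/prefix(b) overlap lengths from shared exact k-mers."""
    nmax = min(len(a), len(b)) - 1
    if nmax < min_overlap:
        return []
    if len(a) <= 4000 and len(b) <= 4000:
        return list(range(nmax, min_overlap - 1, -1))
    # index k-mers of a's tail, then look up sampled k-mers of b's head
    tail_start = len(a) - nmax
    index: dict[str, list[int]] = {}
    tail = a[tail_start:]
    for i in range(0, len(tail) - k + 1):
        index.setdefault(tail[i : i + k], []).append(tail_start + i)
    cands = set()
    for q in range(0, min(nmax, len(b)) - k + 1, stride):
        for p in index.get(b[q : q + k], ()):
            L = len(a) - p + q
            if min_overlap <= L <= nmax:
                cands.add(L)
    return sorted(cands, reverse=True)


def _best_overlap(a: str, b: str, min_overlap: int, max_mismatch_rate: float):
    """Longest qualifying suffix(a)/prefix(b) overlap.

    Returns (hit, best_sub) where hit is (length, mismatches) or None, and
    best_sub is the lowest-rate sub-threshold candidate seen (or None).
    """
    best_sub = None
    for L in _overlap_candidates(a, b, min_overlap):
        mm = _mismatches(a[len(a) - L :], b[:L])
        if mm <= max_mismatch_rate * L:
            return (L, mm), best_sub
        if best_sub is None or mm / L < best_sub[1] / best_sub[0]:
            best_sub = (L, mm)
    return None, best_sub


_RC = str.maketrans("ACGTN", "TGCAN")


def merge_inserts(
    insert_a: str,
    insert_b: str,
    min_overlap: int = 100,
    max_mismatch_rate: float = 0.01,
    id_a: str = "A",
    id_b: str = "B",
) -> ContigMerge:
    """Merge two inserts through their maximal terminal overlap.

    Both orders and both strands of B are tried; the longest overlap at
    <= ``max_mismatch_rate`` wins (fewest mismatches among equals). Overlaps
    equal to a whole input are rejected (degenerate containment guard).
    Raises :class:`MergeError`, reporting the best sub-threshold candidate,
    when nothing qualifies.
    """
    b_rc = insert_b.translate(_RC)[::-1]
    attempts = [
        (insert_a, insert_b, f"{id_a}+{id_b}"),
        (insert_b, insert_a, f"{id_b}+{id_a}"),
        (insert_a, b_rc, f"{id_a}+revcomp({id_b})"),
        (b_rc, insert_a, f"revcomp({id_b})+{id_a}"),
    ]
    results = []
    best_sub = None
    for left, right, label in attempts:
        hit, sub = _best_overlap(left, right, min_overlap, max_mismatch_rate)
        if hit is not None:
            results.append((hit[0], hit[1], left, right, label))
        elif sub is not None:
            if best_sub is None or sub[1] / sub[0] < best_sub[1] / best_sub[0]:
                best_sub = sub
    if not results:
        raise MergeError(
            "no qualifying terminal overlap"
            + (f"; best candidate {best_sub[0]} bp with {best_sub[1]} mismatches" if best_sub else ""),
            best_candidate=best_sub,
        )
    results.sort(key=lambda r: (-r[0], r[1]))
    L, mm, left, right, label = results[0]
    contig = left + right[L:]
    merge = ContigMerge(
        contig=contig,
        overlap_length=L,
        mismatches_in_overlap=mm,
        source_ids=(id_a, id_b),
        orientation=label,
    )
    merge.check(len(insert_a), len(insert_b))
    return merge
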