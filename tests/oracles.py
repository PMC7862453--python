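"""Independent brute-force oracles used to check the package's fast paths.

Everything here is deliberately simple and slow: naive scans, exhaustive
enumeration, unbanded dynamic programming. None of it shares code with the
implementation under test.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
         "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
         "B": "V", "V": "B", "D": "H", "H": "D"}


def rc(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def naive_scan(sequence: str, motif: str) -> list[int]:
    """Per-position IUPAC matcher, both strands, 1-based starts, deduplicated."""
    hits = set()
    for pat in (motif, rc(motif)):
        k = len(pat)
        for i in range(len(sequence) - k + 1):
            if all(sequence[i + t] in IUPAC_SETS[pat[t]] for t in range(k)):
                hits.add(i + 1)
    return sorted(hits)


def longest_suffix_prefix(s: str, min_overlap: int, max_divergence: float) -> int:
    """Brute-force longest terminal suffix/prefix match (< len/2)."""
    n = len(s)
    for L in range((n - 1) // 2, min_overlap - 1, -1):
        mm = sum(1 for a, b in zip(s[:L], s[n - L:]) if a != b)
        if mm <= max_divergence * L:
            return L
    return 0


def best_suffix_prefix_overlap(a: str, b: str, min_overlap: int, max_rate: float):
    """Brute force over every suffix(a)/prefix(b) length; longest qualifying."""
    for L in range(min(len(a), len(b)) - 1, min_overlap - 1, -1):
        mm = sum(1 for x, y in zip(a[-L:], b[:L]) if x != y)
        if mm <= max_rate * L:
            return L, mm
    return None


def gotoh_score(a: str, b: str, match=1, mismatch=-2, gap_open=-5, gap_extend=-1) -> int:
    """Unbanded affine-gap global alignment score (gap of L costs open+L*ext).

    Row-vectorized three-state DP with a prefix-max scan for the horizontal
    state; structurally unrelated to the banded implementation.
    """
    m, n = len(a), len(b)
    NEG = -(10**12)
    av = np.frombuffer(a.encode(), np.uint8)
    bv = np.frombuffer(b.encode(), np.uint8)
    M = np.full(n + 1, NEG, np.int64)
    X = np.full(n + 1, NEG, np.int64)
    Y = np.full(n + 1, NEG, np.int64)
    M[0] = 0
    if n:
        Y[1:] = gap_open + gap_extend * np.arange(1, n + 1)
    jj = np.arange(n + 1)
    for i in range(1, m + 1):
        Mp, Xp, Yp = M, X, Y
        s = np.where(bv == av[i - 1], match, mismatch)
        X = np.maximum(np.maximum(Mp, Yp) + gap_open + gap_extend, Xp + gap_extend)
        X[0] = gap_open + gap_extend * i
        diag = np.maximum(np.maximum(Mp[:-1], Xp[:-1]), Yp[:-1])
        M = np.full(n + 1, NEG, np.int64)
        M[1:] = diag + s
        base = np.maximum(M, X)
        t = base + gap_open - gap_extend * jj
        Y = np.full(n + 1, NEG, np.int64)
        if n:
            Y[1:] = np.maximum.accumulate(t[:-1]) + gap_extend * jj[1:]
    return int(max(M[n], X[n], Y[n]))


def gotoh_score_tiny(a: str, b: str, match=1, mismatch=-2, gap_open=-5, gap_extend=-1) -> int:
    """Plain recursive affine aligner for very short strings (oracle's oracle)."""

    @lru_cache(maxsize=None)
    def go(i, j, state):
        # state: 0 start/match, 1 in a-gap, 2 in b-gap
        if i == len(a) and j == len(b):
            return 0
        best = -(10**9)
        if i < len(a) and j < len(b):
            best = max(best, (match if a[i] == b[j] else mismatch) + go(i + 1, j + 1, 0))
        if i < len(a):
            cost = gap_extend if state == 1 else gap_open + gap_extend
            best = max(best, cost + go(i + 1, j, 1))
        if j < len(b):
            cost = gap_extend if state == 2 else gap_open + gap_extend
            best = max(best, cost + go(i, j + 1, 2))
        return best

    return go(0, 0, 0)


_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def enumerate_structures(seq: str, min_loop: int = 3) -> list[frozenset]:
    """Every pseudoknot-free pair set over the sequence (1-based pairs)."""
    seq = seq.upper().replace("T", "U")
    n = len(seq)

    @lru_cache(maxsize=None)
    def gen(i: int, j: int) -> frozenset:
        # structures over positions i..j inclusive (0-based), as a frozenset of frozensets
        if j - i < min_loop + 1:
            return frozenset([frozenset()])
        out = set(gen(i + 1, j))
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in _PAIRS:
                left = gen(i + 1, k - 1)
                right = gen(k + 1, j) if k + 1 <= j else frozenset([frozenset()])
                for L in left:
                    for R in right:
                        out.add(L | R | {(i + 1, k + 1)})
        return frozenset(out)

    return list(gen(0, n - 1)) if n else [frozenset()]


def score_structure(seq: str, pairs: frozenset, model: str, stack_bonus: int = 1) -> int:
    """Score a pair set under the named model (pair weights + stacking bonus)."""
    seq = seq.upper().replace("T", "U")
    weights = (
        {"AU": 1, "UA": 1, "CG": 1, "GC": 1, "GU": 1, "UG": 1}
        if model == "maxpair"
        else {"AU": 2, "UA": 2, "CG": 3, "GC": 3, "GU": 1, "UG": 1}
    )
    bonus = stack_bonus if model == "stack" else 0
    total = 0
    for i, j in pairs:
        total += weights[seq[i - 1] + seq[j - 1]]
        if (i + 1, j - 1) in pairs:
            total += bonus
    return total


def best_score(seq: str, model: str, min_loop: int = 3,
               forced_unpaired: tuple[int, int] | None = None) -> int:
    """Exhaustive optimum; optionally over structures leaving an interval unpaired."""
    best = 0
    for pairs in enumerate_structures(seq, min_loop):
        if forced_unpaired is not None:
            lo, hi = forced_unpaired
            if any(lo <= i <= hi or lo <= j <= hi for i, j in pairs):
                continue
        best = max(best, score_structure(seq, pairs, model))
    return best


def mww_exact_p(x, y) -> float:
    """Two-sided exact MWW p by full labeling enumeration (ties at 0.5)."""
    x, y = list(x), list(y)
    pooled = x + y
    nx = len(x)

    def u_of(xs, ys):
        return sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys)

    u_obs = u_of(x, y)
    lo = hi = total = 0
    for comb in itertools.combinations(range(len(pooled)), nx):
        cs = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in cs]
        u = u_of(xs, ys)
        total += 1
        lo += u <= u_obs
        hi += u >= u_obs
    return min(1.0, 2.0 * min(lo / total, hi / total))


def feature_overlap_brute(pos: int, features, proximity: int):
    """Naive proximity scan; returns [(name, signed distance)]."""
    out = []
    for name, start, end in features:
        if pos < start:
            d = pos - start
        elif pos > end:
            d = pos - end
        else:
            d = 0
        if abs(d) <= proximity:
            out.append((name, d))
    return out
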