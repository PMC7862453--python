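"""Exhaustive secondary-structure enumerator used by the acceptance script to
verify the dynamic-programming fold models independently."""

from __future__ import annotations

from functools import lru_cache

_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def enumerate_structures(seq: str, min_loop: int = 3):
    seq = seq.upper().replace("T", "U")
    n = len(seq)

    @lru_cache(maxsize=None)
    def gen(i: int, j: int) -> frozenset:
        if j - i < min_loop + 1:
            return frozenset([frozenset()])
        out = set(gen(i + 1, j))
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in _PAIRS:
                for left in gen(i + 1, k - 1):
                    for right in gen(k + 1, j) if k + 1 <= j else [frozenset()]:
                        out.add(left | right | {(i + 1, k + 1)})
        return frozenset(out)

    return list(gen(0, n - 1)) if n else [frozenset()]


def score_structure(seq: str, pairs, model: str, stack_bonus: int = 1) -> int:
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


def best_score(seq: str, model: str, min_loop: int = 3) -> int:
    return max(
        (score_structure(seq, p, model) for p in enumerate_structures(seq, min_loop)),
        default=0,
    )
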