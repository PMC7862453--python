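"""RNA secondary-structure impact scoring for allelic variants.

Two exact dynamic-programming folding models are built in:

* ``maxpair`` — base-pair maximization (Nussinov-style) over Watson-Crick
  and GU wobble pairs;
* ``stack`` — weighted pairs (GC=3, AU=2, GU=1) with a bonus for each
  stacked pair, a coarse nearest-neighbor stand-in.

Both are exact and desk-verifiable against exhaustive enumeration; an
external thermodynamic backend (e.g. a ViennaRNA wrapper) can be plugged in
through the ``backend`` hook of :class:`FoldParams` and must return the same
:class:`SecondaryStructure` type. Scores are in model units, not kcal/mol.

On top of folding the module provides: the opening penalty dG_open (cost of
forcing an interval unpaired), the structural index D between two structures
(Euclidean norm of the difference of their base-pair indicator vectors, i.e.
sqrt of the symmetric-difference count), composition-preserving
randomization nulls with empirical P-values (r+1)/(n+1) and z-scores, the
two-sided Mann-Whitney-Wilcoxon test (exact by enumeration for small
samples), and riboSNitch calling for allelic variants.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numba import njit
from scipy import stats as sps

from .align import align_units
from .variants import left_normalize

_NEGS = -1_000_000

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}


def _encode_rna(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"not an RNA/DNA base: {exc.args[0]!r}") from exc


def _score_matrix(model: str) -> np.ndarray:
    s = np.zeros((4, 4), dtype=np.int32)
    if model == "maxpair":
        au, gc, gu = 1, 1, 1
    elif model == "stack":
        au, gc, gu = 2, 3, 1
    else:
        raise ValueError(f"unknown fold model {model!r}")
    s[0, 3] = s[3, 0] = au
    s[1, 2] = s[2, 1] = gc
    s[2, 3] = s[3, 2] = gu
    return s


@dataclass
class FoldParams:
    """Folding parameters. ``window`` is the analysis window for variant
    scoring (100 and 350 nt are the conventional choices); ``step`` the
    scan step. ``backend`` may be a callable (sequence, params) ->
    SecondaryStructure replacing the built-in models."""

    model: str = "maxpair"
    min_loop: int = 3
    window: int = 100
    step: int = 10
    stack_bonus: int = 1
    backend: Callable | None = None

    def __post_init__(self) -> None:
        if self.window < 2 * self.min_loop:
            raise ValueError("window must be at least 2*min_loop")
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure: set of 1-based pairs (i<j)."""

    length: int
    pairs: frozenset[tuple[int, int]]
    score: int
    model: str = "maxpair"

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"invalid pair ({i},{j})")
            if i in seen or j in seen:
                raise ValueError("a base participates in two pairs")
            seen.update((i, j))
        for (i, j), (k, l) in itertools.combinations(sorted(self.pairs), 2):
            if i < k < j < l:
                raise ValueError("crossing pairs (pseudoknot)")

    @property
    def partner(self) -> np.ndarray:
        p = np.zeros(self.length + 1, dtype=np.int64)
        for i, j in self.pairs:
            p[i], p[j] = j, i
        return p

    def dot_bracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i - 1], chars[j - 1] = "(", ")"
        return "".join(chars)

    @classmethod
    def from_dot_bracket(cls, db: str, score: int = 0, model: str = "maxpair"):
        stack: list[int] = []
        pairs = set()
        for idx, c in enumerate(db, start=1):
            if c == "(":
                stack.append(idx)
            elif c == ")":
                if not stack:
                    raise ValueError("unbalanced dot-bracket")
                pairs.add((stack.pop(), idx))
            elif c != ".":
                raise ValueError(f"bad dot-bracket character {c!r}")
        if stack:
            raise ValueError("unbalanced dot-bracket")
        return cls(len(db), frozenset(pairs), score, model)


@njit(cache=True)
def _fold_dp(code, smat, min_loop, bonus, blocked):  # pragma: no cover
    n = code.shape[0]
    W = np.zeros((n, n), np.int32)
    P = np.full((n, n), _NEGS, np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            ps = smat[code[i], code[j]]
            if ps > 0 and not blocked[i] and not blocked[j]:
                best = W[i + 1, j - 1] if i + 1 <= j - 1 else 0
                if P[i + 1, j - 1] > _NEGS:
                    v = P[i + 1, j - 1] + bonus
                    if v > best:
                        best = v
                P[i, j] = ps + best
            w = W[i + 1, j]
            if W[i, j - 1] > w:
                w = W[i, j - 1]
            if P[i, j] > w:
                w = P[i, j]
            for k in range(i + 1, j):
                v = W[i, k] + W[k + 1, j]
                if v > w:
                    w = v
            W[i, j] = w
    return W, P


def _traceback_pairs(W, P, code, smat, min_loop, bonus):
    n = code.shape[0]
    pairs: set[tuple[int, int]] = set()
    stack = [(0, n - 1, 0)]  # 0 = W, 1 = P
    while stack:
        i, j, m = stack.pop()
        if i >= j:
            continue
        if m == 0:
            if j - i <= min_loop or W[i, j] == 0:
                continue
            w = W[i, j]
            if w == W[i + 1, j]:
                stack.append((i + 1, j, 0))
                continue
            if w == W[i, j - 1]:
                stack.append((i, j - 1, 0))
                continue
            if w == P[i, j]:
                stack.append((i, j, 1))
                continue
            for k in range(i + 1, j):
                if w == W[i, k] + W[k + 1, j]:
                    stack.append((i, k, 0))
                    stack.append((k + 1, j, 0))
                    break
        else:
            pairs.add((i + 1, j + 1))  # to 1-based
            ps = smat[code[i], code[j]]
            if i + 1 <= j - 1:
                if P[i + 1, j - 1] > _NEGS and P[i, j] == ps + P[i + 1, j - 1] + bonus:
                    stack.append((i + 1, j - 1, 1))
                else:
                    stack.append((i + 1, j - 1, 0))
    return pairs


def fold(
    sequence: str,
    params: FoldParams | None = None,
    blocked: np.ndarray | None = None,
) -> SecondaryStructure:
    """Optimal structure of a sequence under the selected model.

    ``blocked`` is an optional boolean mask of positions forced unpaired.
    Sequences too short to form a loop fold to the all-unpaired structure.
    """
    params = params or FoldParams()
    if params.backend is not None and blocked is None:
        return params.backend(sequence, params)
    code = _encode_rna(sequence)
    n = len(code)
    if blocked is None:
        blocked = np.zeros(n, dtype=np.bool_)
    blocked = np.asarray(blocked, dtype=np.bool_)
    if n < params.min_loop + 2:  # too short for any pair
        return SecondaryStructure(n, frozenset(), 0, params.model)
    smat = _score_matrix(params.model)
    bonus = params.stack_bonus if params.model == "stack" else 0
    W, P = _fold_dp(code, smat, params.min_loop, bonus, blocked)
    pairs = _traceback_pairs(W, P, code, smat, params.min_loop, bonus)
    return SecondaryStructure(n, frozenset(pairs), int(W[0, n - 1]), params.model)


@dataclass(frozen=True)
class OpeningResult:
    """Score penalty for forcing an interval unpaired (>= 0; 0 iff the
    interval is already unpaired in the unconstrained optimum)."""

    interval: tuple[int, int]
    delta_g_open: int


def opening_penalty(
    sequence: str, interval: tuple[int, int], params: FoldParams | None = None
) -> OpeningResult:
    """dG_open of a 1-based inclusive interval within the sequence."""
    params = params or FoldParams()
    lo, hi = interval
    if not (1 <= lo <= hi <= len(sequence)):
        raise ValueError(f"interval {interval} outside sequence of length {len(sequence)}")
    if hi - lo + 1 > params.window:
        raise ValueError("interval longer than the analysis window")
    free = fold(sequence, params)
    mask = np.zeros(len(sequence), dtype=np.bool_)
    mask[lo - 1 : hi] = True
    constrained = fold(sequence, params, blocked=mask)
    return OpeningResult(interval, free.score - constrained.score)


def map_through_variant(length: int, pos: int, ref: str, alt: str) -> dict[int, int | None]:
    """Map reference-window positions into the variant-applied frame.

    The variant is anchored and left-normalized at ``pos``. Positions inside
    the replaced reference footprint (beyond the anchor) map to None.
    """
    delta = len(alt) - len(ref)
    m: dict[int, int | None] = {}
    for p in range(1, length + 1):
        if p <= pos:
            m[p] = p
        elif p < pos + len(ref):
            m[p] = None
        else:
            m[p] = p + delta
    return m


def structural_index(
    s1: SecondaryStructure,
    s2: SecondaryStructure,
    coordinate_map: dict[int, int | None] | None = None,
) -> float:
    """Structural index D between two structures on a common frame.

    D is the Euclidean norm of the difference of the binary base-pair
    indicator vectors: sqrt(|pairs(s1) symmetric-difference pairs(s2)|).
    With a coordinate map (for indel alleles), s1 pairs are mapped into the
    s2 frame; a pair with an unmapped endpoint counts toward the difference.
    """
    if coordinate_map is None:
        if s1.length != s2.length:
            raise ValueError("structures of different length need a coordinate map")
        mapped = set(s1.pairs)
        unmapped = 0
    else:
        mapped = set()
        unmapped = 0
        for i, j in s1.pairs:
            mi, mj = coordinate_map.get(i), coordinate_map.get(j)
            if mi is None or mj is None:
                unmapped += 1
            else:
                mapped.add((min(mi, mj), max(mi, mj)))
    return math.sqrt(len(mapped.symmetric_difference(s2.pairs)) + unmapped)


def apply_variant(sequence: str, pos: int, ref: str, alt: str) -> str:
    """Apply an anchored variant to a sequence (1-based pos)."""
    if sequence[pos - 1 : pos - 1 + len(ref)].upper().replace("T", "U") != ref.upper().replace(
        "T", "U"
    ):
        raise ValueError(f"reference allele mismatch at position {pos}")
    return sequence[: pos - 1] + alt + sequence[pos - 1 + len(ref) :]


def _statistic(
    ref_seq: str, pos: int, ref: str, alt: str, params: FoldParams, which: str
) -> float:
    alt_seq = apply_variant(ref_seq, pos, ref, alt)
    if which == "D":
        s_ref = fold(ref_seq, params)
        s_alt = fold(alt_seq, params)
        cmap = map_through_variant(len(ref_seq), pos, ref, alt)
        return structural_index(s_ref, s_alt, None if len(ref) == len(alt) else cmap)
    if which == "ddG":
        iv_ref = (pos, pos + len(ref) - 1)
        iv_alt = (pos, pos + len(alt) - 1)
        g_ref = opening_penalty(ref_seq, iv_ref, params).delta_g_open
        g_alt = opening_penalty(alt_seq, iv_alt, params).delta_g_open
        return float(abs(g_alt - g_ref))
    raise ValueError(f"unknown statistic {which!r}")


@dataclass
class NullResult:
    """A randomization null for one variant and statistic."""

    observed: float
    null: np.ndarray
    empirical_p: float
    z_score: float  # NaN when the null has zero spread
    statistic: str
    tie_broken_p: float = float("nan")
    # empirical_p uses the conservative (r+1)/(n+1) rule and is therefore
    # superuniform when the statistic ties; tie_broken_p randomizes ties and
    # is exactly uniform under the null (used for calibration checks)

    @property
    def n(self) -> int:
        return len(self.null)


def _shuffle_context(
    seq: str, footprint: tuple[int, int], rng: np.random.Generator, mode: str = "mono"
) -> str:
    """Permute the sequence outside the variant footprint (composition kept).

    ``mode='mono'`` is a mononucleotide shuffle; ``'di'`` approximates a
    dinucleotide shuffle by permuting non-overlapping 2-mers of the context.
    """
    lo, hi = footprint
    context_idx = [i for i in range(len(seq)) if not (lo - 1 <= i <= hi - 1)]
    chars = list(seq)
    ctx = [chars[i] for i in context_idx]
    if mode == "mono":
        perm = rng.permutation(len(ctx))
        shuffled = [ctx[p] for p in perm]
    elif mode == "di":
        blocks = [ctx[i : i + 2] for i in range(0, len(ctx), 2)]
        order = rng.permutation(len(blocks))
        shuffled = [c for b in order for c in blocks[b]]
    else:
        raise ValueError(f"unknown shuffle mode {mode!r}")
    for i, c in zip(context_idx, shuffled):
        chars[i] = c
    return "".join(chars)


def randomization_null(
    sequence: str,
    variant: tuple[int, str, str],
    params: FoldParams | None = None,
    statistic: str = "D",
    n: int = 100,
    seed: int | np.random.Generator = 0,
    shuffle_mode: str = "mono",
) -> NullResult:
    """Monte-Carlo null for a variant's structural statistic.

    Each replicate permutes the window outside the variant footprint
    (preserving nucleotide composition and the variant site itself),
    re-applies the variant at the same offset and recomputes the statistic.
    empirical_p = (r+1)/(n+1) with r the number of null values >= observed.
    """
    if n < 20:
        raise ValueError("n must be >= 20 for a usable null")
    params = params or FoldParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos, ref, alt = variant
    observed = _statistic(sequence, pos, ref, alt, params, statistic)
    null = np.empty(n)
    footprint = (pos, pos + len(ref) - 1)
    for t in range(n):
        shuf = _shuffle_context(sequence, footprint, rng, shuffle_mode)
        null[t] = _statistic(shuf, pos, ref, alt, params, statistic)
    r = int((null >= observed).sum())
    p = (r + 1) / (n + 1)
    n_greater = int((null > observed).sum())
    n_tied = r - n_greater
    # rank the observation uniformly among its ties (including itself)
    p_tb = (n_greater + 1 + int(rng.integers(0, n_tied + 1))) / (n + 1)
    sd = float(null.std(ddof=1))
    z = (observed - float(null.mean())) / sd if sd > 0 else float("nan")
    return NullResult(observed, null, p, z, statistic, p_tb)


def mww_test(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney-Wilcoxon test.

    Exact by enumeration of all labelings when n_x + n_y <= 12, normal
    approximation with tie correction (and continuity correction) otherwise.
    Returns (U of the first sample, p). All values tied across both samples
    gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")

    def u_of(xs, ys):
        u = 0.0
        for a in xs:
            for b in ys:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    u_obs = u_of(x, y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return u_obs, 1.0
    nx, ny = len(x), len(y)
    if nx + ny <= 12:
        lo = hi = 0
        total = 0
        for comb in itertools.combinations(range(nx + ny), nx):
            mask = np.zeros(nx + ny, dtype=bool)
            mask[list(comb)] = True
            u = u_of(pooled[mask], pooled[~mask])
            total += 1
            if u <= u_obs:
                lo += 1
            if u >= u_obs:
                hi += 1
        p = min(1.0, 2.0 * min(lo / total, hi / total))
        return u_obs, p
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=True)
    return u_obs, float(res.pvalue)


@dataclass
class ImpactResult:
    """Per-variant RNA structural impact summary."""

    variant: tuple[int, str, str]
    structural_index: float
    delta_delta_g_open: float
    empirical_p: float
    z_score: float
    mww_u: float
    mww_p: float
    ribosnitch: bool
    per_window: list[tuple[int, float, float]] = field(default_factory=list)
    # (window length, D, empirical_p) per analysis window


def _window_around(seq_len: int, pos: int, footprint: int, window: int) -> tuple[int, int]:
    """1-based window of the requested length centered on the variant, clipped."""
    half = (window - footprint) // 2
    lo = max(1, pos - half)
    hi = min(seq_len, lo + window - 1)
    lo = max(1, hi - window + 1)
    return lo, hi


def call_ribosnitch(
    reference: str,
    alternate: str,
    params: FoldParams | None = None,
    alpha: float = 0.05,
    windows: tuple[int, ...] = (100, 350),
    n: int = 100,
    seed: int = 0,
    statistic: str = "D",
    probe: int = 11,
) -> ImpactResult:
    """Score a variant between two alleles and flag potential riboSNitches.

    The first difference between the alleles (left-normalized) defines the
    variant; a window of each requested length is centered on it and a
    randomization null computed per window. The flag is set when the
    empirical P-value is <= alpha in at least one window. The MWW test
    compares the sliding-probe dG_open profiles of the two alleles over the
    largest window. alpha is applied per variant with no multiple-testing
    correction.
    """
    params = params or FoldParams()
    ref_seq = reference.upper().replace("T", "U")
    alt_seq = alternate.upper().replace("T", "U")
    if ref_seq == alt_seq:
        return ImpactResult((0, "", ""), 0.0, 0.0, 1.0, float("nan"), 0.0, 1.0, False)
    pair = align_units(ref_seq, alt_seq, band=64)
    # first difference -> one variant (pos, ref, alt) on the reference allele
    raw = None
    i = j = 1
    for op, length in pair.ops:
        if op == "M":
            for t in range(length):
                if ref_seq[i - 1 + t] != alt_seq[j - 1 + t]:
                    raw = (i + t, ref_seq[i - 1 + t], alt_seq[j - 1 + t])
                    break
            if raw:
                break
            i += length
            j += length
        elif op == "D":
            raw = (i, ref_seq[i - 1 : i - 1 + length], "")
            break
        else:
            raw = (i, "", alt_seq[j - 1 : j - 1 + length])
            break
    pos, ref, alt = left_normalize(*raw, ref_seq)
    rng = np.random.default_rng(seed)

    best = None
    per_window = []
    for w in sorted(windows):
        lo, hi = _window_around(len(ref_seq), pos, len(ref), w)
        wseq = ref_seq[lo - 1 : hi]
        wvar = (pos - lo + 1, ref, alt)
        wparams = FoldParams(
            model=params.model,
            min_loop=params.min_loop,
            window=w,
            step=params.step,
            stack_bonus=params.stack_bonus,
            backend=params.backend,
        )
        nr = randomization_null(wseq, wvar, wparams, statistic=statistic, n=n, seed=rng)
        per_window.append((w, nr.observed, nr.empirical_p))
        if best is None or nr.empirical_p < best[1].empirical_p:
            best = (w, nr, wseq, wvar, wparams)
    w, nr, wseq, wvar, wparams = best

    # ddG_open of the variant footprint in the best window
    dd = _statistic(wseq, *wvar, wparams, "ddG")

    # MWW over sliding-probe opening profiles of the two alleles
    alt_wseq = apply_variant(wseq, *wvar)
    prof_ref, prof_alt = [], []
    for start in range(1, len(wseq) - probe + 2, params.step):
        prof_ref.append(opening_penalty(wseq, (start, start + probe - 1), wparams).delta_g_open)
    for start in range(1, len(alt_wseq) - probe + 2, params.step):
        prof_alt.append(opening_penalty(alt_wseq, (start, start + probe - 1), wparams).delta_g_open)
    mu, mp = mww_test(prof_ref, prof_alt)

    flag = any(p <= alpha for (_, _, p) in per_window)
    return ImpactResult(
        variant=(pos, ref, alt),
        structural_index=nr.observed if statistic == "D" else float("nan"),
        delta_delta_g_open=dd,
        empirical_p=nr.empirical_p,
        z_score=nr.z_score,
        mww_u=mu,
        mww_p=mp,
        ribosnitch=flag,
        per_window=per_window,
    )
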