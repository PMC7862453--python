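"""Restriction-site scanning, cloning-enzyme selection, TAR hook design and
digest fragment (band) prediction.

The guiding design constraint mirrors the cloning strategy for releasing an
intact rDNA repeat array: a useful enzyme has no recognition site anywhere in
the repeat units but cuts in both junction flanks, so a single digest releases
the whole array as one fragment that can be captured between two short
(~170-200 bp) targeting hooks.

Cut positions are approximated by the motif start: both enzymes of interest
(EcoRV, ApaLI) cut within their 6-mer recognition sites, and sub-motif offsets
are far below the ~kb resolution at which band sizes are read.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

from .seq import IUPAC, is_iupac_motif, revcomp


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease as a name plus IUPAC recognition motif."""

    name: str
    motif: str
    cut_offset: int = 0  # reserved: offset of the cut within the motif

    def __post_init__(self) -> None:
        if len(self.motif) < 4:
            raise ValueError(f"enzyme {self.name}: motif must be at least 4 nt")
        if not is_iupac_motif(self.motif):
            raise ValueError(f"enzyme {self.name}: invalid IUPAC motif {self.motif!r}")
        object.__setattr__(self, "motif", self.motif.upper())


ECORV = Enzyme("EcoRV", "GATATC")
APALI = Enzyme("ApaLI", "GTGCAC")


def read_enzymes(path: str) -> list[Enzyme]:
    """Read a TSV of (name, motif) rows."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed enzyme line {lineno}")
            out.append(Enzyme(parts[0], parts[1]))
    return out


@dataclass
class SiteMap:
    """Sorted 1-based motif start positions of an enzyme on a sequence.

    Matches on either strand are reported by their start on the forward
    coordinate system; palindromic motifs therefore appear once per locus.
    """

    enzyme: Enzyme
    positions: list[int]
    seq_length: int

    def __post_init__(self) -> None:
        if self.positions != sorted(set(self.positions)):
            raise ValueError("positions must be strictly increasing")


def _motif_regex(motif: str) -> re.Pattern:
    # sequence 'N' never matches: classes contain concrete bases only
    return re.compile("(?=" + "".join("[" + "".join(sorted(IUPAC[c])) + "]" for c in motif) + ")")


def scan_sites(sequence: str, enzyme: Enzyme) -> SiteMap:
    """All and only IUPAC-matching motif positions on either strand."""
    sequence = sequence.upper()
    hits = set()
    for pat in {enzyme.motif, revcomp(enzyme.motif)}:
        rx = _motif_regex(pat)
        hits.update(m.start() + 1 for m in rx.finditer(sequence))
    return SiteMap(enzyme, sorted(hits), len(sequence))


class Fragment(NamedTuple):
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def predict_fragments(sitemap: SiteMap, seq_length: int, query: tuple[int, int]) -> Fragment:
    """The inter-site digest fragment containing the query interval.

    Fragment boundaries sit at motif starts: sites s1<s2<... partition the
    sequence into [1,s1-1], [s1,s2-1], ..., [sk,L]. A site strictly inside
    the query means the query is not released intact and raises ValueError.
    """
    qs, qe = query
    if not (1 <= qs <= qe <= seq_length):
        raise ValueError(f"query interval {query} outside sequence of length {seq_length}")
    spanning = [s for s in sitemap.positions if qs < s <= qe]
    if spanning:
        raise ValueError(
            f"query interval {query} spans {sitemap.enzyme.name} site(s) at {spanning}: "
            "not released intact"
        )
    left = [s for s in sitemap.positions if s <= qs]
    right = [s for s in sitemap.positions if s > qe]
    start = max(left) if left else 1
    end = (min(right) - 1) if right else seq_length
    return Fragment(start, end)


def select_cloning_enzymes(nor, candidates: list[Enzyme]) -> list[tuple[Enzyme, int, int]]:
    """Enzymes that release the intact repeat array, with their innermost flank sites.

    Qualifying enzymes have zero sites overlapping the array interval and at
    least one site in each flank. Returns (enzyme, innermost 5' site,
    innermost 3' site) sorted by released-fragment length ascending; empty
    list (with a warning) if nothing qualifies.
    """
    astart, aend = nor.array_interval
    results = []
    for enz in candidates:
        sm = scan_sites(nor.sequence, enz)
        k = len(enz.motif)
        if any(p + k - 1 >= astart and p <= aend for p in sm.positions):
            continue
        left = [p for p in sm.positions if p + k - 1 < astart]
        right = [p for p in sm.positions if p > aend]
        if not left or not right:
            continue
        frag = predict_fragments(sm, len(nor.sequence), (astart, aend))
        results.append((frag.length, enz, max(left), min(right)))
    if not results:
        warnings.warn("no candidate enzyme releases the array intact")
    results.sort(key=lambda t: t[0])
    return [(enz, i5, i3) for _, enz, i5, i3 in results]


@dataclass
class HookDesign:
    """A TAR targeting hook: an interval just inside a released fragment end."""

    side: str  # "5'" or "3'"
    start: int  # 1-based inclusive, on the source sequence
    end: int
    distance_to_cut: int = 0
    distance_to_array: int | None = None
    sequence: str = field(default="", repr=False)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _count_occurrences(hay: str, needle: str) -> int:
    n = 0
    i = hay.find(needle)
    while i != -1:
        n += 1
        i = hay.find(needle, i + 1)
    return n


def design_hooks(
    sequence: str,
    fragment: tuple[int, int],
    length_range: tuple[int, int] = (170, 200),
    search_window: int = 1000,
    array_interval: tuple[int, int] | None = None,
) -> tuple[HookDesign, HookDesign]:
    """Pick unique 5' and 3' targeting hooks immediately inside a fragment.

    Hooks start flush with the cut (distance_to_cut 0) when a unique sequence
    of acceptable length exists there; otherwise the start slides inward, up
    to ``search_window`` bp. Uniqueness means a single exact occurrence
    within the released fragment. Raises ValueError (suggesting widening
    ``length_range``) when no unique hook exists near an end.
    """
    lo, hi = length_range
    fstart, fend = fragment
    frag_seq = sequence[fstart - 1 : fend]
    if len(frag_seq) <= 2 * hi:
        raise ValueError("fragment shorter than twice the maximum hook length")

    def dist_to_array(pos_start: int, pos_end: int) -> int | None:
        if array_interval is None:
            return None
        astart, aend = array_interval
        if pos_end < astart:
            return astart - pos_end
        if pos_start > aend:
            return pos_start - aend
        return 0

    def pick(side: str) -> HookDesign:
        for offset in range(0, search_window - lo + 1):
            for L in range(hi, lo - 1, -1):
                if side == "5'":
                    s_local = offset
                else:
                    s_local = len(frag_seq) - offset - L
                if s_local < 0 or s_local + L > len(frag_seq):
                    continue
                cand = frag_seq[s_local : s_local + L]
                if _count_occurrences(frag_seq, cand) == 1:
                    start = fstart + s_local
                    end = start + L - 1
                    return HookDesign(
                        side=side,
                        start=start,
                        end=end,
                        distance_to_cut=offset,
                        distance_to_array=dist_to_array(start, end),
                        sequence=cand,
                    )
        raise ValueError(
            f"no unique {side} hook of length {lo}-{hi} within {search_window} bp of the "
            "fragment end; consider expanding length_range"
        )

    return pick("5'"), pick("3'")
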