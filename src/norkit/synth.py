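"""Synthetic nucleolar organizer regions with known ground truth.

The generator emulates the architecture of a human acrocentric NOR: a
proximal-junction (PJ) flank, ``n_units`` tandem rDNA repeat units — each a
transcribed region (5'ETS, 18S, ITS1, 5.8S, ITS2, 28S, 3'ETS) followed by a
long intergenic spacer (IGS) — and a distal-junction (DJ) flank. Every unit
is an independently mutated copy of one reference unit, with region-specific
variant rates (IGS typically ~2x the transcribed region, 5.8S invariant),
so every downstream stage can be checked against stored truth.

Restriction-enzyme recognition motifs are actively scrubbed from the repeat
units and planted only at requested flank positions, reproducing the property
that makes array-releasing digests possible. Background sequence is i.i.d.
at a chosen GC content: downstream operations depend on motif placement and
edit structure, not realistic k-mer composition.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import restriction
from .seq import DNA, IUPAC, random_dna, revcomp, rotate
from .variants import VariantRecord, left_normalize, region_of, variant_type

REGION_ORDER = ("5'ETS", "18S", "ITS1", "5.8S", "ITS2", "28S", "3'ETS", "IGS")

# Full-scale defaults: ~13.4 kb transcribed region + ~30 kb IGS => ~43 kb unit,
# with mature-rRNA segment lengths in standard human proportions.
DEFAULT_REGION_LENGTHS = {
    "5'ETS": 3660,
    "18S": 1870,
    "ITS1": 1080,
    "5.8S": 160,
    "ITS2": 1170,
    "28S": 5070,
    "3'ETS": 360,
    "IGS": 29700,
}


def default_indel_length_dist(mean: float = 3.0, max_len: int = 20) -> np.ndarray:
    """Truncated geometric distribution over indel lengths 1..max_len."""
    p = 1.0 / mean
    probs = np.array([(1 - p) ** (k - 1) * p for k in range(1, max_len + 1)])
    return probs / probs.sum()


@dataclass
class NORSpec:
    """Parameters of a synthetic NOR; identical (spec, seed) => identical output."""

    pj_length: int = 40_000
    dj_length: int = 40_000
    n_units: int = 2
    region_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_REGION_LENGTHS))
    variant_rate: dict[str, float] = field(
        default_factory=lambda: {r: 0.0 for r in REGION_ORDER}
    )
    indel_fraction: float = 0.1
    indel_length_dist: np.ndarray = field(default_factory=default_indel_length_dist)
    gc_content: float = 0.5
    # enzyme name -> list of flank positions; positive p = position p in the PJ,
    # negative -q = position q in the DJ (both 1-based within the flank)
    planted_sites: dict[str, list[int]] = field(default_factory=dict)
    enzyme_motifs: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.pj_length <= 0 or self.dj_length <= 0:
            raise ValueError("flank lengths must be positive")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if set(self.region_lengths) != set(REGION_ORDER):
            raise ValueError(f"region_lengths must define exactly {REGION_ORDER}")
        if any(l <= 0 for l in self.region_lengths.values()):
            raise ValueError("all region lengths must be positive")
        for r, rate in self.variant_rate.items():
            if rate < 0:
                raise ValueError(f"negative variant rate for {r}")
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ValueError("indel_fraction must be in [0,1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0,1)")
        for name in self.planted_sites:
            if name not in self.enzyme_motifs:
                raise ValueError(f"no motif given for planted enzyme {name!r}")
        for name, positions in self.planted_sites.items():
            k = len(self.enzyme_motifs[name])
            for p in positions:
                if p > 0 and not (1 <= p <= self.pj_length - k + 1):
                    raise ValueError(f"planted {name} site {p} outside PJ flank")
                if p < 0 and not (1 <= -p <= self.dj_length - k + 1):
                    raise ValueError(f"planted {name} site {p} outside DJ flank")
                if p == 0:
                    raise ValueError("planted positions are 1-based; 0 is invalid")

    @property
    def unit_length(self) -> int:
        return sum(self.region_lengths[r] for r in REGION_ORDER)

    def unit_annotation(self) -> list[tuple[str, int, int]]:
        """Per-region (label, start, end) on the reference unit, 1-based."""
        out = []
        pos = 1
        for r in REGION_ORDER:
            out.append((r, pos, pos + self.region_lengths[r] - 1))
            pos += self.region_lengths[r]
        return out


@dataclass
class NORInstance:
    """A generated NOR with annotation and per-unit ground-truth variants."""

    sequence: str
    annotation: list[tuple[str, int, int, int]]  # (region, unit index, start, end)
    truth_variants: list[VariantRecord]
    planted_site_positions: dict[str, list[int]]
    reference_unit: str
    unit_ids: list[str]
    spec: NORSpec

    @property
    def array_interval(self) -> tuple[int, int]:
        """1-based inclusive interval covered by the repeat-unit array."""
        unit_rows = [(s, e) for (_, u, s, e) in self.annotation if u > 0]
        return min(s for s, _ in unit_rows), max(e for _, e in unit_rows)

    def truth_by_unit(self) -> dict[str, list[VariantRecord]]:
        out: dict[str, list[VariantRecord]] = {u: [] for u in self.unit_ids}
        for rec in self.truth_variants:
            out[rec.unit].append(rec)
        return out

    def check_annotation(self) -> None:
        """Annotation intervals must tile the sequence without overlap."""
        ivs = sorted((s, e) for (_, _, s, e) in self.annotation)
        pos = 1
        for s, e in ivs:
            if s != pos or e < s:
                raise AssertionError(f"annotation does not tile at {s} (expected {pos})")
            pos = e + 1
        if pos != len(self.sequence) + 1:
            raise AssertionError("annotation does not cover the full sequence")


def _find_motif_hits(seq: str, motifs: list[str]) -> list[tuple[int, int]]:
    """0-based [start, end) intervals of any motif occurrence on either strand."""
    hits = []
    for motif in motifs:
        for pat in {motif, revcomp(motif)}:
            start = 0
            while True:
                i = seq.find(pat, start)
                if i == -1:
                    break
                hits.append((i, i + len(pat)))
                start = i + 1
    return hits


def scrub_motifs(
    seq: str,
    motifs: list[str],
    rng: np.random.Generator,
    protected: list[tuple[int, int]] | None = None,
    max_rounds: int = 200,
) -> str:
    """Remove every motif occurrence by point edits, sparing protected intervals."""
    protected = protected or []
    chars = list(seq)
    for _ in range(max_rounds):
        hits = [
            (s, e)
            for s, e in _find_motif_hits("".join(chars), motifs)
            if not any(s >= ps and e <= pe for ps, pe in protected)
        ]
        if not hits:
            return "".join(chars)
        for s, e in hits:
            # edit one position outside any protected interval
            editable = [
                i for i in range(s, e) if not any(ps <= i < pe for ps, pe in protected)
            ]
            i = int(rng.choice(editable))
            chars[i] = rng.choice([c for c in DNA if c != chars[i]])
    raise RuntimeError("failed to scrub enzyme motifs after bounded retries")


def _concretize_motif(motif: str, rng: np.random.Generator) -> str:
    return "".join(
        c if c in DNA else rng.choice(sorted(IUPAC[c])) for c in motif
    )


def mutate_unit(
    reference: str,
    annotation: list[tuple[str, int, int]],
    rates: dict[str, float],
    rng: np.random.Generator | int,
    indel_fraction: float = 0.1,
    indel_length_dist: np.ndarray | None = None,
    unit_id: str = "unit",
    max_tries: int = 1000,
) -> tuple[str, list[VariantRecord]]:
    """Mutate one reference unit region by region at per-region Poisson rates.

    SNVs and indels are placed uniformly within each region; a contiguous
    indel is one variant. Truth records are left-aligned on reference-unit
    coordinates. Overlapping draws are re-drawn; a region with positive rate
    but no sequence raises ValueError.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if indel_length_dist is None:
        indel_length_dist = default_indel_length_dist()
    for label, start, end in annotation:
        if rates.get(label, 0.0) > 0 and end < start:
            raise ValueError(f"region {label} has rate > 0 but zero length")

    events: list[tuple[int, str, str]] = []  # raw (pos, ref, alt) on reference coords
    occupied: set[int] = set()
    lengths_idx = np.arange(1, len(indel_length_dist) + 1)
    for label, start, end in annotation:
        rate = rates.get(label, 0.0)
        length = end - start + 1
        if rate <= 0 or length <= 0:
            continue
        n = rng.poisson(rate * length / 1000.0)
        drawn = 0
        tries = 0
        while drawn < n:
            tries += 1
            if tries > max_tries * max(n, 1):
                raise RuntimeError(f"could not place {n} variants in region {label}")
            pos = int(rng.integers(start, end + 1))
            if rng.random() < indel_fraction:
                ilen = int(rng.choice(lengths_idx, p=indel_length_dist))
                if rng.random() < 0.5:  # deletion
                    if pos + ilen - 1 > end:
                        continue
                    span = range(pos, pos + ilen)
                    if occupied.intersection(span):
                        continue
                    events.append((pos, reference[pos - 1 : pos - 1 + ilen], ""))
                    occupied.update(span)
                else:  # insertion before pos
                    if pos in occupied:
                        continue
                    ins = "".join(rng.choice(list(DNA), size=ilen))
                    events.append((pos, "", ins))
                    occupied.add(pos)
            else:
                if pos in occupied:
                    continue
                refb = reference[pos - 1]
                altb = rng.choice([c for c in DNA if c != refb])
                events.append((pos, refb, altb))
                occupied.add(pos)
            drawn += 1

    # apply right-to-left so earlier coordinates stay valid
    seq = reference
    for pos, ref, alt in sorted(events, key=lambda e: -e[0]):
        if ref:  # SNV or deletion
            seq = seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]
        else:  # insertion before pos
            seq = seq[: pos - 1] + alt + seq[pos - 1 :]

    records = []
    for pos, ref, alt in sorted(events):
        npos, nref, nalt = left_normalize(pos, ref, alt, reference)
        records.append(
            VariantRecord(
                unit=unit_id,
                pos=npos,
                vtype=variant_type(nref, nalt),
                ref=nref,
                alt=nalt,
                region=region_of(npos, annotation),
            )
        )
    return seq, records


def build_nor(spec: NORSpec) -> NORInstance:
    """Generate a synthetic NOR instance from a validated spec (deterministic)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    motifs = [m.upper() for m in spec.enzyme_motifs.values()]
    unit_annot = spec.unit_annotation()

    reference = random_dna(rng, spec.unit_length, spec.gc_content)
    if motifs:
        reference = scrub_motifs(reference, motifs, rng)

    pj = random_dna(rng, spec.pj_length, spec.gc_content)
    dj = random_dna(rng, spec.dj_length, spec.gc_content)

    # plant concretized motifs at requested flank positions
    planted_pj: list[tuple[int, int]] = []
    planted_dj: list[tuple[int, int]] = []
    planted_local: dict[str, list[int]] = {}
    for name, positions in spec.planted_sites.items():
        motif = spec.enzyme_motifs[name].upper()
        for p in positions:
            concrete = _concretize_motif(motif, rng)
            if p > 0:
                pj = pj[: p - 1] + concrete + pj[p - 1 + len(motif) :]
                planted_pj.append((p - 1, p - 1 + len(motif)))
            else:
                q = -p
                dj = dj[: q - 1] + concrete + dj[q - 1 + len(motif) :]
                planted_dj.append((q - 1, q - 1 + len(motif)))
            planted_local.setdefault(name, []).append(p)

    all_zero = all(r <= 0 for r in spec.variant_rate.values())
    units: list[str] = []
    truth: list[VariantRecord] = []
    unit_ids = [f"unit_{i}" for i in range(1, spec.n_units + 1)]
    for uid in unit_ids:
        if all_zero:
            units.append(reference)
            continue
        for attempt in range(50):
            seq, recs = mutate_unit(
                reference,
                unit_annot,
                spec.variant_rate,
                rng,
                spec.indel_fraction,
                spec.indel_length_dist,
                unit_id=uid,
            )
            if not motifs or not _find_motif_hits(seq, motifs):
                break
        else:
            raise RuntimeError(f"mutation kept recreating enzyme sites in {uid}")
        units.append(seq)
        truth.extend(recs)

    # junction windows: re-mutate a unit whose junction recreates a motif
    if motifs and not all_zero:
        k = max(len(m) for m in motifs)
        for _ in range(50):
            joined = pj + "".join(units) + dj
            astart0 = len(pj)  # 0-based start of the array
            aend0 = astart0 + sum(len(u) for u in units)
            bad = [
                (s, e)
                for s, e in _find_motif_hits(joined, motifs)
                if e > astart0 and s < aend0
            ]
            if not bad:
                break
            s, _ = bad[0]
            # re-mutate the unit containing (or right of) the offending hit
            off = max(s - astart0, 0)
            acc = 0
            for ui, useq in enumerate(units):
                if off < acc + len(useq):
                    break
                acc += len(useq)
            seq, recs = mutate_unit(
                reference,
                unit_annot,
                spec.variant_rate,
                rng,
                spec.indel_fraction,
                spec.indel_length_dist,
                unit_id=unit_ids[ui],
            )
            units[ui] = seq
            truth = [r for r in truth if r.unit != unit_ids[ui]] + recs
        else:
            raise RuntimeError("could not clear enzyme sites from array junctions")

    sequence = pj + "".join(units) + dj

    # annotation on actual (post-indel) coordinates
    annotation: list[tuple[str, int, int, int]] = [("PJ", 0, 1, len(pj))]
    pos = len(pj) + 1
    for ui, useq in enumerate(units, start=1):
        # recompute per-region lengths for this unit from its truth variants
        deltas = {r: 0 for r in REGION_ORDER}
        for rec in truth:
            if rec.unit == f"unit_{ui}":
                deltas[rec.region] = deltas.get(rec.region, 0) + (len(rec.alt) - len(rec.ref))
        for r in REGION_ORDER:
            rl = spec.region_lengths[r] + deltas.get(r, 0)
            annotation.append((r, ui, pos, pos + rl - 1))
            pos += rl
    annotation.append(("DJ", 0, pos, len(sequence)))

    # global planted-site positions
    array_len = sum(len(u) for u in units)
    planted_global: dict[str, list[int]] = {}
    for name, positions in planted_local.items():
        for p in positions:
            g = p if p > 0 else spec.pj_length + array_len + (-p)
            planted_global.setdefault(name, []).append(g)
        planted_global[name].sort()

    nor = NORInstance(
        sequence=sequence,
        annotation=annotation,
        truth_variants=truth,
        planted_site_positions=planted_global,
        reference_unit=reference,
        unit_ids=unit_ids,
        spec=spec,
    )
    nor.check_annotation()
    return nor


@dataclass
class CloneTemplate:
    """A simulated circular TAR/BAC clone and its linearized emission."""

    vector_sequence: str
    hook5: str
    hook3: str
    insert: str
    circular: bool
    rotation: int
    emitted: str
    circular_overlap: int
    enzyme: restriction.Enzyme
    fragment: tuple[int, int]  # released-fragment interval on the NOR


def simulate_clone(
    nor: NORInstance,
    enzyme: restriction.Enzyme,
    vector: str,
    hooks: tuple[str, str] | None = None,
    rotation: int | None = None,
    circular_overlap: int = 0,
    rng: np.random.Generator | int | None = None,
) -> CloneTemplate:
    """Digest the NOR, capture the released array fragment in a circular clone,
    and emit a rotated linearization (optionally with a duplicated terminal
    segment emulating circular assembly overlap).

    Raises ValueError naming the offending position if the enzyme cuts inside
    the repeat array.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(0 if rng is None else int(rng))
    astart, aend = nor.array_interval
    sm = restriction.scan_sites(nor.sequence, enzyme)
    k = len(enzyme.motif)
    inside = [p for p in sm.positions if p + k - 1 >= astart and p <= aend]
    if inside:
        raise ValueError(
            f"enzyme {enzyme.name} cuts inside the repeat array at position {inside[0]}"
        )
    frag = restriction.predict_fragments(sm, len(nor.sequence), (astart, aend))
    insert = nor.sequence[frag.start - 1 : frag.end]
    if hooks is None:
        h5, h3 = restriction.design_hooks(
            nor.sequence, (frag.start, frag.end), array_interval=(astart, aend)
        )
        hooks = (h5.sequence, h3.sequence)
    circle = vector + insert
    r = int(rng.integers(0, len(circle))) if rotation is None else rotation % len(circle)
    emitted = rotate(circle, r)
    if circular_overlap > 0:
        emitted = emitted + emitted[: min(circular_overlap, len(emitted) // 2)]
    return CloneTemplate(
        vector_sequence=vector,
        hook5=hooks[0],
        hook3=hooks[1],
        insert=insert,
        circular=True,
        rotation=r,
        emitted=emitted,
        circular_overlap=circular_overlap,
        enzyme=enzyme,
        fragment=(frag.start, frag.end),
    )
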