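"""Variant calling on aligned rDNA units and descriptive variant statistics.

Variants live on a designated reference-unit coordinate system (1-based).
A contiguous indel of any length is one variant; indels are left-aligned
(leftmost equivalent placement) and anchored VCF-style on the preceding base.
No multiple-testing correction is applied anywhere in this module: the
outputs are descriptive counts and densities.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .align import AlignedPair, Scoring, align_units


@dataclass(frozen=True)
class VariantRecord:
    """One variant keyed to a reference unit (anchored, left-normalized)."""

    unit: str            # id of the unit carrying the variant
    pos: int             # 1-based position on the reference unit
    vtype: str           # SNV | INS | DEL
    ref: str
    alt: str
    region: str = ""

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)


def left_normalize(pos: int, ref: str, alt: str, refseq: str) -> tuple[int, str, str]:
    """Left-align and anchor a raw variant against the reference sequence.

    Accepts raw events with possibly empty alleles (pure insertion/deletion)
    and returns the leftmost anchored representation. For events shifted to
    position 1 the anchor falls on the base after the event, VCF-style.
    """
    while True:
        if not ref or not alt:
            if pos > 1:
                pos -= 1
                b = refseq[pos - 1]
                ref, alt = b + ref, b + alt
            else:
                after = len(ref)  # reference bases consumed starting at pos 1
                b = refseq[after] if after < len(refseq) else "N"
                ref, alt = ref + b, alt + b
                break
            continue
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            continue
        break
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def variant_type(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "SNV"
    return "INS" if len(alt) > len(ref) else "DEL"


def region_of(pos: int, annotation: list[tuple[str, int, int]]) -> str:
    """Region label for a 1-based reference position ('unannotated' if none)."""
    for label, start, end in annotation:
        if start <= pos <= end:
            return label
    return "unannotated"


def call_variants(
    pair: AlignedPair,
    ref_seq: str,
    alt_seq: str,
    annotation: list[tuple[str, int, int]] | None = None,
    unit_id: str | None = None,
) -> list[VariantRecord]:
    """Project an alignment onto the reference unit as variant records.

    The first sequence of the pair is the reference. One record per
    mismatch; one record per contiguous gap run, left-aligned. Positions
    outside the annotation get region 'unannotated', never dropped.
    """
    pair.check()
    annotation = annotation or []
    unit_id = unit_id or pair.id_b
    raw: list[tuple[int, str, str]] = []
    i = 1  # next reference position
    j = 1  # next alt position
    for op, length in pair.ops:
        if op == "M":
            rs = ref_seq[i - 1 : i - 1 + length]
            as_ = alt_seq[j - 1 : j - 1 + length]
            for t in range(length):
                if rs[t] != as_[t]:
                    raw.append((i + t, rs[t], as_[t]))
            i += length
            j += length
        elif op == "D":  # deletion from the reference
            raw.append((i, ref_seq[i - 1 : i - 1 + length], ""))
            i += length
        else:  # 'I': insertion before reference position i
            raw.append((i, "", alt_seq[j - 1 : j - 1 + length]))
            j += length
    records = []
    for pos, ref, alt in raw:
        pos, ref, alt = left_normalize(pos, ref, alt, ref_seq)
        records.append(
            VariantRecord(
                unit=unit_id,
                pos=pos,
                vtype=variant_type(ref, alt),
                ref=ref,
                alt=alt,
                region=region_of(pos, annotation),
            )
        )
    return records


def variants_to_frame(records: list[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "CHROM": r.unit,
                "POS": r.pos,
                "REF": r.ref,
                "ALT": r.alt,
                "TYPE": r.vtype,
                "REGION": r.region,
            }
            for r in records
        ],
        columns=["CHROM", "POS", "REF", "ALT", "TYPE", "REGION"],
    )


@dataclass
class DivergenceSummary:
    """Pairwise variant counts with per-group mean and standard error."""

    pairs: pd.DataFrame  # columns: unit_a, unit_b, group, n_variants

    def summary(self) -> pd.DataFrame:
        if self.pairs.empty:
            return pd.DataFrame(columns=["group", "n_pairs", "mean", "sem"])
        g = self.pairs.groupby("group")["n_variants"]
        out = g.agg(n_pairs="size", mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
        out["sem"] = out["sem"].fillna(0.0)
        return out.reset_index()

    @property
    def mean(self) -> float:
        return float(self.pairs["n_variants"].mean()) if len(self.pairs) else float("nan")

    @property
    def sem(self) -> float:
        n = len(self.pairs)
        if n == 0:
            return float("nan")
        if n == 1:
            return 0.0
        return float(self.pairs["n_variants"].std(ddof=1) / np.sqrt(n))


def pairwise_divergence(
    units: dict[str, str],
    groups: dict[str, str] | None = None,
    scoring: Scoring | None = None,
    band: int = 200,
) -> DivergenceSummary:
    """Variant counts for every unordered pair of units, summarized per group.

    Within a pair the lexicographically first unit id acts as the local
    reference; the count is symmetric under this convention. Pairs whose
    units belong to different groups get the joint label "ga|gb".
    """
    ids = sorted(units)
    if len(ids) < 2:
        warnings.warn("pairwise_divergence needs at least 2 units; returning empty summary")
        return DivergenceSummary(pd.DataFrame(columns=["unit_a", "unit_b", "group", "n_variants"]))
    groups = groups or {u: "all" for u in ids}
    rows = []
    for a, b in itertools.combinations(ids, 2):
        pair = align_units(units[a], units[b], scoring=scoring, band=band, id_a=a, id_b=b)
        n_var = len(call_variants(pair, units[a], units[b], unit_id=b))
        ga, gb = groups[a], groups[b]
        label = ga if ga == gb else "|".join(sorted((ga, gb)))
        rows.append({"unit_a": a, "unit_b": b, "group": label, "n_variants": n_var})
    return DivergenceSummary(pd.DataFrame(rows))


@dataclass
class SharingTable:
    """Variant sharing classes across units and chromosome groups.

    universal: carried in >=2 units and seen in every chromosome group
    (requires >=2 groups); shared: >1 carrier but not all groups;
    unique: exactly one carrier.
    """

    table: pd.DataFrame  # columns: pos, ref, alt, carriers, n_carriers, groups, cls

    def counts(self) -> dict[str, int]:
        c = self.table["cls"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in ("universal", "shared", "unique")}


def classify_sharing(
    variants_per_unit: dict[str, list[VariantRecord]],
    group_map: dict[str, str],
) -> SharingTable:
    """Classify each variant key by how it is shared across units/groups."""
    missing = [u for u in variants_per_unit if u not in group_map]
    if missing:
        raise ValueError(f"units without a chromosome group: {missing}")
    all_groups = set(group_map[u] for u in variants_per_unit)
    carriers: dict[tuple[int, str, str], set[str]] = {}
    for unit, recs in variants_per_unit.items():
        for r in recs:
            carriers.setdefault(r.key, set()).add(unit)
    rows = []
    for key in sorted(carriers):
        units = carriers[key]
        covered = set(group_map[u] for u in units)
        if len(units) == 1:
            cls = "unique"
        elif covered == all_groups and len(all_groups) >= 2:
            cls = "universal"
        else:
            cls = "shared"
        rows.append(
            {
                "pos": key[0],
                "ref": key[1],
                "alt": key[2],
                "carriers": ",".join(sorted(units)),
                "n_carriers": len(units),
                "groups": ",".join(sorted(covered)),
                "cls": cls,
            }
        )
    return SharingTable(
        pd.DataFrame(rows, columns=["pos", "ref", "alt", "carriers", "n_carriers", "groups", "cls"])
    )


def region_density(
    variants: list[VariantRecord],
    annotation: list[tuple[str, int, int]],
    igs_label: str = "IGS",
) -> pd.DataFrame:
    """Variants per kb for each annotated region, plus an IGS : transcribed ratio.

    The transcribed side pools every region except ``igs_label``. The ratio
    row has region label 'IGS/transcribed_ratio' and the ratio in the
    'per_kb' column. Zero-length regions are excluded with a warning.
    """
    lengths: dict[str, int] = {}
    for label, start, end in annotation:
        lengths[label] = lengths.get(label, 0) + (end - start + 1)
    counts: dict[str, int] = {label: 0 for label in lengths}
    for r in variants:
        counts[r.region] = counts.get(r.region, 0) + 1
    rows = []
    for label, length in lengths.items():
        if length == 0:
            warnings.warn(f"region {label!r} has zero length; excluded from densities")
            continue
        rows.append(
            {
                "region": label,
                "length_bp": length,
                "n_variants": counts.get(label, 0),
                "per_kb": counts.get(label, 0) / (length / 1000.0),
            }
        )
    df = pd.DataFrame(rows, columns=["region", "length_bp", "n_variants", "per_kb"])
    tr = df[df["region"] != igs_label]
    igs = df[df["region"] == igs_label]
    if len(igs) and tr["length_bp"].sum() > 0:
        tr_density = tr["n_variants"].sum() / (tr["length_bp"].sum() / 1000.0)
        igs_density = float(igs["per_kb"].iloc[0])
        ratio = igs_density / tr_density if tr_density > 0 else float("inf")
        df = pd.concat(
            [
                df,
                pd.DataFrame(
                    [
                        {
                            "region": f"{igs_label}/transcribed_ratio",
                            "length_bp": 0,
                            "n_variants": 0,
                            "per_kb": ratio,
                        }
                    ]
                ),
            ],
            ignore_index=True,
        )
    return df


def map_to_features(
    variants: list[VariantRecord],
    features: list[tuple[str, int, int]],
    proximity: int = 50,
) -> pd.DataFrame:
    """Overlap/proximity report of variants against feature intervals.

    Signed distance: 0 inside the feature, negative upstream of its start,
    positive downstream of its end; features farther than ``proximity`` are
    omitted.
    """
    tree = IntervalTree()
    for idx, (name, start, end) in enumerate(features):
        if end < start:
            raise ValueError(f"malformed feature interval at line {idx + 1}: {name} {start}-{end}")
        # pad by proximity; intervaltree is half-open on the end
        tree.addi(start - proximity, end + proximity + 1, (name, start, end))
    rows = []
    for r in variants:
        for iv in sorted(tree[r.pos]):
            name, start, end = iv.data
            if r.pos < start:
                dist = r.pos - start
            elif r.pos > end:
                dist = r.pos - end
            else:
                dist = 0
            rows.append(
                {
                    "unit": r.unit,
                    "pos": r.pos,
                    "ref": r.ref,
                    "alt": r.alt,
                    "feature": name,
                    "feature_start": start,
                    "feature_end": end,
                    "distance": dist,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["unit", "pos", "ref", "alt", "feature", "feature_start", "feature_end", "distance"],
    )
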