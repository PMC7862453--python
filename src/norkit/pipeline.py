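"""End-to-end pipeline: simulate -> design -> clone -> finish -> merge ->
variants -> structure -> copies, writing every intermediate to disk."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import io, qpcr, restriction, rna, synth
from .align import Scoring, align_units
from .config import RunConfig
from .finishing import finish_assembly, merge_inserts
from .variants import (
    call_variants,
    classify_sharing,
    pairwise_divergence,
    region_density,
    variants_to_frame,
)

log = logging.getLogger("norkit")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on one synthetic NOR; returns the summary report.

    All randomness derives from ``config.seed``. Every intermediate is
    written under ``config.outdir``; a stage failure raises
    :class:`StageError` naming the stage, with prior outputs preserved.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    report: dict = {"seed": config.seed, "config_hash": config.config_hash()}
    log.info("run config hash %s seed %d", config.config_hash(), config.seed)

    # --- simulate -----------------------------------------------------------
    stage = "simulate"
    try:
        sim = config.simulate
        spec = synth.NORSpec(
            pj_length=sim.pj_length,
            dj_length=sim.dj_length,
            n_units=sim.n_units,
            region_lengths=sim.region_lengths or dict(synth.DEFAULT_REGION_LENGTHS),
            variant_rate=sim.variant_rate,
            indel_fraction=sim.indel_fraction,
            gc_content=sim.gc_content,
            planted_sites=sim.planted_sites,
            enzyme_motifs=sim.enzyme_motifs,
            seed=int(rng.integers(2**31)),
        )
        nor = synth.build_nor(spec)
        io.write_fasta([("NOR", nor.sequence), ("reference_unit", nor.reference_unit)],
                       out / "nor.fa")
        io.write_bed(
            [(f"unit_{u}" if u else "NOR", s, e, r) for r, u, s, e in nor.annotation],
            out / "nor_annotation.bed",
        )
        io.write_variant_table(variants_to_frame(nor.truth_variants), out / "truth_variants.tsv")
        report["simulate"] = {
            "nor_length": len(nor.sequence),
            "n_units": spec.n_units,
            "unit_length": spec.unit_length,
            "array_interval": list(nor.array_interval),
            "n_truth_variants": len(nor.truth_variants),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- design -------------------------------------------------------------
    stage = "design"
    try:
        candidates = [restriction.Enzyme(n, m) for n, m in sim.enzyme_motifs.items()]
        selected = restriction.select_cloning_enzymes(nor, candidates)
        if not selected:
            raise RuntimeError("no enzyme releases the array intact")
        enzyme, i5, i3 = selected[0]
        sm = restriction.scan_sites(nor.sequence, enzyme)
        frag = restriction.predict_fragments(sm, len(nor.sequence), nor.array_interval)
        h5, h3 = restriction.design_hooks(
            nor.sequence,
            (frag.start, frag.end),
            (config.design.hook_length_min, config.design.hook_length_max),
            config.design.search_window,
            array_interval=nor.array_interval,
        )
        report["design"] = {
            "enzyme": enzyme.name,
            "innermost_sites": [i5, i3],
            "released_fragment": [frag.start, frag.end],
            "predicted_band_bp": frag.length,
            "hook5": {"interval": [h5.start, h5.end], "length": h5.length},
            "hook3": {"interval": [h3.start, h3.end], "length": h3.length},
        }
        with open(out / "design.json", "w") as fh:
            json.dump(report["design"], fh, indent=2)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- clone + finish -----------------------------------------------------
    stage = "clone"
    try:
        from .seq import random_dna

        vector = random_dna(rng, config.clone.vector_length, sim.gc_content)
        clone = synth.simulate_clone(
            nor, enzyme, vector,
            hooks=(h5.sequence, h3.sequence),
            rotation=config.clone.rotation,
            circular_overlap=config.clone.circular_overlap,
            rng=rng,
        )
        io.write_fasta([("clone_assembly", clone.emitted)], out / "clone_assembly.fa")
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "finish"
    try:
        fin = finish_assembly(
            clone.emitted, vector,
            hooks={"hook5": clone.hook5, "hook3": clone.hook3},
            min_overlap=config.finish.min_overlap,
            max_divergence=config.finish.max_divergence,
            min_identity=config.finish.min_identity,
            min_coverage=config.finish.min_coverage,
        )
        io.write_fasta([("finished_insert", fin.insert)], out / "finished_insert.fa")
        report["finish"] = {
            "insert_length": len(fin.insert),
            "circular_overlap_removed": fin.circular_overlap_removed,
            "hooks_found": fin.hooks_found,
            "insert_matches_truth": fin.insert == clone.insert,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- merge: PJ clone + finished array insert ----------------------------
    stage = "merge"
    try:
        ov = config.merge.designed_overlap
        pj_insert = nor.sequence[: clone.fragment[0] - 1 + ov]
        merged = merge_inserts(
            pj_insert, fin.insert,
            min_overlap=config.merge.min_overlap,
            max_mismatch_rate=config.merge.max_mismatch_rate,
            id_a="PJ_clone", id_b="array_clone",
        )
        truth_slice = nor.sequence[: clone.fragment[1]]
        io.write_fasta([("contig", merged.contig)], out / "contig.fa")
        report["merge"] = {
            "contig_length": len(merged.contig),
            "overlap_length": merged.overlap_length,
            "mismatches_in_overlap": merged.mismatches_in_overlap,
            "orientation": merged.orientation,
            "contig_matches_truth": merged.contig == truth_slice,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- variants -----------------------------------------------------------
    stage = "variants"
    try:
        sc = Scoring(
            match=config.variants.match,
            mismatch=config.variants.mismatch,
            gap_open=config.variants.gap_open,
            gap_extend=config.variants.gap_extend,
        )
        unit_annot = spec.unit_annotation()
        unit_seqs: dict[str, str] = {}
        for r, u, s, e in nor.annotation:
            if u > 0:
                uid = f"unit_{u}"
                unit_seqs.setdefault(uid, "")
                unit_seqs[uid] += nor.sequence[s - 1 : e]
        called = []
        for uid in nor.unit_ids:
            pair = align_units(
                nor.reference_unit, unit_seqs[uid], scoring=sc,
                band=config.variants.band, id_a="reference", id_b=uid,
            )
            called.extend(
                call_variants(pair, nor.reference_unit, unit_seqs[uid], unit_annot, uid)
            )
        io.write_variant_table(variants_to_frame(called), out / "called_variants.tsv")
        div = pairwise_divergence(unit_seqs, scoring=sc, band=config.variants.band)
        div.summary().to_csv(out / "divergence.tsv", sep="\t", index=False)
        per_unit = {uid: [r for r in called if r.unit == uid] for uid in nor.unit_ids}
        sharing = classify_sharing(per_unit, {u: "chr22" for u in nor.unit_ids})
        sharing.table.to_csv(out / "sharing.tsv", sep="\t", index=False)
        dens = region_density(called, unit_annot)
        dens.to_csv(out / "region_density.tsv", sep="\t", index=False)
        ratio = float(dens.loc[dens["region"] == "IGS/transcribed_ratio", "per_kb"].iloc[0])
        report["variants"] = {
            "n_called": len(called),
            "pairwise_mean": div.mean,
            "pairwise_sem": div.sem,
            "igs_transcribed_ratio": ratio,
            "sharing": sharing.counts(),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- structure ----------------------------------------------------------
    stage = "structure"
    try:
        st = config.structure
        params = rna.FoldParams(model=st.model, min_loop=st.min_loop)
        # first transcribed SNV called in a mature rRNA region
        snvs = [r for r in called if r.vtype == "SNV" and r.region in ("18S", "28S")]
        if snvs:
            v = snvs[0]
            rstart = next(s for (lab, s, e) in unit_annot if lab == v.region)
            rend = next(e for (lab, s, e) in unit_annot if lab == v.region)
            region_seq = nor.reference_unit[rstart - 1 : rend]
            vpos = v.pos - rstart + 1
            ref_allele = region_seq.replace("T", "U")
            alt_allele = rna.apply_variant(ref_allele, vpos, v.ref.replace("T", "U"),
                                           v.alt.replace("T", "U"))
            impact = rna.call_ribosnitch(
                ref_allele, alt_allele, params,
                alpha=st.alpha, windows=st.windows, n=st.n_rand,
                seed=int(rng.integers(2**31)),
            )
            report["structure"] = {
                "variant": [v.region, *impact.variant],
                "structural_index": impact.structural_index,
                "delta_delta_g_open": impact.delta_delta_g_open,
                "empirical_p": impact.empirical_p,
                "z_score": None if np.isnan(impact.z_score) else impact.z_score,
                "mww_p": impact.mww_p,
                "ribosnitch": impact.ribosnitch,
            }
        else:
            report["structure"] = {"variant": None}
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- copies -------------------------------------------------------------
    stage = "copies"
    try:
        cp = config.copies
        true_copies = cp.true_copies if cp.true_copies is not None else float(sim.n_units)
        table = qpcr.simulate_ct_table(
            {"hybrid_line": true_copies}, "total_gDNA", cp.calibrator_copies,
            n_target_amplicons=cp.n_amplicons, n_replicates=cp.n_replicates,
            ct_sd=cp.ct_sd, efficiency=cp.efficiency, seed=rng,
        )
        table.data.to_csv(out / "ct_table.tsv", sep="\t", index=False)
        est = qpcr.estimate_copies(table)
        est.to_csv(out / "copy_estimates.tsv", sep="\t", index=False)
        row = est[est["sample"] == "hybrid_line"].iloc[0]
        report["copies"] = {
            "true": true_copies,
            "estimate": float(row["copies"]),
            "se": float(row["se"]),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
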