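# norkit

Simulation and analysis toolkit for **nucleolar organizer regions (NORs)** —
the tandem ribosomal-DNA arrays on acrocentric chromosome short arms — aimed
at the computational side of chromosome-scale rDNA cloning studies: people
who design TAR-cloning experiments that capture an entire rDNA array, finish
the resulting circular BAC/YAC assemblies, and mine the cloned units for
sequence and RNA-structure variation.

A human rDNA unit is ~43 kb: a ~13 kb transcribed region (5'ETS, 18S, ITS1,
5.8S, ITS2, 28S, 3'ETS) plus a ~30 kb intergenic spacer (IGS). Arrays of
such units sit between a proximal junction (PJ) and distal junction (DJ).
Because real arrays are nearly impossible to validate against, `norkit`
pairs every analysis stage with a synthetic-data generator that produces
NORs with *known ground truth* (variants, planted restriction sites,
released fragments), so each stage is testable end to end:

| stage | module | what it does |
|---|---|---|
| simulate | `norkit.synth` | PJ + n mutated units + DJ, with truth variants; circular clone emission |
| design | `norkit.restriction` | IUPAC site scanning, array-releasing enzyme selection, digest band prediction, ~170–200 bp targeting-hook design |
| finish | `norkit.finishing` | circular-overlap trimming, vector removal (exact or ≥95% id), re-orientation, hook verification; suffix/prefix contig merging |
| variants | `norkit.align`, `norkit.variants` | banded affine-gap global alignment of units, left-normalized variant calling, pairwise divergence (mean ± SE), sharing classes (unique/shared/universal), per-region densities, feature proximity |
| structure | `norkit.rna` | exact fold models, opening penalty ΔG_open, structural index D = √\|pairs₁ Δ pairs₂\|, composition-preserving randomization nulls with empirical P = (r+1)/(n+1) and z-scores, exact/asymptotic MWW test, riboSNitch calling |
| copies | `norkit.qpcr` | relative-quantification copy number: RQ = (1+E_t)^(−Ct_t)/(1+E_c)^(−Ct_c) vs a single-copy control, calibrated to a sample of known copies |
| run | `norkit.pipeline` | chains everything on one synthetic NOR, deterministic per seed |

See `docs/methods.md` for the models, parameter defaults and limitations.

## Worked example

Run the full pipeline on a default full-scale synthetic NOR (two 43,070 bp
units, 40 kb flanks, IGS variant rate twice the transcribed rate):

```sh
norkit run --seed 1 --out nor_run/
```

Selected lines of the printed report (`nor_run/report.json`):

```json
"simulate":  {"nor_length": 166154, "n_units": 2, "unit_length": 43070,
              "n_truth_variants": 223}
"design":    {"enzyme": "EcoRV", "released_fragment": [39791, 127446],
              "predicted_band_bp": 87656,
              "hook5": {"interval": [39791, 39990], "length": 200}}
"finish":    {"insert_length": 87656, "circular_overlap_removed": 500,
              "hooks_found": {"hook3": true, "hook5": true},
              "insert_matches_truth": true}
"merge":     {"contig_length": 127446, "overlap_length": 8000,
              "mismatches_in_overlap": 0, "contig_matches_truth": true}
"variants":  {"n_called": 223, "pairwise_mean": 222.0,
              "igs_transcribed_ratio": 1.73}
"copies":    {"true": 2.0, "estimate": 2.15, "se": 0.09}
```

Reading it: EcoRV (planted only in the flanks, as in real junctions) releases
the two-unit array as one 87,656 bp fragment — the predicted Southern band —
bracketed by 200 bp hooks; finishing a randomly rotated circular clone with a
500 bp duplicated terminus recovers the released fragment byte-for-byte, and
merging it with a PJ clone through their designed 8 kb overlap reproduces the
simulated NOR slice exactly (contig 127,446 bp). The variant caller recovers
all 223 planted variants; the measured IGS : transcribed density ratio (1.73)
estimates the simulated 2:1 rate contrast from a single unit pair, and the
qPCR stage re-estimates the simulated copy number from noisy Ct values.

Each stage is also exposed on its own (`norkit simulate/design/finish/merge/
variants/structure/copies`) and as plain library calls.

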