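# Methods

`norkit` reimplements, as a tested pipeline on synthetic data, the
computational core of a chromosome-scale rDNA cloning-and-analysis workflow:
designing restriction digests and recombination hooks that release an intact
tandem rDNA array, finishing circular clone assemblies, comparing repeat
units as variant catalogues, scoring the predicted impact of variants on
rRNA secondary structure, and estimating rDNA copy number from qPCR. This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic data do and do not establish.

## The synthetic NOR generator

A nucleolar organizer region (NOR) is modelled as
`PJ + unit_1 ... unit_n + DJ`: a proximal-junction flank, `n` tandem rDNA
repeat units, and a distal-junction flank. Each unit is an ordered set of
regions — 5'ETS, 18S, ITS1, 5.8S, ITS2, 28S, 3'ETS (together the ~13.4 kb
transcribed region) and a long intergenic spacer (IGS) — with full-scale
default lengths summing to a 43,070 bp unit (mature-rRNA segments in
standard human proportions, ~29.7 kb IGS). All lengths are scalable; the
test suite mostly runs at 1/10 scale.

Background sequence is i.i.d. at a configurable GC content (default 0.5).
This is deliberate: every downstream operation depends on motif placement
and edit structure, not on realistic k-mer composition, and i.i.d.
background makes analytic expectations (Poisson counts, motif hit rates)
exact. The cost is that alignment and hook-uniqueness results on synthetic
data are *easier* than on real rDNA, which contains microsatellites and
long homopolymers; passing tests demonstrate correctness of the algorithms,
not robustness to low-complexity sequence.

Every unit is an independently mutated copy of one reference unit. Variant
counts per region are Poisson at a per-region rate (variants/kb); positions
are uniform within the region; a configurable fraction of variants
(default 0.1) are indels with lengths from a truncated geometric
distribution (mean 3, maximum 20 — matching the largest indel the
characterized arrays feature). The per-region rates are exposed as free
parameters rather than fixed defaults because only observed densities, not
the generative rates, are known for real arrays; tests and the acceptance
script set them explicitly (IGS twice the transcribed region, 5.8S zero,
overall ~7.5/kb or 1.5/kb depending on the experiment). Truth records are
anchored, left-normalized variants on reference-unit coordinates —
byte-comparable with the caller's output.

Restriction motifs are actively scrubbed from the reference unit (and
re-scrubbed from mutated units and array junctions, with bounded retries)
and planted only at requested flank positions. This reproduces the property
that makes the cloning strategy work — enzymes such as EcoRV and ApaLI cut
the junctions but not the repeat units — which i.i.d. sequence would
otherwise violate about once per 4 kb per strand for a 6-mer.

Determinism: one seeded NumPy generator per construction; identical
(spec, seed) yields byte-identical output.

## Restriction design

Site scanning matches IUPAC motifs on both strands with a regex
per concrete strand pattern; palindromes are reported once per locus and a
sequence `N` never matches. Cut positions are approximated by the motif
start: both enzymes of interest cut within their 6-mers, and sub-motif
offsets are far below the ~kb resolution of band sizing (a per-enzyme
`cut_offset` field is reserved). Digest fragments therefore span
`[site_start, next_site_start - 1]`.

Hook design selects ~170–200 bp intervals flush with the released-fragment
ends (sliding inward up to 1 kb if needed), requiring a single exact
occurrence *within the released fragment* — genome-wide uniqueness is not
testable without external data and is out of scope.

## Clone finishing and merging

A simulated clone is `rotate(vector + insert, r)` with an optional
duplicated terminal segment (circular overlap). Finishing proceeds:
(1) collapse the longest terminal suffix–prefix duplication of length
≥ `min_overlap` (default 100 bp) at ≤ `max_divergence` (default 1%)
mismatches, with overlap < len/2 enforced to avoid degenerate self-matches;
(2) locate the vector on the resulting circle — exact string match first,
falling back to infix edit-distance alignment (edlib) accepted at ≥ 95%
identity over ≥ 90% of the vector length, thresholds chosen loose enough
for polished consensus error and strict enough not to fire on hook-length
chance matches; (3) re-orient the insert to begin at the first base after
the removed vector, preserving the input strand; (4) verify hooks by exact
occurrence, flagging (not raising) on failure. The minimum-overlap and
identity defaults are package choices exposed in configuration; no
published values exist for them.

Merging finds the maximal suffix/prefix overlap between two inserts,
trying both orders and both strands. Candidate overlap lengths come from
shared 31-mers (brute force below 4 kb), each verified by vectorized
mismatch counting; the longest overlap at ≤ 1% mismatches wins, with
fewest mismatches breaking length ties across orientations. The contig
length identity |contig| = |A| + |B| − overlap is asserted on every merge.

## Unit alignment and variant statistics

Units diverge by ≪ 1%, so global affine-gap alignment (match +1, mismatch
−2, gap open −5, gap extend −1; a gap of length L costs open + L·extend) is
computed inside a diagonal band that always spans the length difference
plus a margin (initial 200). Because a banded optimum can be a strict
underestimate without touching the band edge, the band is doubled until two
successive widths agree on the score *and* the optimal path is strictly
interior; failure to converge by width 5,000 raises an error identifying
the inputs as non-homologous. The scoring defaults are package choices —
pairwise variant counts depend on the aligner, which is why they are
exposed in configuration.

Variant calling walks the alignment: one record per mismatch, one per
contiguous gap run (an indel of any length is one variant), indels
left-aligned and anchored on the preceding base (VCF convention; events
shifted to position 1 anchor on the following base). Region labels come
from the annotation at the normalized position; unannotated positions are
labelled, never dropped.

Descriptive statistics are exactly that — no multiple-testing correction is
applied anywhere in the variant module. Pairwise divergence reports
per-pair counts with group means and standard errors; sharing classes
partition variant keys into `unique` (one carrier), `universal` (≥ 2
carriers covering every chromosome group, requiring ≥ 2 groups) and
`shared` (the rest); densities are counts per kb per region plus an
IGS : transcribed ratio.

## RNA-structure impact

Two exact integer-scored folding models are built in: pair maximization
over Watson–Crick + GU pairs, and a weighted-stack model (GC=3, AU=2,
GU=1, +1 per stacked pair) as a coarse nearest-neighbor stand-in. Both are
O(n³) dynamic programs with a paired-state/unpaired-state decomposition so
the stacking bonus is exact, verified against exhaustive structure
enumeration for short sequences. The minimum loop is 3 nt; the trivial
all-unpaired short-circuit applies only below the true minimum pairable
length (min_loop + 2). Scores are model units, not kcal/mol; a
thermodynamic backend can be plugged in through `FoldParams.backend` and
must return the same structure type, but all shipped tests run on the
built-ins so that every number in the repository is desk-verifiable.

ΔG_open of an interval is the unconstrained optimum minus the optimum with
the interval forced unpaired (≥ 0, zero iff already unpaired; monotone
under interval growth). The structural index D between two structures on a
common frame is the Euclidean norm of the difference of their base-pair
indicator vectors — √|pairs₁ Δ pairs₂| — which makes D a metric. For indel
alleles, pairs are mapped through the allele alignment; a pair with an
endpoint opposite a gap counts toward the difference. The partner-vector
distance is a defensible alternative reading of "distance of base pairs";
the indicator-vector norm was chosen and is isolated behind
`structural_index`.

Randomization nulls permute the window *outside* the variant footprint
(mononucleotide composition preserved exactly; the footprint keeps the
reference allele so the edit is identical in every replicate; a
dinucleotide-block shuffle is available). With n = 100 replicates the
empirical P is (r+1)/(n+1), r the number of null statistics ≥ observed.
This conservative rule is reported for inference; because the built-in
models yield discrete statistics, ties make it superuniform, so a
tie-randomized companion value (`tie_broken_p`, exactly uniform under the
null) is also reported and used for calibration tests. z-scores use the
null mean and SD (undefined, reported as NaN, when the null has zero
spread — the P-value remains valid).

The MWW test is exact by labeling enumeration for n_x + n_y ≤ 12 (two-sided
p = 2·min(tails), capped at 1; all-tied data gives p = 1) and a
tie-corrected continuity-corrected normal approximation otherwise; the two
routes agree within 0.01 at per-sample n = 12. In `call_ribosnitch` the MWW
compares the sliding-probe ΔG_open profiles of the two alleles across the
analysis window — one defensible assignment of the test to "difference
between variant alleles", since the original assignment of statistic to
test is not fully specified. A variant is flagged a potential riboSNitch
when its empirical P ≤ α (default 0.05, per variant, no correction) in at
least one window; windows default to 100 and 350 nt centered on the
variant and clipped at sequence ends, scanning step 10 nt.

## qPCR copy number

Relative quantification against a single-copy control:
RQ = (1+E_t)^(−Ct_t) / (1+E_c)^(−Ct_c), normalized to a calibrator sample
of known copy number (a required input — typically a total-genomic-DNA
standard at its diploid average; no value is hard-coded) and averaged over
the IGS target amplicons; the SE is taken over (amplicon × replicate)
estimates. Efficiencies default to 1.0 (perfect doubling) and are
configurable per amplicon. The synthetic Ct generator inverts this model
and adds Gaussian well noise (default sd 0.2 cycles); with noise on every
well, correlated control/calibrator error roughly triples the estimate
spread relative to noise on the test sample's target wells only — both
scopes are available and tested, and the estimator is unbiased to first
order in either.

## Problem sizes and tolerances

The shipped tests run at sizes chosen so the whole suite completes in about
a minute: 1/10-scale units (4.3 kb) for round-trips and pipeline runs, 100
full-rate 5 kb units for caller precision/recall (≥ 0.95), 50 replicates of
a 3.2/1.3 kb IGS/transcribed contrast for the 2:1 ratio (±15%), 500
sequences ≤ 18 nt for fold-enumeration equality, 200 randomization cases of
an 80 nt window for P-value calibration, and six full-scale 43 kb units at
a uniform 1.5 variants/kb for pairwise divergence (expected ≈ 2·1.5·43 ≈
129 variants per pair). Exact checks (hook arithmetic, round-trips,
fold-oracle equality, length conservation) carry no tolerance at all.

## Known limitations

- Background sequence is i.i.d.; no microsatellites, homopolymers, GC
  gradients or sub-repeat structure within the IGS.
- No read-level simulation: assemblies are exact rotations with exact
  duplications, so finishing accuracy on noisy long-read consensus is
  untested beyond the approximate vector-location path.
- Folding models are integer-scored stand-ins, not thermodynamics;
  riboSNitch calls on real rRNA require an external energy backend.
- Pairwise variant counts are aligner-parameter-sensitive; comparisons with
  externally reported means are meaningful only at the ±10% level.
- Sharing classes assume variants from all units are on one reference
  coordinate system; cross-reference lift-over is out of scope.
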