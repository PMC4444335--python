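# Methods

## Fitness model and units

A lineage's relative fitness *s* is defined as the per-generation change of
its log2 frequency ratio in a pooled competition. With deterministic
exponential dynamics, f_i(g) ∝ f_i(0)·2^(s_i·g) renormalized to sum to one,
the trajectory log2[f_i(g)/f_i(0)] equals s_i·g minus a population-mean
term common to all lineages; subtracting the slope of a neutral reference
strain removes that term exactly, which is why normalization to a reference
(fitness pinned to 0) is part of the estimation contract rather than a
cosmetic step. Pairwise competitions against a GFP-marked reference are
measured in natural-log units — the slope of ln(dark/GFP) versus
generations — and relate to the pooled unit by a factor of ln 2; both are
exposed (`gfp_competition_fitness(per_generation_log2=True)`) and neither
is silently converted.

## Slope estimation

Per-trajectory fitness is the OLS slope of log2 ratio on generations with a
free intercept. The baseline sample contributes the point (g=0, 0); because
baseline sampling noise enters every subsequent log ratio as a shared
offset, a free intercept absorbs it where a through-origin fit would bias
the slope. At least `min_points = 3` non-missing points are required (two
points always fit exactly and carry no error information); otherwise the
trajectory is reported NA. Counts receive a +1 pseudocount *before*
frequency computation; frequencies use total assigned reads per sample as
the denominator, making them robust to unassignable junk reads. Slopes
from the technical-replicate chemostats of one biological replicate are
averaged unweighted; replicates tracked in only one or two chemostats still
yield a value.

Known small-sample behavior: at low per-lineage read counts the +1
pseudocount floors declining trajectories, biasing strongly negative
fitnesses toward zero. The acceptance script reports this bias at screen
scale (~0.003–0.007 at ~470 reads/lineage/sample) and separately in the
high-count regime, where it is <1e-4.

## Replicate filtering and aggregation

Biological replicates of one Tamp are screened by the sample SD of their
fitness values; Tamps above the cutoff are dropped (`dropped_variance`),
Tamps with fewer than two usable replicates are `dropped_insufficient`.
The cutoff default is 0.05, but the intended use is calibration:
`calibrate_variance_threshold` picks the cutoff whose outcome removes a
target fraction (default 20%) of Tamps, computed per (condition, Tamp)
group. Calibrating on groups pooled across conditions would count real
between-condition fitness differences as replicate noise and was measurably
wrong (it kept 96% instead of 80% in simulation).

Aggregation: with more than 15 usable replicates the Tamp fitness is the
argmax of a Gaussian KDE (Silverman bandwidth, 512-point grid spanning
[min−h, max+h]); with 15 or fewer, the arithmetic mean. The mode is the
contamination-robust choice: replicates whose amplicons formed incorrectly
(truncated, or carrying unrelated aneuploidies) form a minority component
that displaces the mean but not the majority mode. Degenerate inputs (one
value, zero spread) return that value. SE is reported as SD/√n for both
paths so mode- and mean-aggregated Tamps are comparable; a seeded bootstrap
SE (200 resamples) is available by flag.

## Segmentation

Circular binary segmentation is implemented natively. For a segment of n
points, every arc (i, j] with all resulting pieces ≥ `min_width` (default
2) is scored by the squared pooled-variance two-sample t statistic between
arc and complement, computed for all arcs at once from cumulative sums. The
best arc (ties: smallest start, then smallest arc) is accepted if its
permutation p-value — (count+1)/(N+1) over N within-segment shuffles,
default N = 10,000 — is below α = 0.05; permutations run in batches with
early termination once significance is unreachable. Accepted cuts recurse;
afterwards adjacent segments with numerically identical means are merged.
Zero pooled variance with unequal means scores +∞ (a clean step splits even
without noise); a constant segment scores 0 and never splits.

Segmentation runs per chromosome. Arms are not segmented separately, but a
boundary whose flanking points straddle the centromere is excluded from
Upstep/Downstep classification, because the telomere direction that defines
the classes is undefined across the centromere. Classification evaluates
delta = telomere-side mean − centromere-side mean using the flanking
points' arm (right arm: higher coordinates are telomere-side; left arm:
lower). The breakpoint *region* is the closed interval between the flanking
Tamps' initiation points — closed, so the gene at which the telomere-side
Tamp initiates belongs to the region — and gene collection adds
`extra_centromeric = 1` gene on the centromeric side to compensate for
segmentation insensitivity at the boundary.

No smoothing, outlier shrinking, or undo-splits heuristics are applied; the
permutation test and minimum plateau width are the only accept/reject
criteria.

## Synthetic data generator

The simulator emulates the screen end to end: a toy genome (programmatic,
configurable chromosome count/length/gene density); per-condition
piecewise-constant landscapes with breakpoints placed midway between
adjacent Tamp initiation points, a configurable fraction shared across
conditions; Poisson(26)-distributed biological replicates per Tamp; three
technical chemostats; ten timepoints over 25 generations; multinomial read
sampling at configured depth. Strain-construction errors flag each
replicate aberrant with probability 0.5 (0.2 for a targeted pool): the
replicate then realizes the landscape value at a truncation point drawn
uniformly from gene boundaries telomere-ward of its initiation gene —
larger amplicons thus have more truncation opportunities, reproducing the
observed size-dependence without asserting a distribution — or, with small
probability, carries an unrelated additive offset (other large
aneuploidies). Each Tamp also carries a neutral-background fitness drawn
uniformly from [−0.05, 0.04], the fitness range of the deletion strains
such pools are built from.

Selection dynamics are deterministic (no within-chemostat drift): the
fitness being estimated is a deterministic slope and sequencing noise
dominates at realistic depths, so all stochasticity enters through the
multinomial read draw. The dilution rate (0.17 h⁻¹) is informational; the
model is parameterized in generations. Pairwise GFP trajectories start at
50/50 with expected ln(dark/GFP) = s·ln 2·g and optional binomial counting
noise. aCGH profiles place probes on a grid with expected log2 ratio
log2((f·c + (1−f)·ploidy)/ploidy) plus Gaussian noise.

What passing synthetic tests do **not** show about real data: PCR and
transformation biases in barcode abundance, chemostat-to-chemostat
environmental drift, de novo mutation during the assay, barcode sequencing
errors beyond exact/Hamming matching, and non-uniform truncation-point
preferences are all absent from the generator; real screens can violate any
of them.

## aCGH population frequency

The population copy number over a region is ĉ = ploidy·2^(mean probe log2
ratio) (arithmetic mean — the mixture algebra is linear in copy number, not
in log ratio). When the clonal copy number is unknown it is taken as ĉ
rounded up to the next integer above the baseline. The clone frequency is
(ĉ − baseline)/(clonal − baseline), clamped to [0, 1]; values below the 6%
detection limit are flagged. An explicitly supplied clonal copy equal to
the baseline is an error (the mixture fraction is undefined). The recovery
tolerance used in tests is the *mean* absolute error over 100 trials
(<0.02 at probe noise sd 0.1, ≥50 probes): the per-trial error is bounded
below by the probe-averaging SE (≈ ploidy·ln2·2^m̄/(clonal−baseline) ×
sd/√n_probes ≈ 0.01–0.02), so a per-trial bound at 0.02 would be
unattainable at that noise level.

## Statistics

The exact Wilcoxon rank-sum test enumerates all C(nA+nB, nA) assignments of
the midranks for combined n ≤ 12 and counts assignments whose rank sum
deviates from its mean at least as far as observed (two-sided); larger
samples use the tie-corrected normal approximation with continuity
correction. Fisher's exact test sums hypergeometric probabilities of all
tables at most as likely as the observed one; Holm–Bonferroni multiplies
sorted p-values by (m − rank + 1) with monotonicity enforcement and capping
at 1. Both are cross-checked in tests against the scipy implementations,
which are never used as the implementation. The Downstep/Upstep single-gene
fitness contrast and the pleiotropy comparison use an unpaired two-tailed
t test, pooled variance by default with Welch available by flag.
Pleiotropy is the between-condition sample variance (ddof = 1).

## Orchestration and determinism

Every stage communicates through files in the run directory; the manifest
records the configuration hash, seed, and per-stage timings. All randomness
flows from one `numpy` generator seeded by the run seed, so identical
config + seed give byte-identical numeric outputs (asserted in tests). The
CLI exposes `simulate`, `count`, `fit`, `segment`, and the all-in-one
`run`; the cross-condition analysis and report stages execute inside `run`,
where the per-condition segment objects they consume are in memory.

## Problem sizes

Test-suite simulations use 1–2 toy chromosomes with 8–40 genes and read
depths of 2×10³–10⁶; CBS properties use profiles of 30–60 points with
1,000–2,000 permutations; these sizes make each property statistically
decisive while keeping any single test under a minute. The acceptance
script runs the full screen at 4 chromosomes × 40 Tamps × ~26 replicates ×
3 chemostats × 10 timepoints × 3 conditions at depth 10⁶ (about 4,200
lineages), plus 40 low-complexity pools for the high-count slope-bias
measurement.

## Known limitations

- The end-to-end breakpoint recall reported by the acceptance script
  (~0.4–0.7) is limited by the planted neutral-background jitter (sd
  ≈0.026), which acts as irreducible per-point noise on the landscape;
  steps below ~2× that jitter are genuinely undetectable at the profile
  densities simulated. The segmentation itself meets precision/recall ≥0.9
  in the low-noise regime (per-point SE ≤0.015, effect ≥0.05).
- Bar-seq slope estimates are biased toward zero for strongly deleterious
  lineages at low read depth (pseudocount censoring); depth is the remedy.
- Barcode matching is exact or fixed-radius Hamming; no quality-aware or
  indel-tolerant matching.
- No hierarchical shrinkage across Tamps, and no modeling of interactions
  between co-amplified genes: amplicon fitness prediction uses the
  landscape value at the initiation point, which is exactly what a
  Tamp-style amplicon measures but ignores internal synergies.
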