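# Methods

This note documents the models, conventions and numerical choices
behind `methclock`, and what the synthetic-data generator does and does
not emulate.

## Quantification model

Per (sample, marker), methylated and unmethylated read counts arrive
per strand (Watson `W`, Crick `C`). CpG methylation is symmetric, so
counts from both strands are summed when the assay reads both; markers
read on a single strand pass through unchanged. The beta value is
`ME / (ME + UM)` on the merged counts.

**Read-depth threshold.** A merged total below `min_reads` (default 50)
yields a *missing* call. Two comparators are intentionally different:

* pass/fail is inclusive — `total >= min_reads` passes, i.e. only sites
  with *fewer than* 50 reads become missing;
* coverage summaries use strict `depth > t` ("covered more than t ×").

Raising the threshold can only remove calls (monotonicity; tested).
Betas are stored at full precision; rounding to 2–3 decimals happens
only in reports.

**Conversion QC.** The conversion rate from unmethylated lambda
spike-ins is `100 · UM / (ME + UM)` with counts *summed* across lambda
amplicons before the ratio (count-sum pooling, rather than averaging
per-amplicon rates; the two agree at equal depths, and count-summing
weights amplicons by evidence). Zero pooled depth gives a missing rate,
not 0. The non-CpG-cytosine route for capture protocols is the same
pooled ratio over non-CpG cytosines within targets. Lambda markers live
on the reserved chromosome `lambda` and are ordinary panel rows, so the
quantifier has no special case; they are excluded from beta matrices
and routed to QC.

**Normalized depth.** Per-marker depth divided by total mapped reads;
the "perfect distribution" reference line is `1 / n_markers` of the
on-target total. Published figures for comparable assays quote expected
normalized depths (≈0.00060–0.00065) whose denominator is not stated;
this package deliberately uses the transparent `1/n` definition rather
than reverse-engineering a constant.

**File formats.** Counts are read from an internal long TSV
(`sample_id, marker_id, strand, n_meth, n_unmeth`) or from Bismark-style
cytosine coverage files (chromosome, start, end, methylation %, count
methylated, count unmethylated). The percentage column of coverage files
is ignored and recomputed from the counts, guarding against
inconsistent inputs. Panel coordinates are 1-based throughout;
0-based conversion happens only at format boundaries.

## Clock engine

All four estimators share the linear form `intercept + Σ wᵢ·βᵢ` and
differ only in marker sets, weights and units (years for the two age
clocks; pace-of-aging units; MRS units). Missing markers are
mean-imputed from a per-clock means table before prediction; imputation
never alters observed values, is idempotent, and its count is carried on
every output. Platform gaps (markers absent from a technology) go
through the same imputation path — no platform special-casing.

The categorical mortality score is exposed through two routes, because
the field uses both: (a) a per-marker threshold rule counting
risk-aberrant CpGs (strictly beyond the threshold in the risk
direction), and (b) a quadratic map from the calibrated continuous
score, rounded and clipped into [0, 10]. The fixture rule uses
threshold = imputation mean and direction = sign of the continuous
weight. Score interpretation: 0 = reference; 1 ≈ two-fold, 2–5 ≈
three-fold, >5 ≈ seven-fold increased all-cause mortality risk.

## Calibration

Cross-technology bias is corrected on *clock outputs*, never on betas
(all published calibration equations for this panel act on prediction
outputs). Fitting is plain OLS (degree 1 or 2) — a documented
simplification, since both axes carry error; the fitted direction
matches the application direction (raw output on x, reference on y).
Degenerate designs (constant x, rank-deficient quadratic design) raise
errors rather than returning unstable coefficients. Six published
transforms ship as constants in `builtin_transforms()`; their source
cohort is not available, so they are not re-derived.

## Synthetic-data generator

The generator produces the three study designs this kind of assay is
validated with:

* **standards7x2** — methylation standards at beta 0, 0.10, 0.25, 0.50,
  0.75, 0.90, 1, in duplicate (14 libraries);
* **sensitivity16** — levels 0.25/0.75 at DNA inputs 50/25/10/1 ng in
  duplicate (16 libraries), with read depth scaled ∝ input;
* **blood5x2** — donors aged 7, 28, 46, 61, 78 years in duplicate
  (10 libraries).

**Error model.** A read reports methylation with probability
`p = β·(1−f) + (1−β)·(1−c)`, where `c` is the bisulfite conversion rate
(default 0.998) and `f` the inappropriate-conversion rate for methylated
cytosines (default 0.005). Two channels rather than one because
conversion failure is measured from unmethylated lambda while
methylated-read loss is a physically distinct process. Per-target depth
is log-normal (`coverage_mu = log 3000`, `coverage_sigma = 1`), giving a
median ≈ 3000 reads with a heavy right tail — the order observed for
amplicon assays of this panel size, as a default, not a distributional
claim. For both-strand markers, reads are split binomially between
strands (default 0.5) and the strands sampled independently. At low DNA
input, precision is molecule-limited regardless of depth; this is
modeled by resampling each marker's methylation state over
`round(input_ng · 300)` template molecules (~300 haploid copies/ng).
All randomness flows through one `numpy.random.default_rng` (PCG64)
stream per generated dataset, so a fixed seed is bit-reproducible.

**Blood cohorts invert the clock.** Given a generating clock with
weights `w` and means `μ`, a baseline `m = μ + δ·w` is chosen so the
clock evaluates to the cohort reference age a₀ (the mean requested
age), and each donor's betas are `m + w·(age − a₀)/Σw²`, so the clock
applied to noise-free betas returns the age *exactly*. Betas are
clamped to [0.01, 0.99]; if clamping shifts the round-trip by more than
0.1 years, generation fails loudly with an instruction to rescale the
clock. Biological noise (per-donor Gaussian on the beta scale) is
shared between a donor's technical replicates; counting noise is not.
Only the generating clock tracks age — other markers sit at stable
age-independent baselines, so cross-clock age correlations in simulated
cohorts are a property of the generator, not a biological claim.

**Platform bias** is an affine (or quadratic) transform applied to true
betas before sampling, clamped into [0, 1]; the unbiased truth is kept
alongside so calibration can be scored against it.

**What the generator does not emulate:** read-level artifacts (FASTQ,
alignment error, PCR duplicates), amplicon dropout genetics,
marker-specific amplification efficiency (depths are i.i.d. across
markers), cell-type composition, and real inter-individual methylation
variation. Passing tests therefore demonstrate the *statistical
machinery* is correct under the stated error model — not that real
assays achieve the simulated accuracy. In particular, simulated
accuracy (≈0.007 mean |observed−expected| beta at default depth) is far
better than real assays (≈0.05–0.12), because real error is dominated
by chemistry and amplification effects the generator deliberately
omits.

## Evaluation conventions

* Missing cells are handled pairwise-complete (a cell is dropped when
  either side of a comparison is missing); metrics describe measured
  values only.
* All SDs use the n−1 denominator (validated against the duplicated
  donor-age cohort: ages 7–78 duplicated to N = 10 give 44.0 ± 26.1).
* Spearman correlation is the product-moment correlation of mid-ranks
  (ties averaged), via `scipy.stats.spearmanr`.
* Per-level variability of standards is computed per-marker-then-
  averaged ("mean standard deviation"); a pooled alternative is exposed
  via `per_level_sd(..., pooled=True)` since either convention is
  defensible.
* Clock cross-correlations warn below 10 samples; a constant clock
  yields a missing correlation, not an error.
* MAE against chronological age is only reported for clocks whose
  output unit is years.

## Problem sizes and determinism

Tests and the acceptance script use the full 161-marker fixture panel
where panel structure matters, and a small 8-marker panel with a
4-marker clock for simulation-heavy Monte-Carlo properties (20 seeds
for the calibration-improves-MAE and noise-monotonicity properties;
6–10 seeds for variance-profile properties) — sizes chosen so the whole
suite is a desk-scale computation while keeping the binomial-noise
regimes the properties assert about. The quantify → clocks → calibrate
chain contains no randomness; all stochasticity lives in the generator
behind a named seed.

## Known limitations

* OLS calibration ignores error in the predictor axis (no
  errors-in-variables treatment).
* The fixture panel and clocks are synthetic: correct structure (marker
  counts, overlaps, strand availability, units), placeholder content.
* The threshold rule and the quadratic continuous→categorical map for
  the mortality score are both plausible readings of how the
  categorical score is produced; both are provided, neither is claimed
  canonical.
* Bismark ingestion assumes strand-collapsed coverage files; per-strand
  coverage files should be merged upstream or supplied via the internal
  count format.
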