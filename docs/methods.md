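# Methods

This note documents the statistical models implemented in `dysbiokit`,
their assumptions, the parameters that matter, the design choices made
where the design was genuinely open, and the limits of what the synthetic
cohort can certify about real data.

## The synthetic cohort generator

The generator emulates a year-long IBD cohort so that every downstream
stage can be validated against known ground truth.

### Latent dysbiosis state

Each subject carries a two-state (eubiotic/dysbiotic) alternating process
with memoryless sojourns, starting eubiotic. Two time scales are offered:

- **`state_process="grid"` (default).** A discrete-time Markov chain on the
  sampling grid: at each step of `sampling_interval` weeks the chain leaves
  its state with probability `interval / mean`, giving geometric sojourns
  with the configured mean in weeks — the memoryless distribution at the
  observation resolution. Episode-duration ground truth is thereby planted
  at the scale at which episodes are *observed*: the time from the first
  dysbiotic sample of an excursion to the next non-dysbiotic sample equals
  the sojourn itself, and the censored exponential MLE recovers the
  configured means essentially unbiasedly (replicate-mean error ≤ ~3% at
  40 subjects x 20 seeds; `scripts/acceptance.py`).
- **`state_process="continuous"`.** An alternating renewal process with
  exponential sojourns in continuous time, discretised by the state holding
  at each sampling time. We implemented and measured this variant first:
  with 2-weekly sampling and sojourn means of a few weeks, sojourns shorter
  than the sampling interval are missed entirely and merge adjacent runs,
  inflating *observed* episode lengths by ~20–35% at the default means.
  Since the estimand the episode pipeline reports is the mean of observed
  episodes, the grid process is the right ground-truth model for recovery
  studies; the continuous variant remains available for studying exactly
  this discretisation bias (its continuous-time transition times are
  retained on the series).

Per-diagnosis sojourn means default to duration/interval = 7.8/12.8 weeks
(CD) and 4.1/17.2 weeks (UC). Non-IBD subjects run the same process with
duration 4 weeks and interval 60 weeks, i.e. a stationary dysbiotic-state
fraction of ~6%. The earlier candidate of ~10% was rejected for a
structural reason: the classification threshold is the 90th percentile of
the non-IBD score distribution, so whenever the non-IBD dysbiotic-state
fraction drifts above 10% the threshold provably lands *inside* the
dysbiotic score distribution and whole low-scoring subjects fall below it.
Keeping the non-IBD state fraction safely under the threshold quantile
places the decision boundary in the gap between the two score
distributions, which is the regime the scoring method is designed for
(sample-level sensitivity 0.91–1.0 across seeds at default effect size).

### Compositional profiles

Log-scale abundance of taxon *f* in subject *s* at time *t*:

    log a = base_f + subject_{s,f} + z_{s,f,t} + delta_f * state_{s,t}

with cohort-level taxon means `base_f ~ N(0, 1.5)`, subject offsets
`subject ~ N(0, subject_sd)` (default 0.7), an AR(1) temporal process
(`ar_coefficient` 0.7, innovation sd `temporal_sd` 0.6, stationary
initialisation), and a dysbiosis effect `delta_f = ±effect_size` (default
3.0 on the log scale, i.e. ~20-fold) on 40 of 100 taxa (20 depleted, 20
enriched). Exponentiation and total-sum scaling close each sample to
relative abundances; scheduled samples are dropped independently with
`missingness_prob` 0.1.

Why these defaults: dysbiosis in IBD is a broad restructuring — obligate
anaerobes depleted, facultative anaerobes enriched, affecting dominant
clades — so a large responsive fraction with strong fold changes is the
emulated regime, and it yields species-level Bray–Curtis thresholds of
0.55–0.70, in the range seen for real inter-individual gut comparisons.
The log-normal + AR(1) construction (rather than a Dirichlet) separates
between-subject from within-subject variance, producing the observed
ordering intra < inter dissimilarity with an upward trend in Δt. A
metabolite-like coupled table shifts its responsive features by
`coupling_strength × effect_size` with otherwise independent noise.

Randomness is fanned out through named substreams
(`default_rng([seed, stream, group, subject])`), so identical seeds give
byte-identical cohorts and adding subjects never perturbs earlier
subjects' draws.

### What the generator does not emulate

Read-level sequencing noise, taxon-taxon ecological interactions,
zero-inflation beyond what log-normal closure induces, diet, serology,
host expression, medication dynamics, or drifting baselines. Passing
recovery tests on this cohort certifies the *estimators* under their
stated assumptions — not robustness to every property of real microbiome
data.

## Dysbiosis scoring and episodes

- Reference set: non-IBD samples strictly after week 20 of each subject's
  series ("after the 20th week" read as `week > 20`; configurable).
- Score: median Bray–Curtis to the reference, excluding same-subject
  references. The median makes the score robust to the ~10% of reference
  samples that are themselves in a disturbed state.
- Threshold: linear-interpolation (type-7) percentile — the default
  quantile definition across the numerical ecosystem — of the non-IBD
  scores; classification is strictly greater-than, so ties at the
  threshold are non-dysbiotic.
- Episodes: runs in progress at the *start* of a series are ambiguous on
  the left and excluded by default (`include_initial_run=True` keeps
  them); runs truncated by series end are right-censored at the last
  sample. The censored exponential MLE is `sum(lengths)/n_uncensored` with
  SE `mean/sqrt(n_uncensored)`; it equals the numeric maximiser of the
  censored exponential likelihood (tested to 1e-6). Kaplan–Meier curves
  use the product-limit estimator with events before censorings at ties
  (via `lifelines`).
- Cross-type concordance: sample odds ratio of the matched 2x2 table with
  a Haldane–Anscombe 0.5 correction only when a margin is empty, and a
  two-sided Fisher exact p.

## Shift detection

Within-subject pairs of reference (non-IBD) subjects are windowed by time
gap into bins centred on multiples of the sampling interval; bins with
fewer than 30 pairs pool upward into the next bin. Per window, a Gaussian
KDE of the windowed within-subject dissimilarities is compared on a
512-point grid over [0, 1] with the KDE of all between-subject
dissimilarities; the raw threshold is the smallest dissimilarity above the
within-density mode where the between-density exceeds it (linearly
interpolated at the crossing), and the final curve is the running maximum
over increasing gap. Restricting the search to above the mode prevents
KDE tail artefacts at low dissimilarity from triggering; if no crossing
exists above the mode (e.g. the between-distribution sits wholly below
the within-distribution), the scan falls back to the whole grid, so an
inverted geometry still calls essentially every pair. Bandwidths are
Sheather–Jones solve-the-equation (binned implementation, matching R's
`bw.SJ` to <1% on test samples) with a Silverman fallback below 20
points. A single-threshold variant pools all gaps for sparsely sampled
measurement types.

Shift attribution reports the per-feature signed abundance change across
the pair; the primary contributor is the largest absolute change with
exact ties broken toward the lexicographically smaller feature ID. Shift
rates divide call counts by observed consecutive-pair time (52-week
years).

## Temporal statistics

- **Power law.** `d = a·Δt^b + c` by derivative-free least squares: the
  model is linear in (a, c) for fixed b, so b is profiled on a dense grid
  over [-5, 5] and refined with Brent's method. The unconstrained exponent
  family matters for inference: restricting b ≥ 0 makes the F-test against
  the flat line conservative (measured type-I ~0.028 at nominal 0.05),
  whereas the free family is calibrated (~0.045–0.048). The F-test uses
  k = 3 vs 1 parameters; the group comparison nests one joint fit inside
  per-group fits (3 vs 3g parameters).
- **Mantel.** Cross-sectional: Pearson correlation of subject-level
  distance matrices (feature-wise mean profile per subject, no
  renormalisation needed — a mean of compositions is a composition), null
  by free permutation of subject labels, one-sided (greater).
  Longitudinal: correlation over within-subject sample pairs only, null by
  permuting sample labels independently within each subject block — the
  permutation never crosses subjects (audited in tests).
- **PERMANOVA.** Single-variable distance-based linear model: pseudo-F and
  R² = SS_model/SS_total from the Gower-centred matrix (trace identities
  make each permutation O(n²)). Permutation schemes: `within-subject` for
  time-varying variables, `subject-relabel` for subject-constant variables
  (whole subjects' values permuted, samples relabelled — constancy within
  subject is preserved in every permutation), `free` otherwise. Missing
  numeric covariates are mean-imputed. All permutation p-values are
  `(1 + #{perm ≥ obs}) / (1 + n_perm)`; the default `n_perm` is 999.
  Multi-term models are out of scope by design — each variable is tested
  as the sole model term, which avoids order dependence.

Measured type-I error at α = 0.05 (500 replicates, matched-scheme nulls):
blocked PERMANOVA ~0.056, within-subject Mantel ~0.054, power-law F-test
~0.048.

## Matching

The greedy left-to-right algorithm scans window starts over the sorted
union of remaining sample weeks (any feasible window can be slid left to a
sample week without losing members, so the first feasible window is
found). Inside a window, the target week is the one where most types have
a sample exactly (ties earliest); per type the nearest in-window sample is
selected (ties earlier); everything up to the later of selection and
target is then discarded per type. Samples are used at most once.
One caveat discovered by property testing: the number of matched sets is
*not* globally monotone in the window width — a wider window can merge two
near-coincident strict sets into one. The implementation documents this
instead of pretending otherwise.

## Mixed models and networks

The random-intercept LMM is profiled REML: for
θ = σ²_subject/σ²_residual, the per-group covariance inverse is
closed-form, θ is minimised on the log scale (coarse grid then bounded
refinement over [1e-8, 1e8], with the θ→0 boundary always a candidate),
and GLS coefficients, Wald z/p, and conditional residuals
`V⁻¹(y − Xβ)` — exactly orthogonal to the fixed-effect design — follow in
closed form. The fit matches `statsmodels` MixedLM on test instances and a
1,000-point θ-grid oracle everywhere.

Recruitment site enters as a fixed categorical covariate rather than a
second random effect: this keeps the model to one variance component with
an exact 1-D profiled REML while preserving the adjustment; with a handful
of sites the fixed-effect treatment is statistically reasonable and the
choice is noted in outputs.

Differential abundance applies the variance-stabilising transform
appropriate to the measurement type (arcsine square root for relative
abundances; log with pseudocount 1 for intensities; plain log for ratio
scales with non-finite values dropped), a prevalence/variance filter
(features with >90% zeros or no variance removed), per-feature LMM fits
with diagnosis and nested within-diagnosis dysbiosis terms, and BH
adjustment per term across features.

A calibration caveat measured during development: with the generator's
default AR(0.7) temporal autocorrelation, the Wald test on the
*time-varying* dysbiosis term is anticonservative (~0.15 at nominal 0.05)
because the model's covariance (random intercept + white noise) omits the
residual autocorrelation that the state sequence shares. The same caveat
applies to any random-intercept-only analysis of autocorrelated
longitudinal data. Calibration claims in the test suite are therefore made
under the model's assumed covariance (AR coefficient 0), where the
measured type-I error is 0.04–0.07.

Residualisation uses the same machinery with a plain (non-nested)
dysbiosis indicator, optionally omitted (the *unadjusted* variant, which
deliberately leaves dysbiosis-driven covariation in the residuals);
subjects with fewer than four samples are dropped for longitudinal
measurement types, and baseline-only types use fixed-effects OLS. The
association network computes all-against-all Spearman correlations
(average-rank ties, t-approximation p-values) between residual tables of
distinct measurement types on temporally matched samples (min. 8 shared),
BH-adjusts within each type pair, applies the pair's FDR tier (0.05
standard, 0.25 for serology-type measurements), optionally restricts to
edges touching dysbiosis-associated features, keeps the top 300 edges per
pair by ascending p (ties by |rho| descending), and flags nodes of degree
≥ 20 as hubs. Flat all-against-all testing with BH replaces hierarchical
association testing by design.

## Numerical choices and degenerate inputs

- Quantiles: type-7 (linear interpolation) throughout.
- All-zero samples are rejected before Bray–Curtis or normalisation
  (undefined denominator); all-zero features are allowed and removed by
  the prevalence filter.
- Zero-length censored episodes (single-sample runs at series end) are
  retained; they add observation weight of zero and no event.
- Transcription ratios with a zero metagenomic denominator are missing
  values, not errors.
- Bray–Curtis is a dissimilarity, not a metric; no triangle inequality is
  asserted anywhere.
- The KDE grid is 512 points on [0, 1]; crossings are linearly
  interpolated between grid points.

## Problem sizes used in the test and acceptance runs

Unit and integration tests run on cohorts of 12–40 subjects (500–1,200
samples); episode-recovery experiments use 40 subjects x 20 replicate
seeds (~2,000 episodes per condition); calibration experiments use 500
null replicates with 199 permutations each; the differential-abundance
null uses 500 features across 30 subjects. These sizes put Monte-Carlo
error comfortably inside the asserted tolerances while keeping a full run
of suite plus acceptance script in a few minutes on one CPU.

## Known limitations

- The classification pipeline's episode statistics inherit classification
  noise; at realistic cohort sizes the per-group censored MLE carries
  standard errors of 1–2 weeks (the README example shows this).
- Wald inference in the LMM is asymptotic in the number of subjects; no
  small-sample (Satterthwaite/Kenward–Roger) correction is implemented.
- The power-law F-test treats the profiled exponent as a regular
  parameter; its calibration was verified empirically rather than derived.
- The greedy matcher is order-optimal for the stated rules but not
  globally optimal in the number of matched sets.
- Network edges are marginal Spearman associations on residuals;
  no partial-correlation or hierarchical structure is inferred.
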