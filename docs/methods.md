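# Methods

## The retrodiction model

A calibration study assigns each condition a standard score `s_c` and
records, per subject × condition × method, a measured score `y`. The
retrodiction model regresses `s` on an intercept plus `y` — the
direction is deliberate: the measurement is judged by how well it
recovers the manipulation, and an intercept-only null ("a constant
measurement, identical across standard scores") is the common baseline
every method is compared against. Under repeated measures the predictor
is replaced by its deviation from the participant's mean, which removes
stable between-person offsets and is equivalent, in residual sum of
squares, to participant-level intercepts.

### Degrees of freedom

The published statistic for two-condition designs is the within-subject
Cohen's d (`d_z` = mean condition difference / SD of the differences),
interconvertible with the paired t via `t = d·√N`. For the centered
regression on balanced two-condition data one can show algebraically
that converting the regression correlation `r` to a t-statistic at
`df = N − 1` reproduces the classical paired t exactly; the test suite
verifies this to 1e-10 against `scipy.stats.ttest_rel`. We therefore
adopt:

* two-condition, one observation per cell, balanced: `df = N − 1`
  (summary-level studies use the same convention);
* any richer repeated-measures design: `df = n_obs − n_subjects − 1`
  (slope plus one intercept per subject). This convention is a package
  choice — the general repeated-measures df is not uniquely pinned down
  by the d_z equivalence — and is exposed via the `df_rule` knob
  (`auto`/`paired`/`per-observation`).

`sd_within` (the calibration σ_c used in power analysis) is the pooled
within-condition SD: per-condition variances with Bessel's correction,
pooled by their df. It is invariant to shifting all measured scores.

## Evidence synthesis

Study t-statistics are combined by fixed-effect inverse-variance
weighting with `w_k = sqrt(v_k⁻¹ / Σ v_j⁻¹)` (so `Σ w_k² = 1`; equal
variances recover Stouffer's `√K` scaling) and `T̃ = Σ w_k T_k`. For
`v_k` we use the central-t variance `df_k/(df_k − 2)`; an
effect-size-dependent variance (noncentral t) would be an alternative,
but the null-distribution variance is the conventional choice and the
rule is pluggable (`variance_rule`). Studies with `df ≤ 2`, where this
variance is undefined, are excluded from the combination with a logged
warning rather than failing the analysis.

The combined statistic maps to a Bayes factor against the
intercept-only null under a Gaussian linear model with a g-prior:

    2·log BF₁₀ = (N−2)·log(1+g) − (N−1)·log[1 + g·(T̃²/(N−2) + 1)⁻¹]

All Bayes factors are reported on the natural-log scale. `N` is the
summed sample size of the studies actually combined for that method; in
raw repeated-measures data we count subjects, not observations (the
two-condition paired design has one effective difference per subject).
`g` defaults to `N` (unit-information prior) and is configurable
(`g_rule = "total-n"` or a fixed positive value). At `T̃ = 0` the
expression collapses to `−log(1+g)`, so the null evidence scales with
the prior spread, and the factor is strictly increasing in `T̃²`.

Per-study Bayes factors are never multiplied across studies: marginal
likelihoods of separate datasets do not compose that way (later data
must be evaluated conditionally), which is why synthesis happens at the
test-statistic level.

### Overlap bookkeeping

Cross-method comparisons computed on non-identical study sets are
reported with the summed subject overlap of the two methods (studies
containing both; in a complete within-study design the per-method
counts coincide, otherwise the smaller enters the sum). No correction
is applied; instead an overlap-restricted re-analysis (`restrict_to` /
`refit_restricted`) recomputes the evidence on the studies containing
every compared method. Rankings sort by log BF₁₀ descending with ties
broken by method name for determinism.

In `accumulate_evidence`, stages are prefixes of the (date, study_id)
ordering; dates are year-month strings and ties break lexicographically
by study id (the bundled corpus has three studies sharing 2018-07).
Stages that add no study containing the method carry the previous
result forward; stages before a method first appears yield `None`.

## Decision analysis

Minimum relevant effect sizes:

* direct: `d = α·μ_min/σ_c`, with attenuation `α = σ_c/σ ∈ (0,1]`
  encoding extra variability in the substantive experiment (α = 1 gives
  the upper bound `μ_min/σ_c`);
* embedded: `d = α·f·d_c`, a fraction `f` of the calibration effect
  size `d_c` (e.g. "the treatment-arm condition difference must exceed
  the placebo arm's by 50%" gives `f = 0.5`). `d_c` is supplied by the
  user (scalar or per-method mapping): the pooled calibration effect of
  a method is in general not recoverable from a summary table alone,
  and inverse-variance pooling of the bundled table's per-study d
  values does not reproduce the `d_c` values a full raw-data pooling
  yields, so the package does not guess one.

Required per-group n for a two-sample t-test uses, by default, the
normal-approximation formula `n = ceil(2·(z_{1−α*} + z_{power})²/d²)`
with `α* = α` one-tailed and `α/2` two-tailed. An exact noncentral-t
mode (statsmodels' `TTestIndPower`) is available via
`algorithm="exact"`; it is typically one subject more conservative
(53 vs 52 at d = 0.49, where the approximate n of 52 achieves power
0.799). The approximation is the default because it is the classical
closed form and self-consistent with the z-based reasoning above; both
modes are logged by the CLI.

Economics: `participants_saved = groups·(n_current − n_candidate)` and
`net_benefit = participants_saved·cost_per_subject − switch_cost`, both
allowed to be negative. Money is a plain decimal with a currency label;
no conversion. Non-quantifiable benefits (prestige, training value) are
out of scope.

## Synthetic data generator

The generator emulates two-condition within-subject calibration
studies: true score `τ_jc = s_c + aberration`, measured score
`y = loading·τ + subject_effect + noise`, all Gaussian. Defaults:
standard scores ±1 (CS+/CS− analogue), aberration SD 0.3, subject
effect SD 0.5, 15–30 subjects per study — values chosen as a plausible
mid-size psychophysiology study with a moderately effective
manipulation; they are deliberately fixed rather than tuned.
Availability is an independent Bernoulli per study × method, resampled
until at least one method is present. Randomness is split into streams
keyed by (seed, study index, purpose, method), so adding a method never
perturbs the other methods' draws and every corpus is reproducible from
its seed.

What the generator does *not* emulate: raw physiological time series
and their preprocessing, non-Gaussian noise, heteroscedastic conditions,
serial dependence across trials, systematic between-study heterogeneity
(drifting aberration, site effects), or informative missingness
(availability correlated with study size or date). Passing tests
therefore show that the inferential machinery recovers ground truth
under its own assumptions — a necessary check — but not that those
assumptions hold for any particular real dataset.

## Numerical and degenerate-input choices

* `log1p` is used throughout the Bayes-factor formula for stability at
  small g or t.
* A centered predictor with zero variance, a perfect fit (|r| = 1),
  fewer than 3 subjects, or non-positive residual df raise
  `DegenerateFitError` rather than returning infinities.
* `variance_of_t` refuses `df ≤ 2` (`UndefinedVarianceError`); at the
  corpus level such studies are skipped with a warning and recorded in
  `EvidenceResult.studies_excluded`.
* Subjects missing a condition are dropped from the d_z computation but
  retained in the regression fit; both counts are logged.
* Readers drop rows with missing measured scores (count retained on the
  corpus), reject non-constant standard scores within a condition, and
  flag unbalanced designs instead of rejecting them.

## Problem sizes

The test suite and the acceptance script run the bundled nine-study
corpus exactly as shipped; the synthetic ranking-recovery experiment
uses 100 replicates of 10 studies × 50 subjects × 3 methods (500
subjects per replicate), and the pipeline-level type-I check uses 1000
single-study replicates of 24 subjects. These sizes give stable Monte
Carlo rates (binomial SE ≈ 0.7 percentage points at 1000 replicates)
while keeping a full run in tens of seconds.

## Known limitations

* Fixed-effect synthesis assumes a common retrodictive effect across
  studies; random-effects or meta-regression extensions for structured
  heterogeneity are not implemented.
* The central-t variance rule ignores the noncentrality of study
  statistics under the alternative; with strongly heterogeneous df this
  slightly misweights studies.
* Summary-level studies are assumed balanced two-condition designs with
  `df = N − 1`; the table format carries no information to verify this.
* Bayes factors for methods measured on different study subsets are
  comparable only under data homogeneity; the overlap annotation and
  the restricted re-analysis are diagnostics, not corrections.
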