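# Methods

## The model

`trajspur` fits group-based trajectory models (GBTM): finite mixtures of
polynomial trajectories for repeated measures `y_i1..y_it` of `N` subjects,

    P(Y_i) = Σ_j π_j Π_t f(y_it | β_j·poly(time_t), σ),

where each latent subgroup `j` has its own polynomial mean curve (order ≤ 3)
and `f` is a censored normal: the normal density between the scale bounds
with the tail masses collected at the bounds (with infinite bounds, exactly
the normal).  Two assumptions define GBTM and drive everything this package
studies: **zero within-subgroup variation** around the group curve, and a
**single residual SD σ shared by all subgroups and occasions**.  Posterior
membership probabilities follow from Bayes' rule; subjects are classified by
the maximum-probability rule.

The latent class growth model (LCGM) used for sensitivity analysis relaxes
the first assumption: class `j` adds a subject-level random intercept
`b_i ~ N(0, τ_j²)`, so a subject's series is multivariate normal with
compound-symmetric covariance `τ_j² J + σ² I`.  GBTM is the τ=0 special
case, which gives a cheap nesting check (`sup_τ LCGM loglik ≥ GBTM loglik`),
asserted in the tests.

## Estimation

Both models are fitted by EM.  For GBTM with infinite bounds the M-step is
exact: weighted least squares per group for β (on a centred-and-scaled time
basis; coefficients are reported on the original scale) and a closed-form σ
update, so the observed-data log-likelihood is non-decreasing across
iterations — asserted to 1e-9 in the tests.  With finite censoring bounds
the M-step is a bounded quasi-Newton improvement of the expected complete
log-likelihood (a generalized EM).  The LCGM M-step profiles each class's
GLS coefficients through the rank-one (Woodbury) identities of the
compound-symmetric covariance and improves `(τ_1..τ_J, σ)` by a few bounded
quasi-Newton steps.

Mixture likelihoods are multimodal, so every fit is multi-start: one start
partitions subjects by quantiles of their mean response, the rest are random
partitions; the best converged start is kept.  A start is discarded as
degenerate when a component's posterior mass falls below one
subject-equivalent.  Defaults: `tol = 1e-6` on the absolute log-likelihood
change, `max_iter = 500` (GBTM) / `1000` (LCGM), `n_starts = 10` for single
fits.  Group labels are reported sorted by the fitted mean at the first
occasion, so output is reproducible across runs.  LCGM non-convergence
(max_iter reached, oscillating log-likelihood, or a τ hitting the guard at
10× the data SD) is reported via `converged=False` plus a `failure_reason`,
never raised, so selection paths can report failures the way applied
analyses do.

## Selection and adequacy

The number of subgroups is chosen by the BIC approximation to the Bayes
factor.  BIC is used on the `loglik − (p/2)·log N` scale (larger is better,
`N` = subjects); walking k = 1..10, k+1 is accepted while
`2·(BIC_{k+1} − BIC_k) > 10` — the usual "very strong evidence" reading of
2·log B₁₀.  Whether the published rule meant ΔBIC or 2·ΔBIC is ambiguous;
we use 2·ΔBIC, record that in the trace metadata, and also expose a
`min_bic` rule (global BIC optimum).  After selection, each group's leading
polynomial term is tested by a Wald test (observed-information standard
errors from a finite-difference Hessian of the mixture log-likelihood, on
the scaled basis where the leading coefficient's z-statistic is invariant);
non-significant (p ≥ 0.05) leading terms are dropped greedily, groups in
label order, refitting warm-started after each reduction.  Intercepts are
never dropped.  A singular information matrix aborts pruning with a
diagnostic rather than guessing.

Classification adequacy uses three criteria: per-group average posterior
probability (APP, bar at 0.70), relative entropy
`E = 1 − Σ(−p·ln p)/(N ln J)` (bar at 0.80; the log base cancels, a knob
exists for reporting raw entropies; `J=1` returns the vacuous value 1), and
per-group mismatch `100·(π̂_j − assigned_j/N)` in percentage points (flag at
|·| ≥ 2, configurable — the literature only says "close to 0").  Mismatch
sums to zero exactly because both vectors sum to one.

## The synthetic scenarios

The six shipped scenario configurations (`trajspur/data/scenario*.yaml`)
generate, per subject, a subgroup from the mixing weights, a persistent
intercept (normal, uniform, or none), and independent occasion-level noise
around a polynomial group mean — `n = 500` subjects (300 in scenario 2) by
`t = 5` occasions.  Subject streams are keyed by `(seed, subject index)`,
so enlarging `n` never reshuffles earlier subjects.  The configurations
were calibrated once so that the selection-plus-adequacy pipeline
reproduces the documented recovery patterns, and then frozen:

1. **Three distinct subgroups** (benchmark): one rapidly increasing and two
   parallel decreasing curves, separation ≈ 2 within-group SDs.  Everything
   recovers; entropy ≈ 0.98.
2. **Different value ranges** (n = 300): a steep group spanning roughly
   twice the benchmark's range with the largest within-group spread, plus a
   mildly increasing and a mildly decreasing group that cross.  The shared-σ
   fit, its scale set by the steep group, cannot resolve the crossing pair:
   they merge into one flat trajectory holding ~66% of subjects, and — the
   instructive part — every adequacy criterion looks excellent.
3. **Time-point-specific overlap**: two increasing groups overlapping
   heavily early, a decreasing group descending into them late.  Selection
   still says three groups (numerically correct), but classification is
   poor: entropy ~0.7, one APP clearly lowest, sizes off.
4. **Increasing within-subgroup variance**: three linear trajectories from
   a common origin at time 0, persistent offsets, residual SD growing
   linearly over occasions.  The persistent offsets make each true group a
   small continuum, and the fit splits each into two parallel trajectories:
   six groups, yet all three criteria look adequate.
5. **Rainbow**: a single increasing trend with subject intercepts uniform
   on a wide band — a continuum, no subgroups.  The fit slices the band
   into three parallel trajectories; APP looks fine, entropy does not.
6. **No temporal pattern**: a flat mean with continuous normal
   subject-level heterogeneity and occasion noise — no subgroups, no trend.
   The fit reports four trajectory subgroups out of nothing.

Two calibration findings are worth recording.  First, scenario 6 *requires*
the persistent heterogeneity: with purely independent noise a multi-start
ML fit plus the Bayes-factor rule selects one group in every seed we tried —
the spurious-subgroup phenomenon on null data is driven by continuous
subject-level variation being carved into bands, not by occasion noise.
Second, in scenarios 3 and 5 a thorough multi-start fit produces *milder*
pathology than single-start software can: reference values as extreme as a
relative entropy of 0.34 at an accepted three-group solution, or a 58%
middle band from a symmetric uniform continuum, correspond to local optima
with near-duplicate components that a global fit avoids; our pipeline
reproduces the qualitative failures (entropy below the bar, one weak APP,
the largest mismatches of scenarios 1–4) but not those extreme levels.

What the generator does not emulate: missing data and dropout, unbalanced
designs (user panels may be unbalanced; the shipped scenarios are not),
non-normal residuals, and bounded/ordinal outcomes (finite censoring bounds
are supported in the fitter for user data, but the scenarios are
continuous).  Passing tests therefore say nothing about those features of
real data.

## Problem sizes and numerical choices

The study-level checks run all six scenarios over 10 replicate seeds with
5 EM starts per candidate model and k = 1..10, aggregating counts by
majority vote and criteria by means; single-fit unit tests use smaller
panels.  Tie-breaks: maximum-probability assignment resolves ties to the
lowest group index; group-to-truth matching minimises integrated squared
distance between mean curves via the Hungarian algorithm, with surplus
fitted groups reported as spurious splits.  "Correct shape" is matched-curve
RMSE below 25% of the pooled response SD plus agreement of the sign pattern
of the curve's first differences; "correct size" is every matched group
within 5 percentage points of the realized generating share.  σ is floored
at 1e-8; posterior weights at 1e-300 inside logs; log-sum-exp is used for
all mixture reductions.

## Known limitations

* Standard errors come from a finite-difference observed information; for
  near-degenerate fits (duplicated components) the information matrix can
  be singular and pruning then declines to act.
* The LCGM uses a class-specific random intercept only (no random slopes,
  no general covariance), matching the sensitivity analysis it mirrors.
* Model-selection behaviour at k near 10 on heavily overlapping data can
  depend on the number of EM starts; the shipped defaults trade a small
  chance of a missed global optimum for tractable runtime.
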