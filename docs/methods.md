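# Methods

## The task and what the simulator emulates

Each SBORG trial offers a certain reward on an integer grid $1–$6 against
a gamble with two equiprobable outcomes on $0–$6; the response window is a
Poisson(λ = 6 s) draw in whole seconds (the Poisson is discrete, so
fractional limits are not modeled), and a random 33% of trials prompt a
feeling rating. Sessions are a fixed number of trials (208 by default,
the task's average); a trials-per-minute clock model is deliberately out
of scope. Dominated "control" trials — where the sure bet weakly
dominates both gamble outcomes, or vice versa — are injected with a
configurable probability (default 0.2; the true design frequency is not
public). Ties count as dominated, since weak dominance still makes one
option rationally no worse; a trial whose three values all coincide is
classed on the certain side. Option values are drawn uniformly on the
integer grids by rejection within the requested dominance class.
Left/right screen placement has no computational consequence and is not
modeled.

Simulated agents choose by the logistic choice rule and feel by the
happiness model below. Timeouts occur independently per trial
(default 3%, matching the task's observed rarity) and leave no choice,
outcome or rating. The previous-feeling input to the generative choice
rule is the last emitted rating carried forward (0 before the first
rating, on the z-scale).

**Rating scale.** The happiness model is defined on per-participant
z-scored ratings, so the generator emits ratings directly on the z-scale
(latent prediction + Gaussian noise, default sd 0.5 z-units). Fits
therefore take simulated ratings as given; per-session z-scoring
(`standardize=True`) is applied only to raw slider data. An optional
slider mode maps ratings affinely to the −4..+4 integer grid
(2 slider units per z-unit, clipped and rounded) for I/O realism —
re-standardization undoes that map up to discretization. Re-z-scoring
already-z-scale simulations would shift and rescale the generative
weights and is deliberately not done in recovery runs.

What the generator does **not** emulate: reaction times, learning or
drift across trials, sequence constraints on option values, medication
pharmacokinetics, and any rating-slider motor noise beyond the Gaussian
term. Passing recovery tests therefore show that the estimation machinery
is consistent under the model's own assumptions, not that clinical data
satisfy them.

**Generative presets.** Group means for the four condition cells are the
published group-level estimates (happiness weights and forgetting factor
per cell; choice β0–β2 per cell, with β3 = 0 since it was nowhere
significant). Between-subject sds are not published; defaults are 0.05
for the w's, 0.5 for the forgetting factor on its unconstrained scale,
and 0.3 for the β's — plausible scatter, not calibrated values.
Heterogeneity in the forgetting factor acts on the unconstrained (logit)
scale so draws never leave [0, 1].

## The happiness model and its regressors

On the compacted index j = 1..T over a session's non-timeout trials,
each responded trial contributes exactly one nonzero value: CR_j (the
certain value, if chosen), or EV_j (the gamble's expected value, if the
gamble was chosen) together with RPE_j = outcome − EV (so RPE ∈ ±half
the gamble spread, 0 for equal-outcome gambles). The decay sums run over
**all** preceding non-timeout trials, rated or not; timeouts are dropped
from the history entirely. 0^0 is taken as 1, so γ = 0 reduces each sum
to the current trial. `decayed_sum` uses the recursion
S_t = γ·S_{t−1} + x_t, which agrees with the literal power-weighted sum
to ~1e−15 relative error and is O(T) rather than O(T²).

## Hierarchical fit

Per condition cell, for subject s and rated trial t:

    rating_z ~ Normal(Happiness(t; w_s, γ_s), σ_s)

with the non-centered parameterization θ_s = μ + τ ⊙ z_s,
z_s ~ Normal(0, 1), over θ = (w0, w1, w2, w3, η), η the forgetting
factor on the logit scale. Priors: μ ~ Normal(0, 1) per component
(weakly informative on the z-rating scale), τ ~ half-Normal(0.2),
σ_s ~ half-Normal(1). τ and σ are sampled on the log scale with the
Jacobian included. The group-level forgetting factor is reported as the
logistic map of the group-level unconstrained mean.

**Sampler.** The joint posterior (10 + 6·S dimensions for S subjects) is
sampled with an affine-invariant ensemble (80% differential-evolution
moves, 20% snooker moves), vectorized so each log-posterior call
evaluates all walkers at once via the decay recursion. Defaults: walkers
≈ 2× dimension, 4000 steps with the first 2000 discarded, thinned by 5;
the `fast` preset (3000/1500) fits a 12-subject × 208-trial cell in
under a minute on one CPU and is used by the recovery benchmark and the
acceptance script. Walkers start from a per-subject grid-over-γ + OLS
estimate with small jitter. For diagnostics, walkers are grouped into 4
pseudo-chains and split-R̂ / ESS computed with arviz; R̂ > 1.05 flags
(but does not abort) a fit. Divergence counts are not defined for
ensemble moves and are reported as absent. Because walkers of one
ensemble interact, pseudo-chain R̂ is an approximation — it detects
non-mixing but not a shared bias of the whole ensemble; the recovery
benchmark is the guard against the latter. Fixed seeds reproduce draws
exactly.

Sessions with constant ratings (z-scoring undefined) or fewer than 5
rated trials are excluded with a logged warning; a cell needs at least
2 usable subjects.

## Choice model

Only responded trials whose previous trial carries a rating enter the
default (`rated_only`) design matrix — the previous feeling is then
directly observed; `locf` instead carries the last rating forward to all
responded trials after the first rating (which imputation the original
analysis used is ambiguous, so both are provided). Trial 1 is never
included. Fits are per-participant maximum likelihood (statsmodels
Newton/IRLS, log-likelihood tolerance 1e−8). Any |β| > 20, or a failed /
perfectly separated fit, raises a separation flag; flagged subjects are
dropped from group summaries when at least two clean fits remain
(transparency preferred over silent ridge shrinkage). Group summaries
are the mean of per-subject coefficients with t-based 95% CIs and a
one-sample t-test against 0. Predictors enter in raw dollars, the
previous rating in z-units — consistent with the published coefficient
magnitudes.

## Posterior comparisons

The HDI is the narrowest window of ⌈mass·n⌉ sorted draws — for
multimodal samples this still returns one interval (documented
limitation). Difference distributions pair draws index-wise; the cells
are fitted independently, so any pairing is valid and index pairing is
reproducible; unequal draw counts are thinned evenly to match. The
posterior Cohen's d is (mean_A − mean_B) / √((sd_A² + sd_B²)/2); this
pooled form reproduces the published off-medication effect sizes
(4.6206, −4.7254) from the printed means and HDI widths to within ~1%,
which pins down the convention. Credible fractions split exact zeros
evenly; a difference is called credible beyond 97.5% posterior mass on
one side. No multiplicity adjustment is applied across the five
parameters (matching the original analysis).

Within-group on-vs-off contrasts of gamble rates are paired by subject
and use the signed-rank test (the data are paired even though the
original methods name only the rank-sum test); between-group contrasts
use the rank-sum test, exact at small n. All-zero paired differences
return p = 1. Cell-level r² pools all rated trials across the cell's
subjects (the original aggregation is unstated; pooling is declared, not
inferred).

## Problem sizes and numerical choices

The recovery benchmark and acceptance script use the study's own design
sizes (18 + 12 subjects, two visits, 208 trials, 33% rated) with the
`fast` sampler preset; the unit-test suite uses smaller cohorts
(2–6 subjects, 40–300 trials) with proportionally shorter chains.
Separation-prone per-subject logistic fits at ~60 rated-preceded rows
per session carry the usual small-sample away-from-zero bias of logistic
MLE (visible as group means a few tenths above the generative β's);
group-level recovery stays within the quoted standard-error bounds.
Rating-noise draws are floored at 1e−3; walker proposals outside
|parameter| < 50 are rejected outright to keep exponentials finite.

## Known limitations

- The ensemble sampler is not gradient-based; very small cells (2–3
  subjects) mix slowly and need longer chains than the defaults.
- Individual-level sds of the published fits are unknown; preset
  heterogeneity is an assumption, so simulated between-group effect
  sizes (which scale inversely with posterior spread) need not match
  published ones even when group means do.
- The HDI is single-interval; the credible-fraction and difference-HDI
  criteria can disagree within ~±0.5% of the 97.5% boundary.
- The session-file dialect is fixed (CSV, header, UTF-8) with a
  user-supplied column map for foreign exports; no dialect
  auto-detection.
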