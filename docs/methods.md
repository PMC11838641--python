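# Methods

## Scope

`hdproxy` implements a high-dimensional proxy confounding-adjustment
pipeline for new-user treatment comparisons in claims/EHR data, together
with a synthetic cohort generator that provides ground truth for
validating every stage. The pipeline estimates a treatment hazard ratio
over a fixed 183-day intent-to-treat window by (i) generating large
numbers of binary candidate features from structured codes and free-text
notes, (ii) screening them, (iii) fitting cross-fitted LASSO propensity
scores for eight nested covariate sets, (iv) weighting by one of three
PS schemes, and (v) fitting a weighted Cox model with a robust variance,
alongside standardized-difference balance diagnostics.

## Synthetic cohort model

Per patient, a latent comorbidity vector `U ~ N(0, I_k)` drives
everything:

* treatment: `P(A=1) = expit(alpha0 + alpha·U)` (confounding by
  indication when `alpha` and `gamma` share sign), plus optionally an
  extra latent factor that affects treatment only and loads a set of
  planted instrumental-variable codes;
* codes: each claims/EHR code is Bernoulli with
  `logit = s_j * (U[latent_j] - t_j)` — parameterized by an activation
  threshold `t_j ~ U(-1.8, 1.8)` and a steepness with random **sign**
  (risk vs protective proxies). Both choices matter for what a linear
  propensity model can recover: positive-only loadings put all proxy
  thresholds in one tail of `U`, and drawing baseline log-odds (rather
  than thresholds) collapses the thresholds toward zero as steepness
  grows. Marginal prevalences spread over roughly [0.04, 0.96];
* notes: a configurable number of documents per patient (Poisson), each
  a token sequence. Content tokens are drawn from a per-patient
  multinomial `softmax(base + L·U)` over a vocabulary whose tokens each
  load (with random sign) on one latent component; a fixed fraction of
  tokens comes from a stop-word stratum independent of `U`, so stop-word
  removal is testable as genuine noise reduction. All note day offsets
  are strictly pre-index (in [-365, -1]);
* note-only confounders: a configurable fraction of `U` components have
  their code loadings zeroed — their signal reaches the analyst only
  through notes. This is the mechanism behind the "added value of NLP
  features" experiments;
* outcome: exponential survival with hazard
  `h = baseline_hazard * exp(beta_true*A + gamma·U)`, administratively
  censored at 183 days. With a constant baseline hazard the weighted Cox
  estimand equals `beta_true` exactly under correct adjustment, so
  parameter recovery is a clean test.

Everything is deterministic given the config seed; generator parameters
(code loadings, token assignments) are themselves drawn from a
seed-derived stream so a config+seed pair pins the full data law.

## Feature engineering

All NLP output becomes per-patient **presence indicators** (never
counts): simple functional form for the penalized PS model, and the
representation the downstream pipeline assumes.

* n-grams: tokens are lowercased alphanumeric runs; stop words (a
  packaged ~150-word function-word list, user-overridable) are removed
  first and bigrams pair the *filtered* sequence, never across document
  boundaries.
* lexicon concepts: greedy longest-match left-to-right over token
  sequences with nested-match suppression; concept presence per patient.
  Negation and modifiers are out of scope.
* embedding clusters: any provider with `dim` and
  `embed(tokens, position)` plugs in. The built-in providers map tokens
  to fixed pseudo-random unit vectors keyed by a hash of (token, seed);
  the contextual variant perturbs the token vector by a hash of its two
  flanking tokens, and sentence embeddings of a non-contextual provider
  are token-vector means. Units (distinct tokens, context triples, or
  documents — deduplicated within patient so the word-cluster features
  depend only on each patient's token set) are pooled across patients
  and clustered with mini-batch k-means (k-means++ init, batch 1024, 100
  iterations, fixed seed, `n_init=3`); patient feature `c` = 1 iff any
  unit falls in cluster `c`. `k` defaults to 500 per scheme
  (configurable; the experiment grid uses k = 100 at its cohort sizes).

## Screening

Binary code/NLP features with prevalence **strictly** below 0.01 are
dropped (researcher-specified and continuous columns are exempt).
Features are then ranked by marginal treatment correlation — the phi
coefficient for binaries, point-biserial for continuous — and the
top-ranked list is surfaced for instrument review; exclusion happens via
a denylist (in simulations, derivable from the generator's truth).
Constant features get correlation 0 and a flag. Prevalence is
per-cohort, not per-arm.

## Propensity estimation

L1-penalized logistic regression, 10-fold cross-fitting stratified by
treatment. The penalty is chosen per training split by inner 5-fold CV
minimizing binomial deviance over a fixed grid `C ∈ logspace(-2, 0,
5)` (weaker penalties were never selected in any scenario probed and
measurably degraded both bias and balance through overfit out-of-fold
scores); the inner splits are groups of outer folds, which makes the
whole procedure invariant to patient ordering given the fold
assignment.
Out-of-fold probabilities are clipped to `[1e-6, 1 - 1e-6]`. Continuous
covariates are scaled to unit training-split variance (no centering, to
preserve sparsity); binary features enter as 0/1 and all covariates are
penalized alike. The reported selected-predictor count comes from a
full-data refit at the median per-fold penalty; the refit is never used
for inference. AUC is the Mann–Whitney form with ties counted 1/2; NLL
is the mean negative Bernoulli log-likelihood (natural log) of the
pooled out-of-fold predictions.

## Weighting, balance, effect estimation

The three weight formulas (IPTW, overlap, matching) are evaluated
exactly; degenerate `ps ∈ {0, 1}` is an error (clipping happens
upstream). Standardized differences use the pooled two-group form
`|m1 − m0| / sqrt((v1 + v0)/2)` with weighted prevalences/means and, for
binaries, `v = p(1−p)`; the unweighted value is the `w ≡ 1` special
case, and zero pooled variance yields 0 (equal means) or +inf (flagged).
The 0.1 threshold is a reporting flag, never a filter. Balance is
reported for every feature with a candidate flag, so non-candidate
balance (features a model could not see) is always available.

The weighted Cox fit is a single-covariate partial likelihood with
per-patient weights and Breslow tie handling, maximized by Newton
iterations (gradient tolerance 1e-9, step-halving safeguard, a step-size
floor of 1e-13 because at very large n the absolute score tolerance
falls below floating-point resolution of the score sum). The variance is
the Lin–Wei robust sandwich treating weights as fixed; 95% CIs use the
normal quantile 1.96. No events in one arm is reported as
non-identifiable (monotone likelihood). The unadjusted estimate runs
through the same code path with unit weights.

## Pipeline

One master seed fans out into per-stage seeds (cohort, folds, embedding,
clustering) via a hashed counter, so stages can be re-run in isolation
and a run is reproducible from (config, seed). Failures are recorded per
grid cell without aborting the rest. Reports carry a config hash and
package version. The CLI (`hdproxy simulate|features|screen|ps|effects|
run|replicate`) is a thin layer over these functions.

## Simulation studies and their scenarios

The stock `confounded_scenario` plants upward confounding with a null
treatment effect: two latent factors (one note-only), `alpha0 = -0.2`,
`alpha = 0.50`, `gamma = 0.41`, 70 threshold-spread claims codes at
loading scale 5, a 250-token vocabulary emitted over ~160 tokens/patient
(8 notes × 22 tokens, 10% stop words) at topic scale 4. At these
settings the mean unadjusted log hazard ratio over 100 replicates of
n = 2,000 is ≈ 0.37 with ~45% treated and a ~12% event rate. The
event rate is deliberately higher than typical claims outcomes (a few
per mille to a few percent) so that hazard-ratio estimates are precise
enough at n = 2,000 for replicate studies; it affects precision, not
bias. Replicate studies use unigram (bag-of-words) note features for the
claims+NLP model: at this scale bigrams contribute hundreds of
sub-percent-prevalence columns that only add penalization overhead,
while the experiment grid keeps the unigram+bigram default.

Monte-Carlo **bias** is defined as `|mean(log-HR) − beta_true|` over
replicates — the standard simulation bias. Per-replicate absolute
deviations are dominated by the Cox estimator's sampling noise (SE
≈ 0.1 at these event counts) and would conflate variance with bias.

Scenario design lessons that shaped the generator defaults: what governs
achievable bias removal is the *out-of-fold* R² of the latent
confounders given the features, not the (optimistic) in-sample R²;
mixed-sign loadings and mid-range feature prevalences are necessary for
a linear PS model to reconstruct both tails of `U`; and penalty
selection by prediction loss leaves some shrinkage-induced
under-correction, so proxies need to be strong and only moderately
numerous relative to n.

### What passing tests do and do not show

The generator emulates proxy structure, note-only confounders,
instrumental variables and a stop-word stratum, but not real clinical
language, code semantics, informative censoring, EHR discontinuity, or
treatment-effect heterogeneity. Recovery results on synthetic cohorts
show the pipeline is correct and effective *under its assumed data law*;
they do not certify confounding control in any particular real cohort.

### A known scale limitation of the all-balanced criterion

At n = 2,000 with ~300 candidate features, the sampling SE of a weighted
standardized difference is ≥ ~0.045 per feature *even under perfect
balance* (oracle true-PS weights give a mean max-SD of ~0.15 and a
zero-violation rate near 0.1; even unweighted randomized cohorts fail).
The probability that *every* feature shows |SD| < 0.1 therefore plateaus
around 0.3–0.7 regardless of adjustment quality; the "< 0.1 for all
variables" pattern is a large-sample phenomenon (at n ≈ 26,000 the SD
noise is 3.6× smaller and the pattern holds easily). The corresponding
acceptance test asserts the pattern at n = 2,000 anyway and is expected
to fail for this statistical reason; the balance machinery itself is
validated by the exact overlap-balance oracle and the candidate vs
non-candidate contrast.

## Numerical choices

* PS clip bound 1e-6 (prevents infinite weights/NLL).
* Penalty grid `logspace(-2, 0, 5)`; inner-CV selection fits run at
  liblinear tolerance 5e-3 with a 15-iteration cap (they only rank
  penalties), prediction refits at 1e-4.
* Dense design conversion when sparse density > 0.15 (liblinear is
  faster on dense arrays for prevalent binary features).
* k-means ties in assignment resolve to the lowest cluster index
  (argmin behavior).
* Cox Newton: tolerance 1e-9, max 100 iterations, step-halving; Breslow
  risk sets shared across tied times.
* Seeds derived via BLAKE2 hashes of (master, stage), kept below 2^31.

## Problem sizes

Default test and acceptance runs use n = 2,000 cohorts, 100 replicates
for the confounding-recovery study (40 in the acceptance script), 200
replicates for CI coverage, 20 for cross-fit null calibration, and a
single full 8 × 3 grid — sizes chosen as the package's own desk-scale
study design.
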