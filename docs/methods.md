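# Methods

## The problem

Large surveys routinely carry several validated multi-item instruments
(Likert scales) whose analysis variable is the summed score. Item
nonresponse makes scale totals missing at a much higher rate than any
single item, so imputing at the level of totals discards partially
answered scales, while imputing every item with every other item as a
predictor produces conditional models with a hundred or more covariates
that can fail to converge on a few hundred respondents.

`scalemice` implements a middle path inside chained-equations multiple
imputation (MICE / fully conditional specification): each item is still
imputed at item level, but in its prediction equation every *other*
scale is represented only by its summed total, while the item's own
scale contributes its sibling items. For outcome `p`, demographics
`d1..dn`, a 7-item scale S and a 17-item scale T:

    d1 | p, d2..dn, s, t
    s1 | p, d1..dn, s2..s7, t
    t1 | p, d1..dn, s, t2..t17

where `s`, `t` are summed scores, recomputed passively after each draw
that changes their items. The implicit assumption is that items of
different scales are conditionally associated only through the other
scale's total — reasonable when instruments are internally consistent
and administered as coherent blocks. Three predictor schemes are
exposed: `full` (every raw variable), `totals_only` (every scale
collapsed to its total; the target's own scale dropped, since its total
contains the target), and `proposed` (the scheme above).

Predictor counts are counts of *questions*, not design-matrix columns: a
nominal variable counts once no matter how many dummies it expands to.
This is the convention under which a survey of 135 analysis variables
has full-scheme models with 134 predictors each.

## Conditional models and proper draws

Per measurement type: continuous — Bayesian normal linear regression
(variance from its scaled inverse-chi-square posterior, coefficients from
their conditional normal, imputation = linear predictor + Gaussian
noise); binary — logistic; ordinal — proportional odds; nominal —
baseline-category logit. For all categorical families the coefficient
vector is drawn from the asymptotic normal of the fit before category
probabilities are formed, so parameter uncertainty propagates into the
imputations (required for Rubin's-rules variance validity). Imputed
categories always lie in the observed category set.

Sparse categorical fits are a recognised failure mode (separation,
empty cells). The fallback chain is: plain maximum likelihood; then a
ridge-penalised refit (fixed prior precision `ridge`, default 0.1, via
BFGS on the model's own likelihood, covariance from the penalised
observed information); then automatic category collapsing (smallest
share merged into its adjacent category for ordinal, next-rarest for
nominal, floor at two categories, default minimum share 5 % — the value
that merges a 0.3 %/33.7 %/65.3 % education distribution into two
levels while leaving balanced variables untouched); only then an error
naming the target. Predictors constant on the fit rows (e.g. a gate
always satisfied where the response is observed) are dropped from the
design; an ordinal target left with no informative predictors falls
back to draws from its observed marginal.

The sweep visits variables in ascending missingness (structural cells
in neither numerator nor denominator; ties by schema order), except
that a gated variable always follows its gate. Totals are recomputed
before any draw that could read a stale total and at the end of every
sweep. One master seed spawns independent substreams per imputation, so
results are reproducible and independent of execution order.

### Conditional (gated) questions

A question asked only given a particular answer to an earlier gate
(e.g. income amount given willingness to disclose) is imputed only on
rows whose *current* gate value satisfies the gate; other rows hold a
structural-missing sentinel, a state distinct from nonresponse that is
excluded from missingness rates, model fits and imputation. Opt-out
ordinal questions are split losslessly into a binary willingness
variable plus a gated ordinal response (`split_optout_variable`), which
preserves their ordinal scale instead of demoting them to nominal.
Gated predictors enter other models with structural holes set to zero,
i.e. as response-times-willingness terms. Whether gates should predict
unrelated targets is not settled practice; they are included like any
binary item.

## Pooling

Rubin's rules: pooled estimate = mean of per-imputation estimates;
total variance T = W + (1 + 1/M)B with W the mean within-imputation
variance and B the between-imputation sample variance; reference
distribution t with df = (M−1)(1 + W/((1+1/M)B))², infinite when B = 0
(pooled inference then equals single-dataset inference). The classic
df is used rather than the Barnard–Rubin small-sample correction, which
is left as an option; Wald (not likelihood-ratio) tests throughout.
The univariate screen fits one logistic regression per candidate per
completed dataset and pools; the 2×2 selection-agreement summary uses
the Pearson chi-square without continuity correction (the convention
that reproduces the published statistic for such tables) and percent
agreement = main-diagonal share.

## The simulation laboratory

`simulation` emulates a realistic survey setting: n = 323 respondents,
26 variables — binary adherence outcome, age, a 7-item attitude scale
and a 17-item practitioner-satisfaction scale. Complete data are drawn
from a multivariate normal over (outcome latent, age, 24 items) and
then discretised: outcome to the nearer of 0/1, items rounded and
clipped to 1..5.

The source survey's observed moment vectors are unpublished, so the
population defaults are declared here once and are overridable:

| parameter | default | meaning |
|---|---|---|
| item mean / SD | 3.6 / 1.0 | typical agreeable Likert item |
| age mean / SD | 60 / 11 years | hypertensive adult population |
| outcome latent mean / SD | 0.55 / 0.5 | ≈54 % adherent after rounding |
| r_w | 0.5 | within-scale item correlation (internal consistency) |
| r_b | 0.2 | between-scale item correlation |
| r_a | 0.1 | item–age correlation |
| r_o | 0.15 | item–outcome-latent correlation |
| r_ao | 0.1 | age–outcome-latent correlation |

The block matrix is eigenvalue-clipped and diagonal-renormalised if the
chosen blocks are not positive definite (the defaults are).

Missingness is missing-at-random: per respondent and per scale
(independently — the instruments were administered as separate blocks),
one of three categories is drawn from a baseline-category logit on the
outcome and standardised age: all items observed / one-or-two missing
(deleted uniformly) / all missing. Scenario targets are hit exactly in
expectation by root-finding the two intercepts against the empirical
covariate distribution of the dataset at hand:

* base — 35 % all-missing, 8 % partial;
* more_partial — 18 % all-missing, 25 % partial;
* fewer_complete — 55 % all-missing, 15 % partial.

The MAR slope magnitudes in the source setting are unrecoverable; the
defaults (partial: 0.3 on outcome, 0.2 on z-age; all-missing: 0.6, 0.4)
were fixed once at design time, large enough that complete-case
selection is materially non-random (at these defaults the
satisfaction-scale mean of complete cases sits ≈0.8 points below the
population mean, about −1.4 %) while keeping calibration feasible for
every scenario. Slopes are shared across scales and overridable per
scenario.

Six strategies are compared: (1) complete case; (2) proration — the
observed-item sum scaled by scale size over items observed, respondents
with a wholly missing scale dropped; (3) totals set missing whenever
any item is missing, then multiply imputed from a joint normal given
outcome and age; (4) proration for partial scales, joint-normal MI only
for wholly missing scales; (5) item-level chained equations with the
scale-summary scheme and linear-regression draws (items left unrounded
for analysis; rounding back to 1..5 is an option, default off);
(6) all items multiply imputed jointly from a multivariate normal given
outcome and age — the benchmark. The joint-normal model of methods
3/4/6 is sampled by iterated conditional Gaussian draws (Gibbs over the
modelled variables), which is equivalent to sampling the joint normal
but needs no explicit covariance draw; see the burn-in note below.

Four estimands per replication: the two scale-total means and the two
slopes in a logistic regression of the outcome on age and the totals.
Metrics follow standard simulation-study practice: percent bias
100·mean(est − ref)/|mean(ref)| with ref the same replication's
pre-deletion (full-data) analysis — the full-data estimate rather than
the latent truth, because rounding makes the finite-sample estimand
differ slightly from the latent parameters; normalising by the true
latent value is available as an option. Coverage is of nominal 95 %
intervals against the mean full-data estimate; efficiency is the
empirical SE (SD of estimates over replications) as a ratio to
method 1. Monte-Carlo 95 % intervals: normal approximation for bias,
Clopper–Pearson for coverage, a lognormal delta approximation for the
SE ratio that treats the two SDs as independent (slightly conservative,
since methods share replications).

## What the generator does and does not emulate

It reproduces the dimensional structure (323×26), the discreteness of
Likert items, a plausible correlation geometry, and outcome/age-driven
MAR of the published magnitudes. It does not reproduce the real
survey's moments (unpublished), cross-country heterogeneity, nominal or
conditional variables inside the simulated scales, MNAR mechanisms, or
within-respondent correlation of missingness across scales. Passing
simulation checks therefore demonstrates the estimators' behaviour
under a controlled MAR mechanism with rounded-Gaussian items — not
performance on any particular real survey.

### Burn-in of the conditional-Gaussian sampler

Coordinate-wise Gibbs over a block of many correlated variables mixes
slowly when the whole block is missing for a substantial share of rows:
information then enters only through the covariates, and a chain
started from the observed marginal (which is selectively low under
outcome-driven missingness) approaches its stationary mean from below.
Measured against the exact closed-form conditional mean in a correctly
specified Gaussian setting (n = 40 000, a 17-variable block wholly
missing for 35 % of rows), ten sweeps still leave the block's imputed
sum ≈0.27 points (≈0.4 % of its mean) short — enough to masquerade as
estimator bias in a simulation study. The sampler therefore (i)
initialises missing cells from regression draws on the covariates, not
the marginal, and (ii) defaults to 20 burn-in sweeps, the point at
which the measured gap is within draw noise. `sweeps` is exposed for
harder geometries.

## Numerical choices and degenerate inputs

* Linear algebra: normal equations with a Cholesky factor and a tiny
  trace-scaled jitter (1e-10) against collinearity; posterior draws via
  the factor, zero-variance posterior when the fit is exact.
* Category probability draws by inverse CDF on the drawn coefficient
  vector; probabilities clipped at zero and renormalised.
* The ordered model is fit with BFGS on a vectorised logistic
  distribution (the generic scipy distribution dispatch dominates fit
  time otherwise).
* Zero-missingness inputs: every routine returns exact copies.
* A variable with no observed values is a fatal, named error.
* Degenerate categorical targets (one observed level) impute that level.
* `collapse_categories` is idempotent and refuses to go below two
  levels (warning, identity recode).
* Default M = 25 and 10 cycles for case-study-style imputation,
  overridable; the simulation uses M = 10 throughout, matching its
  setting.

## Problem sizes used by the test and acceptance runs

Unit tests run the engine at n = 60–800 with M = 2–4 and 2–3 cycles;
distributional oracles use n = 5 000–10 000 or 200 seed repetitions;
scenario calibration is audited at n = 100 000. The packaged
strategy-comparison study runs the base case at R = 200 replications
with methods 1, 2 and 6 and M = 10 (the acceptance script uses R = 100
by default, `--reps` to change); the full six-method, three-scenario,
R = 1000 design remains available through `scalemice simulate`.

## Known limitations

* No predictive mean matching, random-forest, or other nonparametric
  engines; no MNAR delta adjustment.
* Weighted scale totals are not implemented (totals are plain sums).
* The Barnard–Rubin df correction is not applied.
* The ridge fallback uses a fixed, data-independent precision.
* Ordinal fits on very wide designs remain the computational
  bottleneck of fully categorical runs.
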