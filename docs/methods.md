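# Methods

## Instruments and coding

The DLQI has ten items on a four-level ordinal scale (3 = "Very much" …
0 = "Not at all"); the total is the sum, 0–30, higher = worse. Item 7 is a
two-part question (work/study prevented yes/no; if not prevented, how much of
a problem) combined into one 0–3 score: "prevented" scores 3, otherwise the
second part scores 2/1/0, and an unanswered part scores 0. Any unanswered
item is scored zero, per the instrument developers' rule; the package keeps a
per-item missing mask so zero-filled items remain distinguishable from true
zeros. The text-to-number mapping lives only in the I/O layer — the core
consumes numeric scores.

EQ-5D-3L domain responses are coded 1 (no problems), 2 (some problems),
3 (extreme problems); a state is one of 3⁵ = 243 level patterns, indexed in
base-3 with mobility most significant. Sex is coded 0 = male / 1 = female;
age is years, entering models linearly with no upper clamp.

Complete-case rule: subjects missing age, sex, any EQ-5D domain, or the
*entire* DLQI questionnaire are excluded before fitting; partially missing
DLQI items within a returned questionnaire are zero-filled, never an
exclusion reason. The boundary case of a fully unanswered questionnaire is
exposed explicitly by the filter (reason-coded removal counts) since the
line between "some missing items" and "no questionnaire" is a convention.

## The ordinal mapping model

Per domain, a proportional-odds (cumulative-logit) model with latent score
`Z = b_age·age + b_sex·sex + Σ bᵢ·itemᵢ` and thresholds `a₁ < a₂`:
`P(Y=1) = σ(a₁−Z)`, `P(Y≤2) = σ(a₂−Z)`, `P(Y=3) = 1 − P(Y≤2)`, where σ is
the logistic function. The sign convention (higher Z → worse categories) is
fixed once and shared by fitting, prediction and simulation. DLQI items
enter as numeric 0–3 scores with a single slope each — the bundled published
coefficient table has exactly one weight per item, which is only
reconstructable under this reading (an indicator-coded alternative would
need three parameters per item); the choice is recorded here rather than
silently assumed.

Probabilities are evaluated through the stable sigmoid (`scipy.special.expit`
/ `log_expit`), so |Z−a| up to ~700 cannot overflow, and are arranged so the
three probabilities sum to 1 within floating rounding.

The bundled model carries every published estimate and standard error for
the five domains (n = 3542). It is immutable; refitting produces new model
objects serialized to a versioned JSON schema that rejects `a₁ ≥ a₂` and
missing domains at load time.

## Maximum-likelihood fitting

Parameterization `(a₁, log(a₂−a₁), b)` keeps the threshold ordering
unconstrained-optimizable. The optimizer is quasi-Newton (L-BFGS-B,
analytic gradients, columns internally scaled to unit variance) started at
the empirical cumulative logits with zero slopes, then polished with Newton
steps using a finite-difference Hessian of the analytic gradient until the
gradient max-norm reaches 1e−8 (flagged unconverged past 1e−6 — the
practical signature of separation). Fits are deterministic: no random
initialization, no data-order dependence. Standard errors are square roots
of the diagonal of the inverse observed information at the optimum.

Degenerate outcomes: a domain with all subjects in one category raises an
error. An empty extreme category makes the corresponding threshold
non-estimable; the fit falls back to the two-category cumulative model, the
threshold is reported infinite (so the model simply never predicts the
unobserved category) and a warning is attached. An empty *middle* category
collapses both thresholds onto one cut point (reported with a 1e−6 gap to
preserve the ordering invariant) — a convention, documented here because no
standard treatment exists.

Model comparison uses the likelihood-ratio recipe: χ² = twice the absolute
difference in maximized log-likelihoods, df = difference in free slope
terms (age+sex vs full: 10; DLQI-only vs full: 2), upper-tail chi-square
p-values, two-sided throughout, no multiple-testing adjustment. The test
for parallelism compares the proportional-odds fit against a generalized
cumulative model with a separate slope vector per threshold (df = number of
slopes, 12 for the full covariate set). The generalized model does not
enforce non-crossing of the cumulative curves inside the covariate hull; a
post-fit check warns if they cross, and results carry an explicit
reliability warning when fewer than 30 subjects (configurable) occupy the
top category, where the {1,2}-vs-{3} sub-model is unstable.

The item-domain association screen uses Spearman rank correlation — chosen
as the least-assumption-laden measure for ordinal-ordinal pairs — with
two-sided p-values; constant columns yield NaN rather than an error.

## Utilities and Monte Carlo simulation

The bundled value set is the Dolan (1997) UK MVH time-trade-off tariff:
full health 1.0; constant decrement 0.081 if any domain exceeds level 1;
per-domain level-2/level-3 decrements (mobility 0.069/0.314, self-care
0.104/0.214, usual activities 0.036/0.094, pain/discomfort 0.123/0.386,
anxiety/depression 0.071/0.236); N3 decrement 0.269 applied once if any
domain is at level 3. Its worst state (33333) values at −0.594. The tariff
variant is recorded in the value-set metadata; other additive tariffs load
from JSON. All utilities flow through one vectorized function, so per-state
calls and the 243-entry table agree bit for bit. Utilities are kept at full
precision; rounding (4 dp) happens only in display columns.

Monte Carlo prediction draws the five domains independently given
covariates (matching the separate per-domain models — no residual
cross-domain correlation is induced), via inverse-CDF draws; default
5 repetitions per subject, configurable upward. Per-subject utilities are
computed state → utility → mean (not probability-averaged); the analytic
expectation — the exact 243-state sum — is computed alongside as the
oracle the Monte Carlo mean converges to. Randomness uses one cohort-level
seed combined with a per-subject key (SHA-256 of the subject id) into
per-subject `numpy` substreams, so results are bit-reproducible and
independent of row order.

The linear comparator is ordinary least squares of observed utility on the
DLQI total, reported as `Utility = a − b·total`. Predictions are bounded
above by `a` (and not clamped below): unlike the ordinal route, it cannot
produce a utility of exactly 1.

## Cross-validation protocol

`make_split_plan` draws uniform random halvings (odd cohorts give the extra
subject to set A); each split contributes two exercises with the halves
swapped, so 5 splits = 10 fitted-and-tested models. Exercise-level seeds
derive from the master seed by a documented counter scheme, so any exercise
can be rerun in isolation. Metrics per exercise: mean difference
(mean predicted − mean observed), MSE, MAE, percent of subjects within
0.1/0.2/0.3 (non-strict ≤, with a 1e−12 floating guard; recorded in report
metadata), and a histogram of per-subject differences on fixed width-0.1
bins over [−1.6, 1.6] (left-closed/right-open), which covers the full
attainable difference range under the bundled tariff. Aggregates are
unweighted means over successful exercises (test halves are near-equal
size); histogram counts are summed. A failed fit marks only its exercise.
Subgroup transfer fits on one disjoint subset and evaluates on another,
propagating degenerate-category warnings from the training fit.

## Synthetic cohort generator

Defaults emulate a European dermatology outpatient population:

| parameter | default | rationale |
|---|---|---|
| n | 4010 | study-sized cohort before exclusions |
| age | truncated normal on [18, 95], mean 46.3, sd 16 | reported mean/range; sd unreported, configurable. The location parameter is solved numerically so the *truncated* mean hits the target |
| sex | 56 % female | reported split |
| DLQI items | marginals (0.60, 0.20, 0.13, 0.07) per item | right-skewed, most mass at 0–1; mean 0.67 per item ⇒ expected total 6.7, matching the reported mean total. Only the mean total is reported, so identical marginals across items are assumed; per-item overrides allowed |
| item correlation | single-factor Gaussian copula, ρ = 0.5 | items are positively correlated in real data but no value is reported; configurable |
| EQ-5D responses | categorical draws from the generating model's probabilities (default: the bundled model) | exactly the latent-logistic mechanism the mapping assumes |
| missingness | MCAR, rate 0.117, one uniformly chosen field (age / sex / one EQ-5D domain / whole DLQI) per affected subject | only a total exclusion percentage is reported |

Under these defaults the generated EQ-5D margins land close to published
frequencies (e.g. ≈0.2 % mobility-extreme responses, matching the 11/3542
sparsity that makes that domain's parallelism test unreliable). What the
generator does **not** emulate: country/diagnosis mixture, any real
item-level joint distribution beyond the configured marginals and single
common factor, within-subject inconsistencies between instruments, and
MAR/MNAR missingness. Tests passing on these cohorts therefore demonstrate
correctness of the machinery and self-consistency of the method — not
real-data predictive accuracy, which is only measurable with observed
DLQI/EQ-5D pairs.

## Numerical choices and known limitations

* Probability sums are exact to 1e−12; the fitter's gradient tolerance is
  1e−8 after Newton polish; closed-form cases (intercept-only thresholds =
  empirical cumulative logits) reproduce to 1e−6 or better.
* The generalized (non-parallel) model floors category-2 probabilities at
  1e−12 during optimization; started from the parallel fit this region is
  not visited at well-posed optima.
* Likelihood-ratio tests (including the parallelism test) rely on the
  asymptotic chi-square reference. At small samples with many slope
  parameters (e.g. n ≈ 500 with 10–12 df) they over-reject modestly — a
  few percent above nominal — which is inherent to the plain LR
  construction; no Bartlett-type correction is applied because the method
  deliberately mirrors the standard test. Calibration is near-nominal at
  the sample sizes the mapping is intended for (thousands).
* Parameter-recovery accuracy is governed by the information in the data:
  at n = 20,000 the slope sampling SEs are ~0.02–0.07, so individual
  estimates scatter accordingly around the truth; recovery is verified in
  SE units (and bias vanishes as n grows).
* Coefficient standard errors are stored but not propagated into utility
  predictions (no probabilistic sensitivity analysis).
* Cross-validation problem sizes used by the test-suite and the
  reproduction script (cohorts of 1,000–20,000; 500-replicate null
  calibrations at n = 500) are the package's chosen desk-scale defaults;
  all are configurable.
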