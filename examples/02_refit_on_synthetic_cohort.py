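"""Refit the per-domain ordinal models on a synthetic cohort and inspect recovery.

Simulates 5000 subjects from the bundled generating model, refits the
pain/discomfort proportional-odds model by maximum likelihood, and prints the
recovered coefficients beside the truth with Wald standard errors, plus the
likelihood-ratio tests of the nested covariate sets and the test for
parallelism (proportional-odds assumption).
"""

import warnings

from dlqimap import bundled_model, fit_proportional_odds, lr_test
from dlqimap.fitting import test_parallelism
from dlqimap.synthetic import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(n=5000, missing_rate=0.0, seed=123))
truth = bundled_model()["pain_discomfort"]

full = fit_proportional_odds(cohort, "pain_discomfort")
print(f"pain/discomfort fit: n={full.n_used}, -2LL={full.neg2_loglik:.1f}, "
      f"converged={full.converged}")
print(f"{'param':>8}  {'truth':>7}  {'estimate':>8}  {'SE':>6}")
true_vals = [truth.a1, truth.a2, truth.b_age, truth.b_sex, *truth.b_items]
for name, t, est, se in zip(full.param_names, true_vals, full.params, full.se):
    print(f"{name:>8}  {t:>7.3f}  {est:>8.3f}  {se:>6.3f}")

for reduced_set in ("age_sex", "dlqi"):
    reduced = fit_proportional_odds(cohort, "pain_discomfort", reduced_set)
    t = lr_test(reduced, full)
    print(f"\nLR test vs {reduced_set}: chi2={t.chi_square:.1f}, df={t.df}, p={t.p_value:.2e}")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    par = test_parallelism(cohort, "pain_discomfort", po_fit=full)
print(f"test for parallelism: chi2={par.chi_square:.1f}, df={par.df}, p={par.p_value:.3f}")
print(
    "\nEstimates should sit within ~2 SE of the truth; the DLQI block is"
    "\noverwhelmingly significant, and the parallelism test should be"
    "\nnon-significant since the data truly follow a proportional-odds model."
)
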