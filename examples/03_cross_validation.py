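"""Split-half cross-validation of the ordinal mapping vs the linear comparator.

Simulates a study-sized cohort (n = 4010 with ~11.7% incomplete records),
filters to complete cases, and runs the full validation protocol for both
methods: 5 random halvings, halves swapped, 10 modelling exercises each.
"""

from dlqimap.synthetic import CohortConfig, filter_complete_cases, generate_cohort, inject_missingness
from dlqimap.validation import cross_validate

cfg = CohortConfig(n=4010, missing_rate=0.117, seed=2024)
cohort = inject_missingness(generate_cohort(cfg), cfg.missing_rate, seed=2024)
result = filter_complete_cases(cohort)
print(f"{cfg.n} subjects generated; {result.n_removed} excluded "
      f"({result.removed}); {len(result.cohort)} complete cases\n")

for method in ("olr", "linear"):
    report = cross_validate(result.cohort, method=method, n_splits=5, reps=5, seed=7)
    a = report.aggregate
    print(f"{method:>6}: mean diff {a.mean_difference:+.4f}   MSE {a.mse:.4f}   "
          f"MAE {a.mae:.4f}   within 0.1/0.2/0.3: "
          f"{a.pct_within[0.1]:.0f}%/{a.pct_within[0.2]:.0f}%/{a.pct_within[0.3]:.0f}%")

print(
    "\nEach line aggregates ten fit-and-predict exercises. The mean difference"
    "\n(predicted minus observed cohort mean utility) should be near zero for"
    "\nboth methods on this correctly specified synthetic cohort; MSE/MAE show"
    "\nthe per-subject spread of prediction errors."
)
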