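"""Map a small cohort's DLQI responses to EQ-5D utilities with the bundled model.

Builds a three-subject cohort by hand, computes each subject's EQ-5D response
probabilities under the bundled published model, and derives utilities two
ways: Monte Carlo simulation (5 reps) and the exact analytic expectation.
"""

import numpy as np
import pandas as pd

from dlqimap import bundled_model, predict_utility_mc
from dlqimap.prediction import expected_utility_analytic

cohort = pd.DataFrame(
    [
        # id, age, sex(0=M,1=F), ten DLQI item scores (0-3)
        {"id": "A", "age": 28, "sex": 0, **{f"dlqi{i}": 0 for i in range(1, 11)}},
        {"id": "B", "age": 46, "sex": 1, **{f"dlqi{i}": v for i, v in enumerate([2, 1, 1, 0, 0, 1, 0, 0, 0, 2], 1)}},
        {"id": "C", "age": 71, "sex": 1, **{f"dlqi{i}": v for i, v in enumerate([3, 3, 2, 2, 1, 2, 3, 1, 1, 3], 1)}},
    ]
)

model = bundled_model()
preds = predict_utility_mc(model, cohort, reps=5, seed=1)
analytic = expected_utility_analytic(model, cohort)

print("id  DLQI total  MC mean utility  analytic expectation")
for row, p, a in zip(cohort.itertuples(), preds, analytic):
    total = sum(getattr(row, f"dlqi{i}") for i in range(1, 11))
    print(f"{p.subject_id:>2}  {total:>10d}  {p.mean_utility:>15.4f}  {a:>20.4f}")

print(
    "\nHigher DLQI totals (worse dermatology-specific quality of life) map to"
    "\nlower EQ-5D utilities; the Monte Carlo mean fluctuates around the exact"
    "\nexpectation and converges to it as reps grows."
)
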