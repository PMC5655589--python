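"""EQ-5D-3L states, the UK TTO tariff, and the item-domain association screen.

Walks the 243-state space, shows the additive tariff at its extremes, and
computes Spearman associations between DLQI items and EQ-5D domains on a
synthetic cohort.
"""

from dlqimap import Eq5dState, state_from_index, utility, utility_table
from dlqimap.fitting import item_domain_association
from dlqimap.synthetic import CohortConfig, generate_cohort

table = utility_table()
print(f"{len(table)} EQ-5D-3L states; utility range "
      f"[{table.min():.3f}, {table.max():.3f}]")
for levels in [(1, 1, 1, 1, 1), (1, 1, 1, 2, 1), (2, 2, 2, 2, 2), (3, 3, 3, 3, 3)]:
    s = Eq5dState(*levels)
    print(f"  state {''.join(map(str, levels))}: utility {utility(s):+.3f}")

cohort = generate_cohort(CohortConfig(n=3000, missing_rate=0.0, seed=55))
assoc = item_domain_association(cohort)
print("\nStrongest DLQI item per EQ-5D domain (Spearman rho):")
for domain in assoc.statistic.columns:
    item = assoc.statistic[domain].idxmax()
    rho = assoc.statistic.loc[item, domain]
    print(f"  {domain:>18}: {item} (rho = {rho:.2f})")

print(
    "\nUnder the bundled generating model, pain/discomfort associates most"
    "\nstrongly with DLQI item 1 (skin pain/soreness), mirroring the item's"
    "\ndominant weight in that domain's regression."
)
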