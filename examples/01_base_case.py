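"""Base case: microsimulate 10,000 women through each strategy.

Builds the three strategy trees from the bundled parameter table,
simulates one cohort with common random numbers across arms, and prints
the health-state distribution and the incremental cost-effectiveness
table against routine care.
"""

from ppdcea import ROUTINE, build_strategy_trees, load_default_parameters, simulate_cohorts
from ppdcea.cea import format_table, icer_table
from ppdcea.model import classify_cohort

params = load_default_parameters()
trees = build_strategy_trees(params)
cohorts = simulate_cohorts(trees, params, n=10_000, seed=2024)

print("Health-state counts per 10,000 women:")
for strategy, result in cohorts.items():
    print(f"  {strategy}: {classify_cohort(result).to_dict()}")

results = {s: (r.mean_cost, r.mean_effect) for s, r in cohorts.items()}
table = icer_table(results, reference=ROUTINE, gdp_per_capita=params["gdp_per_capita"])
print("\nCost-effectiveness table (costs USD/woman, effects QALY on a")
print("normalized horizon where 1 = two healthy years; ICER = USD per QALY):")
print(format_table(table).to_string(index=False))
print("\nAn ICER below GDP per capita (USD 11,300) is classed very cost-effective:")
print(table[["strategy", "who_class"]].to_string(index=False))
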