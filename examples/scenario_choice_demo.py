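"""Scenario choice with a random forest on a small reference table.

Simulates a reference table under all eight divergence/admixture
scenarios, trains the classification forest (with linear-discriminant
axes appended to the summary statistics), and classifies a pseudo-observed
dataset generated under Scenario 1. At this reduced table size the error
rates are rougher than at study scale but the machinery is identical.
"""
import numpy as np

import msatabc as M

scenario_set = M.load_default_scenarios()
rng = np.random.default_rng(11)

# pseudo-observed dataset with known generating scenario
scenario = scenario_set.get(1)
draw = M.sample_draw(scenario_set.priors, scenario, rng, n_loci=9)
observed = M.summarize_dataset(M.simulate_dataset(scenario, draw, scenario_set.loci, rng))

table = M.build_reference_table(scenario_set, n_per_scenario=300, seed=2)
M.append_lda_axes(table)
result = M.scenario_choice(table, observed, n_trees=500, seed=3)

print("votes per scenario (500 trees):")
for sid, v in zip(result.scenario_ids, result.votes):
    print(f"  scenario {sid}: {v}")
print(f"selected scenario: {result.selected} (truth: 1)")
print(f"posterior probability of the selection: {result.posterior_probability:.3f}")
print(f"global prior error rate (out-of-bag): {result.prior_error:.3f}")
print("per-scenario class errors:")
for sid, err in sorted(result.class_errors.items()):
    print(f"  scenario {sid}: {err:.3f}")
print("the prior error is the OOB misclassification rate over the whole")
print("prior-predictive table; the posterior probability is 1 minus the")
print("error expected at the observed dataset's position in feature space")
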