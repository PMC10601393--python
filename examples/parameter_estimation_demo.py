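"""Parameter estimation with quantile regression forests.

Restricts a reference table to Scenario 1, trains one regression forest
per parameter (summary statistics plus five PLS components each), and
estimates the split times, admixture proportion and an effective size for
a pseudo-observed dataset whose true parameters are known.
"""
import numpy as np

import msatabc as M

scenario_set = M.load_default_scenarios()
rng = np.random.default_rng(5)
scenario = scenario_set.get(1)

draw = M.sample_draw(scenario_set.priors, scenario, rng, n_loci=9)
observed = M.summarize_dataset(M.simulate_dataset(scenario, draw, scenario_set.loci, rng))

table = M.build_reference_table(
    scenario_set, n_per_scenario=1500, seed=8, scenario_ids=[1]
)
estimates = M.estimate_parameters(
    table, observed, ["t2", "ta", "ra", "NeI"], n_trees=500, n_oob=400, seed=9
)

print(f"{'param':>6} {'truth':>9} {'median':>9} {'90% interval':>22} "
      f"{'NMAE':>6} {'cover':>6}")
for name, est in estimates.items():
    truth = draw.values[name]
    print(f"{name:>6} {truth:9.3g} {est.median:9.3g} "
          f"[{est.q05:9.3g}, {est.q95:9.3g}] {est.global_nmae:6.2f} "
          f"{est.coverage90:6.2f}")
print("NMAE is the mean |estimate - truth|/truth over out-of-bag table rows;")
print("'cover' is how often each row's own 90% interval contains its truth.")
print("times are in generations (multiply by the 100-year generation time")
print("for calendar ages); Ne in diploid individuals.")
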