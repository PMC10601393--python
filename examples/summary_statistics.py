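"""Compute the 130-statistic ABC feature vector for a simulated dataset.

The vector holds, averaged over loci: per-population allele number,
gene diversity, allele-size variance and Garza-Williamson M; pooled
diversity, Weir-Cockerham F_ST, shared-allele distance and delta-mu^2 per
population pair; directed assignment log-likelihoods; and a maximum-
likelihood admixture coefficient per (target, parent-pair) triple.
"""
import numpy as np

import msatabc as M

scenario_set = M.load_default_scenarios()
rng = np.random.default_rng(7)
scenario = scenario_set.get(1)
draw = M.sample_draw(scenario_set.priors, scenario, rng, n_loci=9)
dataset = M.simulate_dataset(scenario, draw, scenario_set.loci, rng)

vector = M.summarize_dataset(dataset)
names = M.feature_names(dataset.populations)
print(f"{vector.size} features for {dataset.n_populations} populations")

for name in ("HET_I", "MGW_I", "FST_I_V", "DAS_I_V", "DM2_I_V",
             "LIK_I_V", "AML_III_II_IV"):
    print(f"  {name:>15} = {vector[names.index(name)]: .4f}")
print("AML_III_II_IV is the ML proportion of lineage III's ancestry assigned")
print(f"to lineage II; the generating admixture proportion was ra = "
      f"{draw.values['ra']:.3f}")
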