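"""Estimate a divergence time by rejection ABC (scaled-down demo).

Simulates an 'observed' dataset under a three-population scenario with a
known root split (9,000 generations), builds a prior-predictive simulation
table, and recovers the split time from the F_ST / Phi_ST summary vector.
A full-scale version of this experiment (the ten-population scenario,
20,000 simulations) runs in scripts/acceptance.py.
"""

import numpy as np

from yamori.abc import PriorSpec, abc_reject, build_sim_table, model_choice
from yamori.coalescent import simulate_snp_counts
from yamori.models import DemographicModel, PopulationSpec, SplitEvent
from yamori.sumstats import summary_vector_from_counts

scenario = DemographicModel(
    populations=(
        PopulationSpec("mainland", 8000, 10),
        PopulationSpec("island", 8000, 10),
        PopulationSpec("coast", 8000, 10),
    ),
    splits=(
        SplitEvent(3000.0, "coast", "island"),
        SplitEvent(9000.0, "island", "mainland"),
    ),
)

counts, sizes = simulate_snp_counts(scenario, n_snps=2000, seed=7)
prior = PriorSpec.default(scenario)
table = build_sim_table(scenario, prior, n_sims=4000, n_snps=120, seed=3, model_label="M1")
observed = summary_vector_from_counts(
    counts, np.broadcast_to(sizes, counts.shape), table.population_order
)

posterior = abc_reject(observed, table, tolerance=0.01)
q = posterior.quantiles
print(f"accepted {posterior.n_accepted} of {table.n_rows} simulations (tolerance 1%)")
for p, truth in (("t:island", 9000), ("t:coast", 3000)):
    print(f"{p:<9} truth {truth:>5}  posterior median {q.loc['q0.5', p]:7.0f} "
          f"[{q.loc['q0.025', p]:.0f}, {q.loc['q0.975', p]:.0f}] (95% interval)")
# The island split is the root of this scenario. At this demo scale (4,000
# simulations, 120 SNPs per row) the 95% interval comfortably covers the truth
# while the median still carries ABC noise; the full-scale experiment in
# scripts/acceptance.py (20,000 simulations, 250 SNPs per row) tightens it.
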