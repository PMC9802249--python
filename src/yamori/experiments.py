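"""Parameter-recovery experiments at desk scale.

Two self-contained calibration experiments for the pipeline's headline
quantities, each simulating its own synthetic truth and measuring how well
the estimator recovers it:

* :func:`root_split_recovery` — rejection ABC on one dataset simulated under
  the adopted divergence scenario at its reported median split times; returns
  the posterior median of the oldest (root) split, whose generating value is
  6,506 generations.
* :func:`bottleneck_timing` — stairway inference on a single-population SFS
  simulated with a 50-fold bottleneck whose onset sits 2,000 generations
  (3,000 years) before present, the island population's reported bottleneck
  date; returns the year-scaled time of the fitted Ne minimum.
"""

from __future__ import annotations

import numpy as np

from .abc import PriorSpec, abc_reject, build_sim_table
from .coalescent import simulate_snp_counts
from .models import build_m1
from .stairway import (
    NeTrajectory,
    StairwayConfig,
    expected_branch_times,
    fit_stairway,
    ne_minimum_time,
    scale_to_years,
    trajectory_model,
)
from .sumstats import summary_vector_from_counts

__all__ = ["root_split_recovery", "bottleneck_timing", "ROOT_SPLIT_TRUTH", "BOTTLENECK_TRUTH_YEARS"]

#: Generating value of the root (mainland-to-island) split, generations.
ROOT_SPLIT_TRUTH = 6506.0

#: Onset of the synthetic island bottleneck, years before present.
BOTTLENECK_TRUTH_YEARS = 3000.0


def _derive_seeds(seed: int, n: int) -> list[int]:
    return [int(s % (2**31 - 1)) for s in np.random.SeedSequence(seed).generate_state(n)]


def root_split_recovery(
    seed: int = 0,
    n_sims: int = 20_000,
    n_snps_obs: int = 5_000,
    n_snps_sim: int = 250,
    tolerance: float = 0.01,
) -> dict:
    """Simulate one dataset under the ten-population divergence scenario
    (median split times, Ne = 10,000 everywhere, the study's sample sizes,
    ``n_snps_obs`` ascertained SNPs); build an ``n_sims``-row prior-predictive
    table under the default priors; run rejection ABC on the F_ST / Phi_ST
    vector and report the posterior median of the root split time."""
    obs_seed, table_seed = _derive_seeds(seed, 2)
    m1 = build_m1()
    counts, sizes = simulate_snp_counts(m1, n_snps=n_snps_obs, seed=obs_seed)
    prior = PriorSpec.default(m1)
    table = build_sim_table(
        m1, prior, n_sims=n_sims, n_snps=n_snps_sim, seed=table_seed, model_label="M1"
    )
    observed = summary_vector_from_counts(
        counts, np.broadcast_to(sizes, counts.shape), table.population_order
    )
    posterior = abc_reject(observed, table, tolerance)
    median = float(posterior.quantiles.loc["q0.5", "t:Fukue"])
    return {
        "posterior_median_generations": median,
        "generating_value": ROOT_SPLIT_TRUTH,
        "n_sims": n_sims,
        "n_accepted": posterior.n_accepted,
        "tolerance": tolerance,
    }


def bottleneck_trajectory() -> NeTrajectory:
    """The synthetic island history: 10,000 diploids anciently, a 50-fold
    crash spanning [1,400, 2,000] generations with its onset at 2,000
    generations (3,000 years at 1.5 y/generation), recovered to 10,000 toward
    the present."""
    return NeTrajectory(
        np.array([0.0, 1400.0, 2000.0]), np.array([10_000.0, 200.0, 10_000.0])
    )


def bottleneck_timing(
    seed: int = 0,
    n_snps: int = 20_000,
    n_bootstrap: int = 200,
    mu: float = 3.75e-8,
    generation_time_years: float = 1.5,
    n_diploids: int = 6,
) -> dict:
    """Simulate an SFS for ``2 * n_diploids`` lineages under the bottleneck
    trajectory with a sequence length calibrated to yield ``n_snps`` SNPs in
    expectation, fit the stairway estimator with default nrand candidates,
    and report the year-scaled time of the median trajectory's Ne minimum."""
    sim_seed, fit_seed = _derive_seeds(seed, 2)
    traj = bottleneck_trajectory()
    n = 2 * n_diploids
    et = expected_branch_times(traj, n, seed=fit_seed)
    total_length = float((et * np.arange(n, 1, -1)).sum())
    n_sites = n_snps / (mu * total_length)
    model = trajectory_model(traj, n_diploids, mu=mu, generation_time_years=generation_time_years)
    from .coalescent import simulate_sfs

    sfs = simulate_sfs(model, n_snps=n_snps, folded=True, seed=sim_seed)["pop"]
    config = StairwayConfig(
        nseq=n,
        mu_per_site_per_generation=mu,
        generation_time_years=generation_time_years,
        n_sites=n_sites,
        n_bootstrap=n_bootstrap,
        seed=fit_seed,
    )
    fit = fit_stairway(sfs, config)
    fit_years = scale_to_years(fit)
    t_years = float(ne_minimum_time(fit_years))
    return {
        "ne_minimum_time_years": t_years,
        "generating_value_years": BOTTLENECK_TRUTH_YEARS,
        "n_snps": n_snps,
        "n_bootstrap": n_bootstrap,
        "chosen_nrand": fit.chosen_nrand,
    }
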