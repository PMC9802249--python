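"""ABC: prior sampling, simulation tables, rejection posteriors and model
choice."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from yamori.abc import (
    ABCPosterior,
    ParamSpec,
    PriorSpec,
    SimulationTable,
    abc_reject,
    build_sim_table,
    instantiate_model,
    model_choice,
    posterior_quantiles,
    sample_prior,
)
from yamori.coalescent import SampleConfig, simulate_snp_counts
from yamori.models import DemographicModel, MigrationSpec, build_m1
from yamori.sumstats import summary_vector_from_counts


def observed_vector(model, table, n_snps=1500, seed=77):
    cts, sizes = simulate_snp_counts(model, n_snps=n_snps, seed=seed)
    return summary_vector_from_counts(
        cts, np.broadcast_to(sizes, cts.shape), table.population_order
    )


@pytest.fixture(scope="module")
def toy_table(toy_three_pop):
    prior = PriorSpec.default(toy_three_pop)
    return build_sim_table(
        toy_three_pop, prior, n_sims=1200, n_snps=80, seed=7, model_label="M1"
    )


class TestPriorSampling:
    def test_degenerate_prior_gives_identical_draws(self, toy_three_pop):
        prior = PriorSpec(
            params=(
                ParamSpec("ne:A", "loguniform", 5000, 5000),
                ParamSpec("ne:B", "loguniform", 5000, 5000),
                ParamSpec("ne:C", "loguniform", 5000, 5000),
                ParamSpec("t:B", "uniform", 9000, 9000),
                ParamSpec("t:C", "uniform", 3000, 3000),
            ),
        )
        draws = sample_prior(prior, toy_three_pop, 50, seed=1)
        assert (draws.nunique() == 1).all()
        m = instantiate_model(toy_three_pop, draws.iloc[0])
        assert m.split_of("B").time_generations == 9000

    def test_uniform_mean_matches_law_of_large_numbers(self, toy_three_pop):
        prior = PriorSpec.default(toy_three_pop, root_time_bounds=(1000, 5000))
        draws = sample_prior(prior, toy_three_pop, 10_000, seed=3)
        root = draws["t:B"]
        se = root.std() / np.sqrt(len(root))
        assert abs(root.mean() - 3000) < 3 * se

    def test_hierarchical_ordering_always_satisfied(self):
        m1 = build_m1()
        prior = PriorSpec.default(m1)
        draws = sample_prior(prior, m1, 2000, seed=5)
        by_derived = {s.derived: s.ancestral for s in m1.splits}
        for derived, anc in by_derived.items():
            if anc in by_derived:  # ancestor itself splits later
                assert (draws[f"t:{derived}"] < draws[f"t:{anc}"]).all()

    def test_every_draw_instantiates_a_valid_model(self, toy_three_pop):
        prior = PriorSpec.default(toy_three_pop)
        draws = sample_prior(prior, toy_three_pop, 200, seed=8)
        for i in range(0, 200, 40):
            m = instantiate_model(toy_three_pop, draws.iloc[i])
            assert isinstance(m, DemographicModel)

    def test_infeasible_bounds_rejected(self, toy_three_pop):
        prior = PriorSpec(
            params=(
                ParamSpec("ne:A", "loguniform", 1e3, 1e4),
                ParamSpec("ne:B", "loguniform", 1e3, 1e4),
                ParamSpec("ne:C", "loguniform", 1e3, 1e4),
                ParamSpec("t:B", "uniform", 100, 200),
                ParamSpec("t:C", "uniform", 500, 900),  # child cannot fit below parent
            ),
        )
        with pytest.raises(ValueError, match="infeasible"):
            sample_prior(prior, toy_three_pop, 100, seed=0)

    def test_bad_param_specs_rejected(self):
        with pytest.raises(ValueError):
            ParamSpec("x", "uniform", 5, 1)
        with pytest.raises(ValueError):
            ParamSpec("x", "loguniform", 0, 1)
        with pytest.raises(ValueError):
            ParamSpec("x", "gaussian", 0, 1)


class TestSimulationTable:
    def test_deterministic_rerun(self, toy_three_pop):
        prior = PriorSpec.default(toy_three_pop)
        a = build_sim_table(toy_three_pop, prior, 10, n_snps=40, seed=11)
        b = build_sim_table(toy_three_pop, prior, 10, n_snps=40, seed=11)
        pd.testing.assert_frame_equal(a.stats, b.stats)
        pd.testing.assert_frame_equal(a.params, b.params)

    def test_column_count_is_twice_choose_two(self, toy_table):
        assert toy_table.stats.shape[1] == 2 * 3  # 2 * C(3, 2)

    def test_mean_fst_increases_with_root_split_prior(self, toy_three_pop):
        shallow = PriorSpec.default(toy_three_pop, root_time_bounds=(200, 2000))
        deep = PriorSpec.default(toy_three_pop, root_time_bounds=(20_000, 60_000))
        t_sh = build_sim_table(toy_three_pop, shallow, 120, n_snps=60, seed=2)
        t_dp = build_sim_table(toy_three_pop, deep, 120, n_snps=60, seed=2)
        assert (
            t_dp.stats["fst:A|B"].mean() > t_sh.stats["fst:A|B"].mean() + 0.1
        )

    def test_roundtrip_save_load(self, toy_table, tmp_path):
        toy_table.save(tmp_path / "tbl")
        back = SimulationTable.load(tmp_path / "tbl")
        assert back.model_label == toy_table.model_label
        pd.testing.assert_frame_equal(back.stats, toy_table.stats)


class TestRejection:
    def test_tolerance_one_accepts_everything(self, toy_three_pop, toy_table):
        obs = observed_vector(toy_three_pop, toy_table)
        post = abc_reject(obs, toy_table, 1.0)
        assert post.n_accepted == toy_table.n_rows
        pd.testing.assert_frame_equal(
            post.accepted.sort_values(list(post.accepted.columns)).reset_index(drop=True),
            toy_table.params.sort_values(list(toy_table.params.columns)).reset_index(drop=True),
        )

    def test_exact_match_has_zero_distance_and_is_accepted(self, toy_three_pop, toy_table):
        row = toy_table.stats.iloc[5].to_numpy()
        from yamori.data import SummaryVector

        obs = SummaryVector(
            values=row,
            labels=list(toy_table.stats.columns),
            population_order=toy_table.population_order,
            fst_estimator=toy_table.fst_estimator,
        )
        post = abc_reject(obs, toy_table, 0.01)
        assert post.distances[0] == 0.0
        assert post.n_accepted == int(np.ceil(0.01 * toy_table.n_rows))

    def test_mad_standardization_is_affine_invariant(self, toy_three_pop, toy_table):
        obs = observed_vector(toy_three_pop, toy_table)
        post1 = abc_reject(obs, toy_table, 0.05)
        scaled = dataclasses.replace(
            toy_table, stats=toy_table.stats * 7.5 + 0.3, params=toy_table.params
        )
        obs2 = dataclasses.replace(obs, values=obs.values * 7.5 + 0.3)
        post2 = abc_reject(obs2, scaled, 0.05)
        pd.testing.assert_frame_equal(post1.accepted, post2.accepted)

    def test_invalid_tolerance(self, toy_three_pop, toy_table):
        obs = observed_vector(toy_three_pop, toy_table)
        with pytest.raises(ValueError):
            abc_reject(obs, toy_table, 0.0)

    def test_posterior_quantiles(self):
        post = ABCPosterior(
            accepted=pd.DataFrame({"x": [1.0, 2, 3, 4, 5]}),
            distances=np.zeros(5),
            tolerance=1.0,
            n_table=5,
            quantiles=pd.DataFrame(),
        )
        q = posterior_quantiles(post, [0.0, 0.5, 1.0])
        assert q.loc["q0.0", "x"] == 1
        assert q.loc["q0.5", "x"] == 3
        assert q.loc["q1.0", "x"] == 5
        probs = np.linspace(0, 1, 11)
        qs = posterior_quantiles(post, probs)["x"].to_numpy()
        assert (np.diff(qs) >= 0).all()

    def test_coverage_of_root_time_interval(self, toy_three_pop, toy_table):
        """Over 100 replicates with truth drawn from the prior, the 95%
        posterior interval for the root split covers truth in >= 85%."""
        prior = PriorSpec.default(toy_three_pop)
        truths = sample_prior(prior, toy_three_pop, 100, seed=99)
        covered = 0
        for i in range(100):
            truth_model = instantiate_model(toy_three_pop, truths.iloc[i])
            cts, sizes = simulate_snp_counts(
                truth_model, SampleConfig.from_model(toy_three_pop), n_snps=80, seed=2000 + i
            )
            obs = summary_vector_from_counts(
                cts, np.broadcast_to(sizes, cts.shape), toy_table.population_order
            )
            post = abc_reject(obs, toy_table, 0.03)
            lo, hi = np.quantile(post.accepted["t:B"], [0.025, 0.975])
            covered += lo <= truths.iloc[i]["t:B"] <= hi
        assert covered >= 85


@pytest.fixture(scope="module")
def tables(toy_three_pop):
    migs = tuple(
        MigrationSpec(a, b, 1e-3)
        for s in toy_three_pop.splits
        for a, b in ((s.derived, s.ancestral), (s.ancestral, s.derived))
    )
    toy_mig = dataclasses.replace(toy_three_pop, migrations=migs)
    p1 = PriorSpec.default(toy_three_pop)
    p2 = PriorSpec.default(toy_mig, migration_bounds=(3e-3, 3e-2))
    t1 = build_sim_table(toy_three_pop, p1, 1200, n_snps=80, seed=1, model_label="M1")
    t2 = build_sim_table(toy_mig, p2, 1200, n_snps=80, seed=2, model_label="M2")
    t1b = build_sim_table(toy_three_pop, p1, 1200, n_snps=80, seed=3, model_label="M1b")
    return t1, t2, t1b


class TestModelChoice:
    def test_probabilities_sum_to_one(self, toy_three_pop, tables):
        t1, t2, _ = tables
        obs = observed_vector(toy_three_pop, t1)
        for method in ("rejection", "mnlogistic"):
            res = model_choice(obs, [t1, t2], tolerance=0.02, method=method)
            assert sum(res.probabilities.values()) == pytest.approx(1.0)

    def test_identical_models_split_evenly(self, toy_three_pop, tables):
        t1, _, t1b = tables
        obs = observed_vector(toy_three_pop, t1)
        res = model_choice(obs, [t1, t1b], tolerance=0.1, method="rejection")
        n = res.n_accepted
        se = np.sqrt(0.25 / n)
        assert abs(res.probabilities["M1"] - 0.5) < 3 * se

    def test_separable_scenarios_recover_truth(self, toy_three_pop, tables):
        t1, t2, _ = tables
        obs = observed_vector(toy_three_pop, t1)  # generated without migration
        res = model_choice(obs, [t1, t2], tolerance=0.02, method="mnlogistic")
        assert res.best_model == "M1"
        assert res.probabilities["M1"] > 0.9

    def test_methods_agree_in_argmax_when_separable(self, toy_three_pop, tables):
        t1, t2, _ = tables
        obs = observed_vector(toy_three_pop, t1)
        rej = model_choice(obs, [t1, t2], tolerance=0.02, method="rejection")
        mnl = model_choice(obs, [t1, t2], tolerance=0.02, method="mnlogistic")
        assert rej.best_model == mnl.best_model

    def test_single_table_rejected(self, toy_three_pop, tables):
        t1, _, _ = tables
        obs = observed_vector(toy_three_pop, t1)
        with pytest.raises(ValueError):
            model_choice(obs, [t1], tolerance=0.1)
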