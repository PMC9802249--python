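"""Structured-coalescent simulator: closed-form oracles, cross-simulator
agreement with msprime, and structural invariants."""

import numpy as np
import pytest

from yamori import _kernels
from yamori.coalescent import (
    SampleConfig,
    _encode,
    simulate_genealogy,
    simulate_sfs,
    simulate_snp_counts,
    simulate_snps,
)
from yamori.models import DemographicModel, MigrationSpec, PopulationSpec, SplitEvent
from yamori.sumstats import summary_vector


def _tree_stats(model, haploids, seed, n_reps):
    enc = _encode(model, SampleConfig(haploids))
    return _kernels.sim_tree_stats(seed, *enc, n_reps)


class TestSinglePopulationOracles:
    def test_two_lineage_tmrca_mean_is_2n(self, single_pop):
        tm, _ = _tree_stats(single_pop, {"A": 2}, seed=11, n_reps=20_000)
        se = tm.std() / np.sqrt(len(tm))
        assert abs(tm.mean() - 2000) < 3 * se

    def test_total_length_matches_harmonic_sum(self, single_pop):
        # E[total length] = 4N * sum_{k=1}^{n-1} 1/k
        _, tl = _tree_stats(single_pop, {"A": 10}, seed=7, n_reps=20_000)
        expected = 4 * 1000 * sum(1 / k for k in range(1, 10))
        se = tl.std() / np.sqrt(len(tl))
        assert abs(tl.mean() - expected) < 3 * se

    def test_sfs_follows_one_over_i_law(self, single_pop):
        counts, sizes = simulate_snp_counts(
            single_pop, SampleConfig({"A": 4}), n_snps=10_000, seed=42
        )
        freq = np.bincount(counts[:, 0], minlength=5)[1:4] / 10_000
        expected = np.array([1, 1 / 2, 1 / 3]) / (1 + 1 / 2 + 1 / 3)
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert np.all(np.abs(freq - expected) < 3 * se)

    def test_two_lineages_only_singletons(self, single_pop):
        counts, _ = simulate_snp_counts(single_pop, SampleConfig({"A": 2}), n_snps=10, seed=5)
        assert (counts[:, 0] == 1).all()


class TestStructuredScenarios:
    def test_tmrca_exceeds_split_time_without_migration(self):
        m = DemographicModel(
            populations=(PopulationSpec("A", 1000, 1), PopulationSpec("B", 1000, 1)),
            splits=(SplitEvent(5000.0, "B", "A"),),
        )
        tm, _ = _tree_stats(m, {"A": 1, "B": 1}, seed=3, n_reps=3000)
        assert tm.min() > 5000.0

    def test_size_change_shifts_tmrca(self):
        # 10x larger ancient size => older two-lineage TMRCA on average
        from yamori.models import SizeChange

        small = DemographicModel(
            populations=(PopulationSpec("A", 1000, 1),), splits=()
        )
        grown = DemographicModel(
            populations=(PopulationSpec("A", 1000, 1),),
            splits=(),
            size_changes=(SizeChange("A", 500.0, 10_000.0),),
        )
        tm_s, _ = _tree_stats(small, {"A": 2}, seed=1, n_reps=8000)
        tm_g, _ = _tree_stats(grown, {"A": 2}, seed=1, n_reps=8000)
        assert tm_g.mean() > tm_s.mean() * 2

    def test_every_site_polymorphic_in_total_sample(self, toy_three_pop):
        counts, sizes = simulate_snp_counts(toy_three_pop, n_snps=2000, seed=9)
        tot = counts.sum(axis=1)
        assert (tot >= 1).all() and (tot <= sizes.sum() - 1).all()

    def test_seed_determinism(self, toy_three_pop):
        a, _ = simulate_snp_counts(toy_three_pop, n_snps=300, seed=77)
        b, _ = simulate_snp_counts(toy_three_pop, n_snps=300, seed=77)
        c, _ = simulate_snp_counts(toy_three_pop, n_snps=300, seed=78)
        assert (a == b).all()
        assert (a != c).any()

    def test_exchangeability_of_individuals(self, toy_three_pop):
        ds = simulate_snps(toy_three_pop, n_snps=500, seed=21)
        rng = np.random.default_rng(0)
        order = []
        for pop in ds.pop_names:
            idx = [i for i, p in enumerate(ds.populations) if p == pop]
            order.extend(rng.permutation(idx))
        shuffled = ds.subset_individuals(np.array(order))
        sv1 = summary_vector(ds)
        sv2 = summary_vector(shuffled)
        np.testing.assert_allclose(sv1.values, sv2.values, rtol=1e-12)


class TestGenealogyObject:
    def test_times_increase_rootward_and_leaf_count(self, toy_three_pop):
        g = simulate_genealogy(toy_three_pop, seed=4)
        assert g.n_leaves == 60
        parent = g.parents()
        has_parent = parent >= 0
        assert np.all(
            g.node_time[parent[has_parent]] >= g.node_time[np.flatnonzero(has_parent)]
        )
        assert g.tmrca == g.node_time[-1]
        assert g.total_branch_length > 0


class TestSfsMode:
    def test_folded_sfs_mass_conservation(self, single_pop):
        out = simulate_sfs(single_pop, SampleConfig({"A": 4}), n_snps=500, folded=True, seed=1)
        assert out["A"].total == 500
        assert out["total"].total == 500

    def test_folding_identity_same_seed(self, single_pop):
        cfg = SampleConfig({"A": 6})
        unf = simulate_sfs(single_pop, cfg, n_snps=400, folded=False, seed=13)["A"]
        fol = simulate_sfs(single_pop, cfg, n_snps=400, folded=True, seed=13)["A"]
        n = unf.n
        for j in range(1, n // 2 + 1):
            expect = unf.counts[j] + (unf.counts[n - j] if j != n - j else 0)
            assert fol.counts[j] == expect

    def test_unascertained_mode_is_refused(self, single_pop):
        with pytest.raises(ValueError, match="polymorphic"):
            simulate_snps(single_pop, n_snps=10, ascertained=False, seed=0)


class TestAgainstMsprime:
    """Cross-simulator oracle: expected pairwise diversity, TMRCA and F_ST on
    small scenarios agree within Monte-Carlo error."""

    def _msprime_tmrca(self, demography, samples, n_reps, seed):
        import msprime

        ts_iter = msprime.sim_ancestry(
            samples=samples,
            demography=demography,
            ploidy=1,
            num_replicates=n_reps,
            random_seed=seed,
        )
        return np.array([ts.max_root_time for ts in ts_iter])

    def test_single_population_tmrca(self):
        import msprime

        m = DemographicModel(populations=(PopulationSpec("A", 1000, 5),), splits=())
        tm_mine, _ = _tree_stats(m, {"A": 10}, seed=2, n_reps=8000)
        dem = msprime.Demography()
        # ploidy=1: msprime sizes are haploid, so 2*Ne matches the diploid rate
        dem.add_population(name="A", initial_size=2000)
        tm_ms = self._msprime_tmrca(dem, {"A": 10}, 8000, seed=3)
        se = np.sqrt(tm_mine.var() / len(tm_mine) + tm_ms.var() / len(tm_ms))
        assert abs(tm_mine.mean() - tm_ms.mean()) < 3.5 * se

    def test_two_population_split_tmrca(self):
        import msprime

        m = DemographicModel(
            populations=(PopulationSpec("A", 2000, 3), PopulationSpec("B", 500, 3)),
            splits=(SplitEvent(3000.0, "B", "A"),),
        )
        tm_mine, _ = _tree_stats(m, {"A": 6, "B": 6}, seed=8, n_reps=6000)
        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=4000)
        dem.add_population(name="B", initial_size=1000)
        # mass migration (not add_population_split) keeps A active before the
        # merge, matching this model's ancestral-population semantics
        dem.add_mass_migration(time=3000, source="B", dest="A", proportion=1.0)
        tm_ms = self._msprime_tmrca(dem, {"A": 6, "B": 6}, 6000, seed=9)
        se = np.sqrt(tm_mine.var() / len(tm_mine) + tm_ms.var() / len(tm_ms))
        assert abs(tm_mine.mean() - tm_ms.mean()) < 3.5 * se

    def test_island_model_with_migration_tmrca(self):
        import msprime

        rate = 5e-4
        m = DemographicModel(
            populations=(PopulationSpec("A", 1000, 2), PopulationSpec("B", 1000, 2)),
            splits=(SplitEvent(1e8, "B", "A"),),
            migrations=(MigrationSpec("A", "B", rate), MigrationSpec("B", "A", rate)),
        )
        tm_mine, _ = _tree_stats(m, {"A": 4, "B": 4}, seed=5, n_reps=6000)
        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=2000)
        dem.add_population(name="B", initial_size=2000)
        dem.set_migration_rate("A", "B", rate)
        dem.set_migration_rate("B", "A", rate)
        tm_ms = self._msprime_tmrca(dem, {"A": 4, "B": 4}, 6000, seed=6)
        se = np.sqrt(tm_mine.var() / len(tm_mine) + tm_ms.var() / len(tm_ms))
        assert abs(tm_mine.mean() - tm_ms.mean()) < 3.5 * se

    def test_two_population_fst_against_msprime_branch_stat(self):
        """Mean Hudson F_ST of SNP-mode simulation vs the same scenario's
        msprime branch-mode F_ST (mutation-rate-free oracle)."""
        import msprime

        split_t, ne = 8000.0, 1000.0  # deep split: 4N generations
        m = DemographicModel(
            populations=(PopulationSpec("A", ne, 8), PopulationSpec("B", ne, 8)),
            splits=(SplitEvent(split_t, "B", "A"),),
        )
        counts, sizes = simulate_snp_counts(m, n_snps=30_000, seed=10)
        from yamori.sumstats import hudson_fst_from_counts

        fst_mine = hudson_fst_from_counts(
            counts[:, 0], np.full(len(counts), sizes[0]),
            counts[:, 1], np.full(len(counts), sizes[1]),
        )
        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=2 * ne)
        dem.add_population(name="B", initial_size=2 * ne)
        dem.add_mass_migration(time=split_t, source="B", dest="A", proportion=1.0)
        reps = msprime.sim_ancestry(
            samples={"A": 8, "B": 8}, demography=dem, ploidy=1,
            num_replicates=400, random_seed=12,
        )
        # ratio-of-averages oracle: aggregate branch-mode diversity and
        # divergence over replicates, then form Hudson's 1 - Hw/Hb
        pops = [list(range(0, 8)), list(range(8, 16))]
        dw, db = [], []
        for ts in reps:
            da, dbb = ts.diversity(pops, mode="branch")
            dw.append(0.5 * (da + dbb))
            db.append(float(ts.divergence(pops, indexes=[(0, 1)], mode="branch")[0]))
        fst_ms = 1.0 - np.mean(dw) / np.mean(db)
        assert abs(fst_mine - fst_ms) < 0.02
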