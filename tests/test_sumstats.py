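"""Summary statistics: projection, folding, F_ST / Phi_ST oracles and
filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yamori.data import MISSING, SFS, SNPDataset
from yamori.sumstats import (
    fold_sfs,
    hudson_fst_from_counts,
    maf_filter,
    observed_sfs,
    pairwise_fst,
    pairwise_phi_st,
    pop_allele_counts,
    project_sfs,
    site_allele_counts,
    summary_vector,
    summary_vector_from_counts,
)
from yamori.synthetic import toy_phi_table

from _amova_oracle import brute_force_amova_phi


def dataset(rows, pops, ancestral_known=True):
    rows = np.asarray(rows, dtype=np.int8)
    return SNPDataset(
        genotypes=rows,
        individuals=[f"i{k}" for k in range(rows.shape[0])],
        populations=list(pops),
        ancestral_known=ancestral_known,
    )


class TestAlleleCounts:
    def test_dosage_sum_and_called_size(self):
        ds = dataset([[0], [1], [2]], ["P", "P", "P"])
        d, m = site_allele_counts(ds, "P")
        assert d[0] == 3 and m[0] == 6

    def test_all_missing_site_has_zero_size(self):
        ds = dataset([[MISSING, 0], [MISSING, 1]], ["P", "P"])
        d, m = site_allele_counts(ds, "P")
        assert m[0] == 0 and m[1] == 4

    def test_fixed_alternate(self):
        ds = dataset([[2], [2], [2]], ["P", "P", "P"])
        d, m = site_allele_counts(ds, "P")
        assert d[0] == 6 and m[0] == 6

    def test_minor_orientation_without_ancestral_flag(self):
        ds = dataset([[2], [2], [2]], ["P", "P", "P"], ancestral_known=False)
        d, _ = site_allele_counts(ds, "P")
        assert d[0] == 0  # 6/6 alternate folds to minor count 0

    def test_unknown_population_rejected(self):
        ds = dataset([[0]], ["P"])
        with pytest.raises(KeyError):
            site_allele_counts(ds, "Q")


class TestProjection:
    def test_projection_to_own_size_is_identity(self):
        d = np.array([1, 2, 3])
        m = np.array([4, 4, 4])
        sfs = project_sfs(d, m, 4)
        np.testing.assert_allclose(sfs.counts, [0, 1, 1, 1, 0])

    def test_enumerated_hypergeometric_example(self):
        # one site, 2 of 4 copies, projected to 3: C(2,j) C(2,3-j) / C(4,3)
        sfs = project_sfs(np.array([2]), np.array([4]), 3)
        np.testing.assert_allclose(sfs.counts, [0, 0.5, 0.5, 0])

    def test_small_sites_skipped_and_mass_conserved(self):
        d = np.array([1, 1, 2, 0])
        m = np.array([10, 4, 8, 2])  # only the m >= 6 sites are usable
        sfs = project_sfs(d, m, 6)
        assert sfs.total == pytest.approx(2.0)

    @given(st.integers(0, 20), st.integers(2, 10))
    @settings(max_examples=40, deadline=None)
    def test_mass_conservation_property(self, d, extra):
        m = d + extra
        n_proj = min(m, 7)
        if n_proj < 2:
            return
        sfs = project_sfs(np.array([d]), np.array([m]), n_proj)
        assert sfs.total == pytest.approx(1.0)

    def test_projection_default_is_2n_minus_1(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(15, 50)).astype(np.int8)
        ds = dataset(g, ["T"] * 15)
        sfs = observed_sfs(ds, "T")
        assert sfs.n == 29  # 2N - 1 for N = 15 diploids

    def test_rejects_tiny_projection(self):
        with pytest.raises(ValueError):
            project_sfs(np.array([1]), np.array([4]), 1)


class TestFolding:
    def test_folding_identity(self):
        folded = fold_sfs(SFS(4, [0, 3, 5, 7, 0]))
        np.testing.assert_allclose(folded.counts, [0, 10, 5])

    def test_symmetric_spectrum(self):
        folded = fold_sfs(SFS(4, [0, 2, 6, 2, 0]))
        np.testing.assert_allclose(folded.counts, [0, 4, 6])

    def test_mass_conserved_and_idempotence_rejected(self):
        sfs = SFS(5, [1, 2, 3, 4, 5, 6])
        folded = fold_sfs(sfs)
        assert folded.total == sfs.total
        with pytest.raises(ValueError, match="folded"):
            fold_sfs(folded)


class TestHudsonFst:
    def test_identical_counts_never_positive(self):
        # with unbiased within-heterozygosity (the convention the
        # hand-enumerated oracle below fixes), literally identical counts give
        # a small negative value, never spurious positive differentiation
        d = np.array([3, 1, 4])
        n = np.array([8, 8, 8])
        v = hudson_fst_from_counts(d, n, d, n)
        assert -0.2 < v <= 0.0

    def test_two_samples_of_one_pool_average_to_zero(self):
        # unbiasedness: repeated pairs of samples from one allele pool
        rng = np.random.default_rng(4)
        vals = []
        for _ in range(300):
            dA = rng.binomial(20, 0.3, size=50)
            dB = rng.binomial(20, 0.3, size=50)
            n = np.full(50, 20)
            vals.append(hudson_fst_from_counts(dA, n, dB, n))
        assert abs(np.mean(vals)) < 3 * np.std(vals) / np.sqrt(len(vals))

    def test_fixed_differences_give_one(self):
        d = np.full(5, 8)
        n = np.full(5, 8)
        assert hudson_fst_from_counts(d, n, np.zeros(5), n) == pytest.approx(1.0)

    def test_hand_enumerated_single_site(self):
        # popA 2/8, popB 6/8: Hw = 2*2*6/(8*7) = 0.42857, Hb = 0.625
        v = hudson_fst_from_counts(np.array([2]), np.array([8]), np.array([6]), np.array([8]))
        assert v == pytest.approx(1 - 0.42857142857 / 0.625, abs=1e-10)

    def test_no_usable_sites_returns_nan(self):
        v = hudson_fst_from_counts(np.array([1]), np.array([1]), np.array([0]), np.array([2]))
        assert np.isnan(v)


class TestWeirCockerham:
    def test_fixed_difference_is_one(self):
        ds = dataset([[2]] * 4 + [[0]] * 4, ["A"] * 4 + ["B"] * 4)
        assert pairwise_fst(ds, "A", "B", "weir_cockerham") == pytest.approx(1.0)

    def test_agrees_in_sign_and_scale_with_hudson_on_divergent_data(self):
        rng = np.random.default_rng(3)
        gA = rng.binomial(2, 0.15, size=(12, 300)).astype(np.int8)
        gB = rng.binomial(2, 0.75, size=(12, 300)).astype(np.int8)
        ds = dataset(np.vstack([gA, gB]), ["A"] * 12 + ["B"] * 12)
        wc = pairwise_fst(ds, "A", "B", "weir_cockerham")
        hu = pairwise_fst(ds, "A", "B", "hudson")
        assert wc > 0.2 and hu > 0.2
        assert abs(wc - hu) < 0.1

    def test_unknown_estimator(self):
        ds = toy_phi_table()
        with pytest.raises(ValueError):
            pairwise_fst(ds, "A", "B", estimator="nei")


class TestPhiSt:
    def test_identical_population_pool_is_near_zero(self, toy_three_pop):
        # two labels drawn from one panmictic pool: Phi fluctuates around 0
        from yamori.coalescent import simulate_snps
        from yamori.models import DemographicModel, PopulationSpec

        pool = DemographicModel(
            populations=(PopulationSpec("P", 5000, 30),), splits=()
        )
        ds = simulate_snps(pool, n_snps=3000, seed=6)
        relabeled = SNPDataset(
            genotypes=ds.genotypes,
            individuals=ds.individuals,
            populations=["X"] * 15 + ["Y"] * 15,
            ancestral_known=True,
        )
        assert abs(pairwise_phi_st(relabeled, "X", "Y")) < 0.01

    def test_fixed_differences_give_one(self):
        ds = dataset([[2, 0]] * 4 + [[0, 2]] * 4, ["A"] * 4 + ["B"] * 4)
        assert pairwise_phi_st(ds, "A", "B") == pytest.approx(1.0)

    def test_toy_table_matches_brute_force_amova(self):
        ds = toy_phi_table()
        mine = pairwise_phi_st(ds, "A", "B")
        oracle = brute_force_amova_phi(ds, "A", "B")
        assert mine == pytest.approx(oracle, abs=1e-12)

    def test_random_complete_tables_match_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            g = rng.integers(0, 3, size=(10, 8)).astype(np.int8)
            ds = dataset(g, ["A"] * 5 + ["B"] * 5)
            d, m, _ = pop_allele_counts(ds, ["A", "B"])
            if np.all(d.sum(axis=1) % (m.sum(axis=1)) == 0):
                continue  # monomorphic table carries no signal
            mine = pairwise_phi_st(ds, "A", "B")
            oracle = brute_force_amova_phi(ds, "A", "B")
            assert mine == pytest.approx(oracle, abs=1e-12)


class TestSummaryVector:
    def test_length_for_ten_populations(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, size=(30, 40)).astype(np.int8)
        ds = dataset(g, [f"P{k % 10}" for k in range(30)])
        sv = summary_vector(ds)
        assert len(sv.values) == 90  # 2 * C(10, 2)

    def test_matches_direct_pairwise_calls(self):
        ds = toy_phi_table()
        sv = summary_vector(ds)
        assert sv.values[0] == pytest.approx(pairwise_fst(ds, "A", "B", "hudson"))
        assert sv.values[1] == pytest.approx(pairwise_phi_st(ds, "A", "B"))
        assert sv.labels == ["fst:A|B", "phi:A|B"]

    def test_missing_individual_changes_nothing(self):
        ds = toy_phi_table()
        g = np.vstack([ds.genotypes, np.full((1, ds.n_sites), MISSING, dtype=np.int8)])
        ds2 = SNPDataset(
            genotypes=g,
            individuals=ds.individuals + ["ghost"],
            populations=ds.populations + ["A"],
            ancestral_known=True,
        )
        np.testing.assert_allclose(summary_vector(ds).values, summary_vector(ds2).values)

    def test_count_path_requires_hudson(self):
        with pytest.raises(ValueError):
            summary_vector_from_counts(
                np.zeros((3, 2)), np.full((3, 2), 4), ["A", "B"], fst_estimator="weir_cockerham"
            )

    def test_genotype_estimator_path(self):
        ds = toy_phi_table()
        sv = summary_vector(ds, fst_estimator="weir_cockerham")
        assert sv.fst_estimator == "weir_cockerham"
        assert sv.values[0] == pytest.approx(pairwise_fst(ds, "A", "B", "weir_cockerham"))


class TestMafFilter:
    def test_zero_threshold_keeps_polymorphic_data(self):
        ds = toy_phi_table()
        assert maf_filter(ds, 0.0).n_sites == ds.n_sites

    def test_threshold_drops_rare_site(self):
        ds = dataset([[1, 1]] + [[0, 1]] * 4, ["P"] * 5)  # site 0 MAF 0.1, site 1 0.5
        out = maf_filter(ds, 0.2)
        assert out.n_sites == 1 and out.site_ids == ["snp1"]

    def test_matches_per_site_recount(self):
        rng = np.random.default_rng(8)
        g = rng.integers(-1, 3, size=(20, 100)).astype(np.int8)
        g[g < 0] = MISSING
        g[:, 0] = 1  # keep at least one call per site
        ds = dataset(g, ["P"] * 20)
        thr = 0.15
        out = maf_filter(ds, thr)
        kept = 0
        for j in range(ds.n_sites):
            col = ds.genotypes[:, j]
            called = col[col != MISSING]
            if len(called) == 0:
                continue
            d = int(called.sum())
            m = 2 * len(called)
            if min(d, m - d) / m >= thr:
                kept += 1
        assert out.n_sites == kept

    def test_out_of_range_threshold(self):
        ds = toy_phi_table()
        with pytest.raises(ValueError):
            maf_filter(ds, 0.5)
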