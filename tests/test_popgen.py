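"""Diversity, LD estimation, kinship, PCA, ancestry and N_Q."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import plustree as pt
from plustree.io import GenotypeMatrix


def _gm(scores, pops=None):
    scores = np.asarray(scores, dtype=float)
    return GenotypeMatrix(
        [f"G{i}" for i in range(scores.shape[0])],
        [f"S{j}" for j in range(scores.shape[1])],
        scores,
        pops,
    )


class TestHeterozygosity:
    def test_all_heterozygote_column(self):
        gm = _gm(np.zeros((10, 1)))
        div = pt.heterozygosities(gm, by_population=False, bias_corrected=False)
        row = div.per_snp.iloc[0]
        assert row["Ho"] == 1.0
        assert row["He"] == pytest.approx(0.5)

    def test_monomorphic_column(self):
        gm = _gm(np.ones((10, 1)))
        div = pt.heterozygosities(gm, by_population=False)
        assert div.per_snp["He"].iloc[0] == 0.0
        assert div.per_snp["Ho"].iloc[0] == 0.0

    def test_hwe_simulation_ho_matches_he(self):
        """Binomial sampling at p = 0.3: observed heterozygosity averages to
        the expected one (2pq) genome-wide."""
        rng = np.random.default_rng(0)
        n, m, p = 500, 2000, 0.3
        alleles = rng.random((n, m, 2)) < p
        scores = alleles.sum(axis=2) - 1.0
        div = pt.heterozygosities(_gm(scores), by_population=False)
        assert abs(div.summary["Ho"].iloc[0] - div.summary["He"].iloc[0]) < 0.01

    def test_tiny_population_rejected(self):
        gm = _gm(np.zeros((3, 2)), pops=["a", "a", "b"])
        with pytest.raises(ValueError):
            pt.heterozygosities(gm)


class TestLDr2:
    def test_identical_snps_give_one(self, rng):
        a = rng.choice([-1.0, 0.0, 1.0], size=200)
        r2, p = pt.ld_r2(a, a)
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert p < 1e-10

    def test_linkage_equilibrium_limit(self):
        rng = np.random.default_rng(1)
        n = 10_000
        a = (rng.random((n, 2)) < 0.4).sum(1) - 1.0
        b = (rng.random((n, 2)) < 0.6).sum(1) - 1.0
        r2, _ = pt.ld_r2(a, b)
        assert r2 < 0.01

    def test_worked_four_haplotype_example(self):
        """Haplotype frequencies (AB, Ab, aB, ab) = (0.4, 0.1, 0.1, 0.4):
        D = 0.4*0.4 - 0.1*0.1 = 0.15, r2 = 0.15^2 / 0.5^4 = 0.36.  The EM
        estimator on the collapsed unphased genotypes recovers it."""
        rng = np.random.default_rng(2)
        n = 10_000
        hap = rng.choice(4, size=(n, 2), p=[0.4, 0.1, 0.1, 0.4])
        a_allele = (hap < 2).sum(axis=1)       # copies of A
        b_allele = ((hap == 0) | (hap == 2)).sum(axis=1)
        r2, p = pt.ld_r2(a_allele - 1.0, b_allele - 1.0)
        assert r2 == pytest.approx(0.36, abs=0.02)
        assert p < 1e-10

    def test_monomorphic_returns_flagged_nan(self, rng):
        a = np.ones(100)
        b = rng.choice([-1.0, 0.0, 1.0], size=100)
        r2, p = pt.ld_r2(a, b)
        assert np.isnan(r2) and np.isnan(p)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            pt.ld_r2(np.zeros(5), np.zeros(5))

    def test_composite_mode_close_to_em_under_hwe(self):
        rng = np.random.default_rng(3)
        n = 2000
        hap = rng.choice(4, size=(n, 2), p=[0.35, 0.15, 0.15, 0.35])
        a = (hap < 2).sum(1) - 1.0
        b = ((hap == 0) | (hap == 2)).sum(1) - 1.0
        r2_em, _ = pt.ld_r2(a, b)
        r2_c, _ = pt.ld_r2(a, b, estimator="composite")
        assert abs(r2_em - r2_c) < 0.05


class TestLDProfiles:
    def test_longer_blocks_give_more_ld(self):
        """Mean within-LG r^2 is larger for 5-cM ancestry blocks than 1-cM
        blocks in every paired replicate (sign test)."""
        wins = 0
        n_rep = 10
        for seed in range(n_rep):
            means = []
            for block in (5.0, 1.0):
                spec = pt.CohortSpec(
                    n_populations=1, n_genotypes_per_pop=60,
                    n_ancestral_clusters=3, divergence=0.3,
                    recombination_block_cM=block, n_snps_mapped=80,
                    n_snps_unmapped=0, n_linkage_groups=2,
                    map_length_cM=60.0, missing_rate=0.0, seed=1000 + seed,
                )
                c = pt.simulate_cohort(spec)
                res = pt.ld_profiles(c.gm, c.gmap, by_population=False)
                means.append(res.summary["mean_r2"].iloc[0])
            wins += means[0] > means[1]
        assert stats.binomtest(wins, n_rep, 0.5, alternative="greater").pvalue < 0.05

    def test_decay_monotone_when_averaged(self):
        """Binned mean r^2 is non-increasing with map distance when averaged
        over replicate cohorts."""
        bins = {}
        for seed in range(20):
            spec = pt.CohortSpec(
                n_populations=1, n_genotypes_per_pop=50, n_ancestral_clusters=3,
                divergence=0.3, recombination_block_cM=4.0, n_snps_mapped=60,
                n_snps_unmapped=0, n_linkage_groups=1, map_length_cM=40.0,
                missing_rate=0.0, seed=2000 + seed,
            )
            c = pt.simulate_cohort(spec)
            res = pt.ld_profiles(
                c.gm, c.gmap, by_population=False, bin_width=8.0
            )
            for _, r in res.decay.iterrows():
                bins.setdefault(r["bin_left"], []).append(r["mean_r2"])
        # admixture LD decays to a genome-wide baseline: check the decaying
        # range (a few block lengths), not the long-range plateau
        lefts = [b for b in sorted(bins) if b < 24.0]
        curve = [np.mean(bins[b]) for b in lefts]
        assert len(curve) >= 3
        assert all(b <= a + 1e-3 for a, b in zip(curve, curve[1:]))

    def test_single_snp_per_lg_is_empty_not_crash(self):
        gm = _gm(np.random.default_rng(0).choice([-1.0, 0.0, 1.0], (30, 2)))
        t = pd.DataFrame(
            {"linkage_group": pd.array([1, 2], dtype="Int64"), "cM": [0.0, 5.0]},
            index=pd.Index(["S0", "S1"], name="snp_id"),
        )
        res = pt.ld_profiles(gm, pt.GeneticMap(t), by_population=False)
        assert res.pairs.empty

    def test_isotig_mode_requires_isotigs(self):
        gm = _gm(np.random.default_rng(0).choice([-1.0, 0.0, 1.0], (30, 2)))
        t = pd.DataFrame(
            {"linkage_group": pd.array([1, 1], dtype="Int64"), "cM": [0.0, 5.0]},
            index=pd.Index(["S0", "S1"], name="snp_id"),
        )
        with pytest.raises(ValueError, match="isotig"):
            pt.ld_profiles(gm, pt.GeneticMap(t), mode="within_isotig")

    def test_isotig_profile_on_cohort(self, small_cohort):
        res = pt.ld_profiles(
            small_cohort.gm, small_cohort.gmap, mode="within_isotig",
            by_population=False, max_pairs_per_group=50,
        )
        assert (res.pairs["distance"] < 6000).all()
        assert not res.summary.empty


class TestKinship:
    def test_duplicate_rows_match_diagonal(self, rng):
        X = rng.choice([-1.0, 0.0, 1.0], size=(20, 300))
        X[5] = X[4]
        K = pt.kinship(X)
        assert abs(K[4, 5] - K[4, 4]) < 1e-10
        assert abs(K[4, 5] - K[5, 5]) < 1e-10

    def test_unrelated_off_diagonal_vanishes_with_snps(self, rng):
        """Independent SNPs, no structure: off-diagonals concentrate around
        zero (up to the -1/(n-1) sample-centering offset) and their spread
        shrinks as markers accumulate."""
        n = 200
        spreads, means = [], []
        for m in (500, 20000):
            X = rng.choice([-1.0, 0.0, 1.0], size=(n, m))
            K = pt.kinship(X)
            off = K[~np.eye(n, dtype=bool)]
            spreads.append(off.std())
            means.append(off.mean())
        assert abs(means[1]) < 0.01
        assert spreads[1] < spreads[0] / 2
        assert spreads[1] < 0.02

    def test_symmetric_and_psd_with_ridge(self, rng):
        X = rng.choice([-1.0, 0.0, 1.0], size=(25, 100))
        K = pt.kinship(X)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        evals = np.linalg.eigvalsh(K + 1e-6 * np.eye(25))
        assert evals.min() > -1e-10

    def test_monomorphic_matrix_rejected(self):
        with pytest.raises(ValueError):
            pt.kinship(np.ones((5, 4)))


class TestPCA:
    def test_two_clusters_separate_on_pc1(self, rng):
        a = rng.choice([-1.0, 0.0, 1.0], size=(30, 200), p=[0.7, 0.2, 0.1])
        b = rng.choice([-1.0, 0.0, 1.0], size=(30, 200), p=[0.1, 0.2, 0.7])
        res = pt.pca(np.vstack([a, b]), n_components=2)
        pc1 = res.scores[:, 0]
        # the two clusters must not overlap on PC1
        mid = (pc1[:30].mean() + pc1[30:].mean()) / 2
        assert (pc1[:30] < mid).all() != (pc1[30:] < mid).all()
        assert (pc1[:30] < mid).all() or (pc1[30:] < mid).all()

    def test_duplicate_genotypes_have_identical_scores(self, rng):
        X = rng.choice([-1.0, 0.0, 1.0], size=(20, 100))
        X[7] = X[3]
        res = pt.pca(X, n_components=5)
        np.testing.assert_allclose(res.scores[3], res.scores[7], atol=1e-8)

    def test_variance_shares_sum_to_one(self, rng):
        X = rng.choice([-1.0, 0.0, 1.0], size=(15, 40))
        res = pt.pca(X)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_single_genotype_rejected(self):
        with pytest.raises(ValueError):
            pt.pca(np.zeros((1, 10)))


class TestAncestry:
    def test_k1_is_null_model(self, small_cohort):
        res = pt.estimate_ancestry(small_cohort.gm, K=1, seed=0)
        np.testing.assert_array_equal(res.Q, np.ones((small_cohort.gm.n_genotypes, 1)))
        assert np.all(res.N_Q == 1.0)
        assert np.isfinite(res.cross_entropy)

    def test_one_hot_clusters_recovered(self):
        spec = pt.CohortSpec(
            n_populations=3, n_genotypes_per_pop=(40, 40, 40),
            n_ancestral_clusters=3,
            admixture_concentration=[[30, 0.05, 0.05], [0.05, 30, 0.05], [0.05, 0.05, 30]],
            divergence=0.3, n_snps_mapped=500, n_snps_unmapped=0,
            n_linkage_groups=3, missing_rate=0.0, seed=21,
        )
        c = pt.simulate_cohort(spec)
        res = pt.estimate_ancestry(c.gm, K=3, n_runs=3, seed=0)
        from itertools import permutations

        true, est = c.Q_true.argmax(1), res.Q.argmax(1)
        match = max(
            np.mean(np.asarray(perm)[est] == true)
            for perm in permutations(range(3))
        )
        assert match >= 0.95

    def test_cross_entropy_elbow_at_true_k(self):
        """Masked cross-entropy over K = 1..6 bottoms out at the true K = 4
        in most replicate cohorts."""
        hits = 0
        n_rep = 6
        for seed in range(n_rep):
            spec = pt.CohortSpec(
                n_genotypes_per_pop=(40, 40, 40), n_snps_mapped=600,
                n_snps_unmapped=0, n_linkage_groups=3, divergence=0.25,
                missing_rate=0.0, seed=100 + seed,
            )
            c = pt.simulate_cohort(spec)
            ces = [
                pt.estimate_ancestry(c.gm, K, n_runs=2, seed=seed, n_iter=40).cross_entropy
                for K in range(1, 7)
            ]
            hits += int(np.argmin(ces)) + 1 == 4
        assert hits >= n_rep - 1

    def test_q_rows_on_simplex(self, small_cohort):
        res = pt.estimate_ancestry(small_cohort.gm, K=4, n_runs=1, seed=1, n_iter=30)
        np.testing.assert_allclose(res.Q.sum(axis=1), 1.0, atol=1e-6)
        assert (res.Q >= 0).all()
        assert ((res.N_Q >= 1.0) & (res.N_Q <= 4.0)).all()

    def test_k_larger_than_cohort_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            pt.estimate_ancestry(small_cohort.gm, K=10**4)


class TestEffectiveClusters:
    @pytest.mark.parametrize(
        "q,expected",
        [
            ((1.0, 0.0, 0.0, 0.0), 1.0),
            ((0.25, 0.25, 0.25, 0.25), 4.0),
            ((0.5, 0.5, 0.0, 0.0), 2.0),
        ],
    )
    def test_analytic_values(self, q, expected):
        assert pt.effective_clusters(np.array(q)) == pytest.approx(expected)

    def test_invalid_row_rejected(self):
        with pytest.raises(ValueError):
            pt.effective_clusters(np.array([0.5, 0.4]))

    def test_schur_concavity_on_random_pairs(self):
        """Robin Hood transfers (large -> small component) never decrease
        N_Q."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            q = rng.dirichlet(np.ones(4) * rng.uniform(0.2, 3.0))
            i, j = int(np.argmax(q)), int(np.argmin(q))
            eps = rng.uniform(0.0, (q[i] - q[j]) / 2)
            q2 = q.copy()
            q2[i] -= eps
            q2[j] += eps
            assert pt.effective_clusters(q2) >= pt.effective_clusters(q) - 1e-12
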