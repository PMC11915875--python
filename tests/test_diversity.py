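import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from microsurv import diversity


def _frame(arr, prefix="s"):
    arr = np.atleast_2d(arr)
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(len(arr))],
                        columns=[f"t{j}" for j in range(arr.shape[1])])


class TestAlpha:
    def test_chao1_bias_corrected_hand_example(self):
        # F1=3 singletons, F2=0 doubletons: 5 + 3*2/(2*1) = 8
        alpha = diversity.alpha_diversity(_frame([5, 3, 1, 1, 1]))
        assert alpha["chao1"].iloc[0] == pytest.approx(8.0)

    def test_uniform_four_taxa(self):
        alpha = diversity.alpha_diversity(_frame([10, 10, 10, 10]))
        assert alpha["shannon"].iloc[0] == pytest.approx(np.log(4))
        assert alpha["simpson"].iloc[0] == pytest.approx(0.75)

    def test_single_taxon_degenerate(self):
        alpha = diversity.alpha_diversity(_frame([42, 0, 0]))
        assert alpha["shannon"].iloc[0] == pytest.approx(0.0)
        assert alpha["simpson"].iloc[0] == pytest.approx(0.0)
        assert alpha["chao1"].iloc[0] == pytest.approx(1.0)

    def test_invariants_on_random_counts(self, rng):
        counts = _frame(rng.integers(0, 200, (20, 30)))
        counts.iloc[:, 0] += 1  # no all-zero samples
        alpha = diversity.alpha_diversity(counts)
        richness = (counts.to_numpy() > 0).sum(axis=1)
        assert (alpha["chao1"].to_numpy() >= richness - 1e-9).all()
        assert (alpha["shannon"].to_numpy() <= np.log(richness) + 1e-9).all()
        assert alpha["simpson"].between(0, 1).all()

    def test_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            diversity.alpha_diversity(_frame([[1, 2], [0, 0]]))


class TestAlphaGroupTests:
    def test_extreme_separation_wilcoxon(self, rng):
        a = rng.normal(0, 1, 20)
        alpha = pd.DataFrame({"shannon": np.concatenate([a, a + 10])},
                             index=[f"s{i}" for i in range(40)])
        res = diversity.alpha_group_tests(alpha, ["A"] * 20 + ["B"] * 20)
        assert res.loc["shannon", "test"] == "wilcoxon"
        assert res.loc["shannon", "rank_p"] < 1e-5
        assert res.loc["shannon", "lm_p"] < 1e-10

    def test_three_identical_groups_kruskal_zero(self):
        vals = np.tile([1.0, 2.0, 3.0], 3)
        alpha = pd.DataFrame({"chao1": vals},
                             index=[f"s{i}" for i in range(9)])
        res = diversity.alpha_group_tests(
            alpha, np.repeat(["A", "B", "C"], 3))
        assert res.loc["chao1", "test"] == "kruskal-wallis"
        assert res.loc["chao1", "rank_stat"] == pytest.approx(0.0, abs=1e-9)

    def test_single_group_rejected(self):
        alpha = pd.DataFrame({"chao1": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="two groups"):
            diversity.alpha_group_tests(alpha, ["A", "A"])


class TestJsd:
    def test_identical_samples_zero(self):
        jsd = diversity.jsd_matrix(_frame([[3, 1], [6, 2]]))
        assert jsd.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_maximal(self):
        jsd = diversity.jsd_matrix(_frame([[5, 0], [0, 7]]))
        assert jsd.iloc[0, 1] == pytest.approx(np.log(2))

    def test_hand_example_against_kl_summation_oracle(self):
        p, q = np.array([1.0, 0.0]), np.array([0.5, 0.5])
        m = (p + q) / 2

        def kl(a, b):
            mask = a > 0
            return float((a[mask] * np.log(a[mask] / b[mask])).sum())

        expected = 0.5 * kl(p, m) + 0.5 * kl(q, m)
        # closed form: 1.5 log 2 - 0.75 log 3
        assert expected == pytest.approx(1.5 * np.log(2) - 0.75 * np.log(3))
        jsd = diversity.jsd_matrix(_frame([[4, 0], [2, 2]]))
        assert jsd.iloc[0, 1] == pytest.approx(expected)

    def test_symmetry_range_and_zero_diagonal(self, rng):
        counts = _frame(rng.integers(0, 100, (12, 8)))
        counts.iloc[:, 0] += 1
        jsd = diversity.jsd_matrix(counts)
        arr = jsd.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0.0)
        assert (arr >= -1e-12).all() and (arr <= np.log(2) + 1e-9).all()

    def test_sqrt_jsd_triangle_inequality(self, rng):
        counts = _frame(rng.integers(0, 60, (6, 5)))
        counts.iloc[:, 0] += 1
        d = np.sqrt(diversity.jsd_matrix(counts).to_numpy())
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestPermanova:
    def test_separated_clusters_attain_minimum_p(self, rng):
        a = rng.normal(0, 0.05, (10, 3))
        b = rng.normal(5, 0.05, (10, 3)) + 5
        pts = np.vstack([a, b])
        from scipy.spatial.distance import pdist, squareform
        D = pd.DataFrame(squareform(pdist(pts)),
                         index=[f"s{i}" for i in range(20)],
                         columns=[f"s{i}" for i in range(20)])
        res = diversity.permanova(D, ["A"] * 10 + ["B"] * 10, n_perm=99,
                                  seed=0)
        assert res["p"] == pytest.approx(1 / 100)

    def test_p_respects_plus_one_floor(self, rng):
        pts = rng.normal(size=(12, 3))
        from scipy.spatial.distance import pdist, squareform
        D = pd.DataFrame(squareform(pdist(pts)),
                         index=[f"s{i}" for i in range(12)],
                         columns=[f"s{i}" for i in range(12)])
        res = diversity.permanova(D, ["A", "B"] * 6, n_perm=99, seed=1)
        assert res["p"] >= 1 / 100

    def test_constant_variable_rejected(self, rng):
        D = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"),
                         columns=list("abcd"))
        with pytest.raises(ValueError, match="constant"):
            diversity.permanova(D, ["A"] * 4, n_perm=99)

    def test_pseudo_f_matches_skbio_without_covariates(self, rng):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        pts = rng.normal(size=(15, 4))
        pts[8:] += 1.0
        from scipy.spatial.distance import pdist, squareform
        ids = [f"s{i}" for i in range(15)]
        D = pd.DataFrame(squareform(pdist(pts)), index=ids, columns=ids)
        labels = ["A"] * 8 + ["B"] * 7
        ours = diversity.permanova(D, labels, n_perm=99, seed=0)
        ref = skbio_permanova(DistanceMatrix(D.to_numpy(), ids),
                              grouping=labels, permutations=99)
        assert ours["pseudo_F"] == pytest.approx(ref["test statistic"],
                                                 rel=1e-10)


class TestRarefaction:
    def test_full_depth_recovers_observed_richness(self):
        counts = _frame([[10, 5, 0, 1]])
        rc = diversity.rarefaction_curves(counts, [16], n_draws=3, seed=0)
        assert rc.iloc[0, 0] == pytest.approx(3.0)

    def test_depth_one_gives_one(self):
        counts = _frame([[10, 5, 3]])
        rc = diversity.rarefaction_curves(counts, [1], n_draws=5, seed=0)
        assert rc.iloc[0, 0] == pytest.approx(1.0)

    def test_matches_hypergeometric_expectation(self):
        # E[richness] = sum_t (1 - C(N-n_t, d)/C(N, d))
        row = np.array([50, 50])
        expected = sum(1 - comb(100 - nt, 2) / comb(100, 2) for nt in row)
        assert expected == pytest.approx(1 + 50 / 99)
        rc = diversity.rarefaction_curves(_frame([row]), [2], n_draws=4000,
                                          seed=0)
        mc_se = 0.5 / np.sqrt(4000)
        assert rc.iloc[0, 0] == pytest.approx(expected, abs=4 * mc_se)

    def test_monotone_in_depth_and_depth_overflow_raises(self, rng):
        counts = _frame(rng.integers(0, 30, (3, 10)))
        counts.iloc[:, 0] += 5
        rc = diversity.rarefaction_curves(counts, [1, 5, 20], n_draws=20,
                                          seed=2)
        assert (rc.diff(axis=1).iloc[:, 1:].to_numpy() >= -1e-9).all()
        with pytest.raises(ValueError, match="exceeds total"):
            diversity.rarefaction_curves(counts, [10**6], n_draws=2, seed=0)
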