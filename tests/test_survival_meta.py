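import numpy as np
import pandas as pd
import pytest

from microsurv import (CoxFit, bh_fdr, meta_random_effects, permutation_test,
                       species_associations, stability_select)
from microsurv.survival_meta import (_dl_pool, build_covariate_matrix,
                                     permutation_pvalues)


def _fit(beta, se):
    return CoxFit.from_beta_se(beta, se, True, 10)


class TestDerSimonianLaird:
    def test_hand_computed_two_study_example(self):
        # betas (0.5, 0.1), both se 0.2: w=25 each, fixed=0.3, Q=2,
        # tau2=(2-1)/(50-25)=0.04, w*=12.5 -> pooled 0.3, se 0.2
        est = meta_random_effects([_fit(0.5, 0.2), _fit(0.1, 0.2)])
        assert est.q_stat == pytest.approx(2.0)
        assert est.tau2 == pytest.approx(0.04)
        assert est.beta_pooled == pytest.approx(0.3)
        assert est.se_pooled == pytest.approx(0.2)

    def test_homogeneous_studies(self):
        est = meta_random_effects([_fit(0.4, 0.2), _fit(0.4, 0.2)])
        assert est.beta_pooled == pytest.approx(0.4)
        assert est.tau2 == 0.0
        assert est.q_stat == pytest.approx(0.0)
        assert est.p_het == pytest.approx(1.0)

    def test_single_study_passthrough(self):
        est = meta_random_effects([_fit(-0.7, 0.3)])
        assert est.beta_pooled == pytest.approx(-0.7)
        assert est.se_pooled == pytest.approx(0.3)
        assert est.p_het == pytest.approx(1.0)

    def test_zero_tau2_equals_fixed_effect_pooling(self):
        # unequal SEs but betas close enough that Q < df
        fits = [_fit(0.30, 0.2), _fit(0.31, 0.4)]
        est = meta_random_effects(fits)
        w = np.array([1 / 0.2**2, 1 / 0.4**2])
        fixed = (w * np.array([0.30, 0.31])).sum() / w.sum()
        assert est.tau2 == 0.0
        assert est.beta_pooled == pytest.approx(fixed)
        assert est.se_pooled == pytest.approx(1 / np.sqrt(w.sum()))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            meta_random_effects([])

    def test_matches_statsmodels_combine_effects(self, rng):
        from statsmodels.stats.meta_analysis import combine_effects

        for _ in range(5):
            betas = rng.normal(0, 0.5, 3)
            ses = rng.uniform(0.1, 0.5, 3)
            res = _dl_pool(betas[:, None], ses[:, None])
            ref = combine_effects(betas, ses**2, method_re="dl")
            summ = ref.summary_frame()
            assert res["beta"][0] == pytest.approx(
                summ.loc["random effect", "eff"], abs=1e-10)
            assert res["tau2"][0] == pytest.approx(ref.tau2, abs=1e-10)


class TestBenjaminiHochberg:
    def test_all_equal_pvalues_unchanged(self):
        q = bh_fdr([0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    def test_hand_step_up_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_pvalue(self):
        assert bh_fdr([0.37]).iloc[0] == pytest.approx(0.37)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([])

    def test_matches_step_up_enumeration_oracle(self, rng):
        p = rng.uniform(size=12)
        m = len(p)
        # oracle: q_j = min_{k: p_k >= p_j} over ordered min of m*p_(k)/k
        order = np.argsort(p)
        q_oracle = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            j = order[rank]
            running = min(running, m * p[j] / (rank + 1))
            q_oracle[j] = running
        assert np.allclose(bh_fdr(p).to_numpy(), q_oracle)
        # monotone in p
        assert (np.diff(bh_fdr(np.sort(p)).to_numpy()) >= -1e-12).all()


class TestCovariateDesign:
    def test_reference_levels_and_dummies(self):
        meta = pd.DataFrame({
            "age": [60.0, 70.0, 65.0],
            "sex": ["Male", "Female", "Male"],
            "stage": ["IIB", "I/IIA", "IIB"],
            "smoking": ["Never", "Current", "Not reported"],
        })
        Z, names = build_covariate_matrix(meta)
        assert names == ["age", "sex_male", "stage_IIB", "smoking_Current",
                         "smoking_Not_reported"]
        assert Z[:, 1].tolist() == [1.0, 0.0, 1.0]

    def test_constant_columns_dropped(self):
        meta = pd.DataFrame({
            "age": [60.0, 70.0], "sex": ["Male", "Male"],
            "stage": ["IIB", "I/IIA"], "smoking": ["Never", "Never"]})
        Z, names = build_covariate_matrix(meta)
        assert names == ["age", "stage_IIB"]


class TestStabilitySelection:
    def test_frequencies_are_multiples_and_deterministic(self, small_sim):
        clr, meta = small_sim["clr"].values, small_sim["metadata"]
        sel1 = stability_select(clr, meta, "os", n_iter=20, seed=5)
        sel2 = stability_select(clr, meta, "os", n_iter=20, seed=5)
        assert sel1.frequency.equals(sel2.frequency)
        scaled = sel1.frequency.to_numpy() * 20
        assert np.allclose(scaled, np.round(scaled))
        assert ((sel1.frequency >= sel1.threshold)
                == sel1.selected).all()

    def test_invariant_to_sample_order(self, small_sim, rng):
        clr, meta = small_sim["clr"].values, small_sim["metadata"]
        perm = rng.permutation(len(meta))
        sel = stability_select(clr, meta, "os", n_iter=10, seed=3)
        sel_p = stability_select(clr.iloc[perm], meta.iloc[perm], "os",
                                 n_iter=10, seed=3)
        assert sel.frequency.sort_index().equals(
            sel_p.frequency.sort_index())

    def test_strong_effect_recovered(self, small_sim):
        clr, meta = small_sim["clr"].values, small_sim["metadata"]
        truth = small_sim["truth"]
        sel = stability_select(clr, meta, "os", n_iter=30, seed=9)
        causal = [t for t in truth.causal_taxa if t in clr.columns]
        assert sel.frequency[causal].mean() > 0.6

    def test_associations_table_shape_and_pooling(self, small_sim):
        clr, meta = small_sim["clr"].values, small_sim["metadata"]
        assoc = species_associations(clr, meta, "os")
        assert len(assoc) == clr.shape[1]
        ok = assoc["n_converged_cohorts"] == 2
        # pooled beta lies between the two cohort betas where homogeneous
        b1 = assoc.loc[ok, "beta_cohort1"]
        b2 = assoc.loc[ok, "beta_cohort2"]
        pooled = assoc.loc[ok, "beta_pooled"]
        assert ((pooled >= np.minimum(b1, b2) - 1e-9)
                & (pooled <= np.maximum(b1, b2) + 1e-9)).all()
        assert (assoc.loc[ok, "p_het"] > 0).all()


class TestPermutationPvalues:
    def test_formula_floor_and_direct_application(self):
        o_j = np.array([0.9, 0.9, 0.0])
        pfreqs = np.zeros((500, 3))
        pfreqs[:49, 1] = 0.95  # 49 of 500 permutations reach O_j
        p = permutation_pvalues(pfreqs, o_j)
        assert p[0] == pytest.approx(1 / 501)
        assert p[1] == pytest.approx(50 / 501)
        assert p[2] == pytest.approx(1.0)  # O_j = 0: every P_ij >= 0

    def test_full_permutation_run_bounds_and_qvalues(self, small_sim):
        clr, meta = small_sim["clr"].values, small_sim["metadata"]
        sel = stability_select(clr, meta, "os", n_iter=10, seed=1)
        summary = permutation_test(clr, meta, "os", sel, n_perm=8, seed=2)
        p = summary.p_perm.to_numpy()
        assert (p >= 1 / 9 - 1e-12).all() and (p <= 1.0).all()
        # q-values consistent with BH ordering: monotone in p
        dfq = pd.DataFrame({"p": summary.p_perm, "q": summary.q_value})
        dfq = dfq.sort_values("p")
        assert (dfq["q"].diff().dropna() >= -1e-12).all()
        zero_freq = sel.frequency == 0
        if zero_freq.any():
            assert (summary.p_perm[zero_freq] == 1.0).all()

    def test_zero_permutations_rejected(self, small_sim):
        clr, meta = small_sim["clr"].values, small_sim["metadata"]
        sel = stability_select(clr, meta, "os", n_iter=5, seed=1)
        with pytest.raises(ValueError):
            permutation_test(clr, meta, "os", sel, n_perm=0)
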