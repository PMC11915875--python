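import numpy as np
import pandas as pd
import pytest

from microsurv import (MRSVector, build_mrs, cox_mrs, km_logrank,
                       stratified_rerun)
from microsurv.survival_meta import SelectionResult


def _selection(taxa, selected):
    freq = pd.Series({t: (1.0 if t in selected else 0.0) for t in taxa},
                     name="O_j")
    return SelectionResult(freq, freq >= 0.6, 10, 0.9, 0.05, 0.6, "os")


def _zscore(v):
    v = np.asarray(v, dtype=float)
    return (v - v.mean()) / v.std(ddof=0)


class TestBuildMrs:
    def test_single_species_equals_zscored_clr_column(self, small_sim):
        clr = small_sim["clr"].values
        taxon = clr.columns[0]
        sel = _selection(clr.columns, [taxon])
        mrs = build_mrs(clr, sel, {taxon: 0.8})
        assert np.allclose(mrs.score.to_numpy(), _zscore(clr[taxon]))

    def test_weight_rescaling_leaves_zscore_unchanged(self, small_sim):
        clr = small_sim["clr"].values
        taxa = list(clr.columns[:3])
        sel = _selection(clr.columns, taxa)
        w = {taxa[0]: 0.5, taxa[1]: -0.5, taxa[2]: 0.2}
        w2 = {t: 2 * v for t, v in w.items()}
        a = build_mrs(clr, sel, w)
        b = build_mrs(clr, sel, w2)
        assert np.allclose(a.score.to_numpy(), b.score.to_numpy())

    def test_hand_dot_products_on_three_sample_fixture(self):
        clr = pd.DataFrame(
            [[1.0, -1.0], [0.5, -0.5], [-1.5, 1.5]],
            index=["s1", "s2", "s3"], columns=["A", "B"])
        sel = _selection(["A", "B"], ["A", "B"])
        mrs = build_mrs(clr, sel, {"A": 0.5, "B": -0.5})
        assert mrs.raw_score.to_numpy() == pytest.approx([1.0, 0.5, -1.5])
        assert mrs.score.mean() == pytest.approx(0.0, abs=1e-12)
        assert mrs.score.std(ddof=0) == pytest.approx(1.0)

    def test_empty_selection_rejected(self, small_sim):
        clr = small_sim["clr"].values
        sel = _selection(clr.columns, [])
        with pytest.raises(ValueError, match="no selected species"):
            build_mrs(clr, sel, {})

    def test_weights_from_association_table(self, small_sim):
        clr = small_sim["clr"].values
        assoc = pd.DataFrame({"beta_pooled": 0.3}, index=clr.columns)
        sel = _selection(clr.columns, list(clr.columns[:2]))
        mrs = build_mrs(clr, sel, assoc)
        assert set(mrs.weights) == set(clr.columns[:2])


class TestCoxMrs:
    def test_strong_synthetic_effect_detected(self, small_sim):
        clr, meta = small_sim["clr"].values, small_sim["metadata"]
        truth = small_sim["truth"]
        causal = [t for t in truth.causal_taxa if t in clr.columns]
        sel = _selection(clr.columns, causal)
        mrs = build_mrs(clr, sel, truth.beta_true)
        pooled, per_cohort = cox_mrs(mrs, meta, "os")
        assert pooled.hr > 1.5
        assert pooled.p_meta < 1e-4
        assert set(per_cohort) == {"cohort1", "cohort2"}

    def test_combined_fit_with_cohort_indicator(self, small_sim):
        clr, meta = small_sim["clr"].values, small_sim["metadata"]
        truth = small_sim["truth"]
        causal = [t for t in truth.causal_taxa if t in clr.columns]
        mrs = build_mrs(clr, _selection(clr.columns, causal),
                        truth.beta_true)
        fit = cox_mrs(mrs, meta, "os", per_cohort=False)
        assert fit.converged and fit.hr > 1.5

    def test_permuted_mrs_is_null(self, small_sim, rng):
        clr, meta = small_sim["clr"].values, small_sim["metadata"]
        truth = small_sim["truth"]
        causal = [t for t in truth.causal_taxa if t in clr.columns]
        mrs = build_mrs(clr, _selection(clr.columns, causal),
                        truth.beta_true)
        pvals = []
        for _ in range(20):
            shuffled = MRSVector(
                pd.Series(rng.permutation(mrs.score.to_numpy()),
                          index=mrs.score.index),
                mrs.raw_score, mrs.weights, mrs.outcome_tag)
            pooled, _ = cox_mrs(shuffled, meta, "os")
            pvals.append(pooled.p_meta)
        assert np.mean(np.array(pvals) < 0.05) <= 0.25


class TestKaplanMeierLogrank:
    def test_no_censoring_steps_through_empirical_survival(self):
        meta = pd.DataFrame({
            "os_time": [1.0, 2.0, 3.0, 4.0], "os_event": [1, 1, 1, 1],
            "cohort": "c1"}, index=["a", "b", "c", "d"])
        score = pd.Series(_zscore([1.0, 2.0, -1.0, -2.0]),
                          index=meta.index)
        mrs = MRSVector(score, score, {"x": 1.0}, "Mortality")
        km = km_logrank(mrs, meta, "os")
        low = km.curves[km.curves["group"] == "low"]
        assert low["survival"].to_numpy() == pytest.approx([1.0, 0.5, 0.0])

    def test_hand_logrank_example_chi2(self):
        # A events at 1,2; B events at 3,4: chi2 = (2-5/6)^2 / (1/4+2/9)
        meta = pd.DataFrame({
            "os_time": [1.0, 2.0, 3.0, 4.0], "os_event": [1, 1, 1, 1],
            "cohort": "c1"}, index=["a1", "a2", "b1", "b2"])
        score = pd.Series(_zscore([2.0, 1.0, -1.0, -2.0]),
                          index=meta.index)  # high risk = early deaths
        mrs = MRSVector(score, score, {"x": 1.0}, "Mortality")
        km = km_logrank(mrs, meta, "os")
        o_minus_e = 2 - (2 / 4 + 1 / 3)
        var = (1 * 2 * 2 * 3) / (16 * 3) + (1 * 1 * 2 * 2) / (9 * 2)
        assert km.logrank_chi2 == pytest.approx(o_minus_e**2 / var)
        assert km.logrank_chi2 == pytest.approx(2.88, abs=0.01)

    def test_identical_groups_chi2_zero(self):
        times = [1.0, 2.0, 3.0]
        meta = pd.DataFrame({
            "os_time": times * 2, "os_event": [1, 1, 0] * 2,
            "cohort": "c1"}, index=[f"s{i}" for i in range(6)])
        score = pd.Series(_zscore([1, 1, 1, -1, -1, -1]), index=meta.index)
        mrs = MRSVector(score, score, {"x": 1.0}, "Mortality")
        km = km_logrank(mrs, meta, "os")
        assert km.logrank_chi2 == pytest.approx(0.0, abs=1e-9)
        assert km.logrank_p == pytest.approx(1.0)

    def test_curves_monotone_and_median_flagging(self, small_sim):
        clr, meta = small_sim["clr"].values, small_sim["metadata"]
        truth = small_sim["truth"]
        causal = [t for t in truth.causal_taxa if t in clr.columns]
        mrs = build_mrs(clr, _selection(clr.columns, causal),
                        truth.beta_true)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", UserWarning)
            km = km_logrank(mrs, meta, "os")
        for g, grp in km.curves.groupby("group"):
            surv = grp["survival"].to_numpy()
            assert (np.diff(surv) <= 1e-12).all()
            assert surv[0] == pytest.approx(1.0)
        # low-risk group may never reach S<=0.5 (flagged NaN median)
        low = km.median_survival["low"]
        assert np.isnan(low) or km.median_survival["high"] < low
        assert km.logrank_p < 0.01

    def test_all_censored_group_flagged(self):
        meta = pd.DataFrame({
            "os_time": [1.0, 2.0, 3.0, 4.0], "os_event": [1, 1, 0, 0],
            "cohort": "c1"}, index=list("abcd"))
        score = pd.Series(_zscore([2.0, 1.0, -1.0, -2.0]), index=meta.index)
        mrs = MRSVector(score, score, {"x": 1.0}, "Mortality")
        with pytest.warns(UserWarning, match="median survival undefined"):
            km = km_logrank(mrs, meta, "os")
        assert np.isnan(km.median_survival["low"])


class TestStratifiedRerun:
    def test_single_level_equals_unstratified(self, small_sim):
        clr, meta = small_sim["clr"].values, small_sim["metadata"]
        truth = small_sim["truth"]
        causal = [t for t in truth.causal_taxa if t in clr.columns]
        mrs = build_mrs(clr, _selection(clr.columns, causal),
                        truth.beta_true)
        meta1 = meta.copy()
        meta1["all"] = "everyone"
        tab = stratified_rerun(mrs, meta1, "os", "all")
        pooled, _ = cox_mrs(mrs, meta1, "os")
        assert len(tab) == 1
        assert tab["hr"].iloc[0] == pytest.approx(pooled.hr)

    def test_small_stratum_skipped_with_warning(self, small_sim):
        clr, meta = small_sim["clr"].values, small_sim["metadata"]
        truth = small_sim["truth"]
        causal = [t for t in truth.causal_taxa if t in clr.columns]
        mrs = build_mrs(clr, _selection(clr.columns, causal),
                        truth.beta_true)
        meta2 = meta.copy()
        meta2["grade"] = "G2"
        meta2.iloc[:1, meta2.columns.get_loc("grade")] = "G4"
        with pytest.warns(UserWarning, match="skipped"):
            tab = stratified_rerun(mrs, meta2, "os", "grade")
        assert list(tab["stratum"]) == ["grade=G2"]

    def test_homogeneous_effect_consistent_across_strata(self, small_sim):
        clr, meta = small_sim["clr"].values, small_sim["metadata"]
        truth = small_sim["truth"]
        causal = [t for t in truth.causal_taxa if t in clr.columns]
        mrs = build_mrs(clr, _selection(clr.columns, causal),
                        truth.beta_true)
        tab = stratified_rerun(mrs, meta, "os", "sex")
        assert len(tab) == 2
        # CIs of the two strata overlap (effect simulated homogeneous)
        lo = tab["ci_low"].max()
        hi = tab["ci_high"].min()
        assert lo < hi
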