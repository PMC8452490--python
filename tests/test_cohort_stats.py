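"""Cohort statistics: CV, PCA, batch variance, group tests, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import meapheno as mp
from meapheno.cohort_stats import bonferroni_adjust, pca_embed
from meapheno.errors import AnalysisError, ParameterError
from oracles import noncentral_t_power, wells_required_oracle


def _table(**cols):
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# coefficient of variation
# ---------------------------------------------------------------------------

def test_cv_hand_computed_and_constant_cases():
    t = _table(line_id=["L1"] * 3, MFR=[1.0, 2.0, 3.0], NBR=[2.0, 2.0, 2.0])
    cv = mp.parameter_cv(t, params=["MFR", "NBR"])
    assert cv.loc["MFR", "mean_cv_pct"] == pytest.approx(50.0)
    assert cv.loc["NBR", "mean_cv_pct"] == pytest.approx(0.0)
    assert not cv.loc["MFR", "stable"] is True or cv.loc["MFR", "mean_cv_pct"] <= 50
    assert cv.loc["NBR", "stable"]


def test_cv_recovers_generative_dispersion():
    """Wells drawn with 20% lognormal dispersion show ~20% CV per line."""
    rng = np.random.default_rng(5)
    rows = []
    for line in ("L1", "L2", "L3"):
        for _ in range(30):
            rows.append({"line_id": line, "MFR": 3.5 * rng.lognormal(0, 0.2)})
    cv = mp.parameter_cv(pd.DataFrame(rows), params=["MFR"])
    assert cv.loc["MFR", "mean_cv_pct"] == pytest.approx(20.2, abs=3.0)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_perfectly_correlated_columns_load_on_one_component(rng):
    x = rng.normal(0, 1, 200)
    t = _table(MFR=x, NBR=2 * x + 1)
    res = pca_embed(t, params=["MFR", "NBR"])
    assert res["variance_explained"][0] == pytest.approx(100.0, abs=1e-8)


def test_isotropic_data_splits_variance_evenly(rng):
    t = _table(MFR=rng.normal(0, 1, 1000), NBR=rng.normal(0, 1, 1000))
    res = pca_embed(t, params=["MFR", "NBR"])
    assert res["variance_explained"][0] == pytest.approx(50.0, abs=5.0)


def test_pca_reconstruction_is_lossless(rng):
    cols = {p: rng.normal(0, rng.uniform(0.5, 3), 40) for p in ("a", "b", "c", "d")}
    t = pd.DataFrame(cols)
    res = pca_embed(t, params=list(cols))
    Z = res["scores"].to_numpy() @ res["loadings"].to_numpy().T
    X = Z * res["sd"] + res["mean"]
    np.testing.assert_allclose(X, t.to_numpy(), rtol=1e-8, atol=1e-8)


def test_pca_sign_convention_fixed(rng):
    t = _table(a=rng.normal(0, 1, 50), b=rng.normal(0, 2, 50))
    res = pca_embed(t, params=["a", "b"])
    L = res["loadings"].to_numpy()
    for k in range(L.shape[1]):
        assert L[np.argmax(np.abs(L[:, k])), k] > 0


def test_pca_needs_enough_data():
    with pytest.raises(AnalysisError):
        pca_embed(_table(a=[1.0], b=[2.0]), params=["a", "b"])


# ---------------------------------------------------------------------------
# batch variance decomposition
# ---------------------------------------------------------------------------

def test_r2_matches_analytic_variance_ratio(rng):
    """Two batches, between-mean gap 2, within-SD 1: R^2 -> 1/(1+1) = 0.5."""
    n = 4000
    y = np.r_[rng.normal(0, 1, n), rng.normal(2, 1, n)]
    t = _table(MFR=y, mea_batch=["A"] * n + ["B"] * n)
    res = mp.variance_explained_by_batch(t, "mea_batch", params=["MFR"])
    assert res["per_parameter"].loc["MFR", "r2"] == pytest.approx(0.5, abs=0.03)
    assert res["combined_pct"] == pytest.approx(50.0, abs=3.0)


def test_shuffled_factor_explains_almost_nothing(rng):
    n = 400
    t = _table(MFR=rng.normal(0, 1, n),
               mea_batch=rng.permutation(np.repeat(list("ABCD"), n // 4)))
    res = mp.variance_explained_by_batch(t, "mea_batch", params=["MFR"])
    assert res["combined_pct"] < 5.0  # null expectation ~ (levels-1)/(n-1)


def test_single_level_factor_is_degenerate(rng):
    t = _table(MFR=rng.normal(0, 1, 20), mea_batch=["A"] * 20)
    with pytest.warns(UserWarning, match="single level"):
        res = mp.variance_explained_by_batch(t, "mea_batch", params=["MFR"])
    assert res["per_parameter"].loc["MFR", "r2"] == 0.0
    assert res["combined_pct"] == 0.0


def test_r2_bounded(rng):
    t = _table(MFR=rng.normal(0, 1, 60), BD=rng.normal(1, 2, 60),
               mea_batch=np.repeat(list("ABC"), 20))
    res = mp.variance_explained_by_batch(t, "mea_batch", params=["MFR", "BD"])
    r2 = res["per_parameter"]["r2"]
    assert ((r2 >= 0) & (r2 <= 1)).all()


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def test_identical_groups_are_never_significant(rng):
    x = rng.normal(0, 1, 12)
    t = pd.DataFrame({
        "g": ["a"] * 12 + ["b"] * 12,
        "MFR": np.r_[x, x], "NBR": np.r_[x, x],
    })
    res = mp.group_compare(t, "g", params=["MFR", "NBR"])
    assert (res["p_adj"] >= 0.9).all()


def test_bonferroni_definition():
    assert bonferroni_adjust(0.01, 17) == pytest.approx(0.17)
    assert bonferroni_adjust(0.2, 17) == 1.0


def test_two_sd_shift_detected_reliably_and_power_matches_oracle():
    """A 2-SD mean shift at n = 12 is detected in >= 95% of seeds (single
    comparison), and the rejection rate under a 17-test Bonferroni family
    matches the noncentral-t oracle within Monte-Carlo error."""
    n_seeds, hits_raw, hits_b17 = 150, 0, 0
    for seed in range(n_seeds):
        r = np.random.default_rng(seed)
        t = pd.DataFrame({"g": ["a"] * 12 + ["b"] * 12,
                          "MFR": np.r_[r.normal(0, 1, 12), r.normal(2, 1, 12)]})
        res = mp.group_compare(t, "g", params=["MFR"])
        hits_raw += bool(res["p_adj"].iloc[0] < 0.05)
        hits_b17 += bool(res["p"].iloc[0] * 17 < 0.05)
    assert hits_raw / n_seeds >= 0.95
    oracle = noncentral_t_power(2.0, 12, alpha=0.05 / 17)
    mc_sd = np.sqrt(oracle * (1 - oracle) / n_seeds)
    # rank test trades a little efficiency against the t oracle
    assert hits_b17 / n_seeds == pytest.approx(oracle, abs=3 * mc_sd + 0.05)


def test_multi_group_uses_stated_tests(rng):
    t = pd.DataFrame({
        "g": np.repeat(["a", "b", "c"], 15),
        "MFR": np.r_[rng.normal(0, 1, 15), rng.normal(0, 1, 15), rng.normal(3, 1, 15)],
    })
    res_kw = mp.group_compare(t, "g", params=["MFR"], correction="dunn")
    assert set(res_kw["test"]) == {"kruskal-wallis", "dunn"}
    shifted = res_kw[res_kw["comparison"].str.contains("c")]
    assert (shifted["p_adj"] < 0.05).any()
    res_t = mp.group_compare(t, "g", params=["MFR"], correction="tukey")
    assert set(res_t["test"]) == {"anova", "tukey"}
    assert (res_t[res_t["comparison"] == "a|b"]["p_adj"] > 0.05).all()


def test_dunn_identical_groups_not_significant(rng):
    x = rng.normal(0, 1, 10)
    t = pd.DataFrame({"g": np.repeat(["a", "b", "c"], 10), "MFR": np.r_[x, x, x]})
    res = mp.group_compare(t, "g", params=["MFR"], correction="dunn")
    pairs = res[res["test"] == "dunn"]
    assert (pairs["p_adj"] >= 0.9).all()


# ---------------------------------------------------------------------------
# burst-shape bin tests
# ---------------------------------------------------------------------------

def test_identical_shape_sets_have_no_significant_bins(rng):
    shapes = rng.normal(1.0, 0.05, (10, 50))
    res = mp.burst_shape_compare(shapes, shapes + rng.normal(0, 1e-6, (10, 50)))
    assert not res["significant"].any()


def test_late_phase_difference_localized(rng):
    a = rng.normal(1.0, 0.08, (15, 60))
    b = rng.normal(1.0, 0.08, (15, 60))
    b[:, 40:] += 1.0  # late-phase divergence only
    res = mp.burst_shape_compare(a, b, bin_width=0.005)
    assert res["significant"][40:].all()
    assert not res["significant"][:30].any()


def test_mismatched_bin_grids_rejected(rng):
    with pytest.raises(ParameterError):
        mp.burst_shape_compare(rng.normal(size=(5, 40)), rng.normal(size=(5, 50)))


# ---------------------------------------------------------------------------
# power planning
# ---------------------------------------------------------------------------

def test_wells_required_matches_noncentral_t_oracle():
    for d in (0.8, 1.0, 1.21, 1.5, 2.5):
        assert mp.wells_required(d) == wells_required_oracle(d)
    assert mp.wells_required(1.21) == 12


def test_wells_required_limits_and_monotonicity():
    assert mp.wells_required(1e6) == 2
    ns = [mp.wells_required(d) for d in (0.5, 0.8, 1.2, 2.0)]
    assert all(a >= b for a, b in zip(ns, ns[1:]))
    assert mp.wells_required(1.0, power=0.9) >= mp.wells_required(1.0, power=0.8)
    with pytest.raises(ParameterError):
        mp.wells_required(0.0)


def test_post_hoc_power_null_equals_alpha(rng):
    x = rng.normal(0, 1, 30)
    t = pd.DataFrame({"g": ["a"] * 30 + ["b"] * 30, "MFR": np.r_[x, x]})
    assert mp.post_hoc_power(t, "g", "MFR") == pytest.approx(0.05, abs=0.01)


def test_post_hoc_power_large_effect_near_one(rng):
    t = pd.DataFrame({"g": ["a"] * 12 + ["b"] * 12,
                      "MFR": np.r_[rng.normal(0, 1, 12), rng.normal(4, 1, 12)]})
    assert mp.post_hoc_power(t, "g", "MFR") > 0.95
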