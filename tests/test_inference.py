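"""Weighted t-tests, Spearman screen, weighted logistic ORs, driver."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from holcbirths.inference import (MODEL_COVARIATES, balance_table,
                                  descriptive_table, fit_outcome_model,
                                  prevalence_by_grade, run_full_analysis,
                                  spearman_screen, weighted_t_test)


# --------------------------------------------------------------------------
# weighted t-test
# --------------------------------------------------------------------------

def test_unit_weights_reduce_to_welch():
    rng = np.random.default_rng(0)
    a, b = rng.normal(0, 1, 40), rng.normal(0.5, 2, 55)
    ours = weighted_t_test(a, b)
    ref = stats.ttest_ind(a, b, equal_var=False)
    assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)
    assert ours.diff == pytest.approx(a.mean() - b.mean())


def test_identical_arms_give_zero_difference():
    x = np.arange(10.0)
    t = weighted_t_test(x, x)
    assert t.diff == 0
    assert t.p == pytest.approx(1.0)


def test_weight_rescaling_invariance():
    rng = np.random.default_rng(1)
    a, b = rng.normal(size=30), rng.normal(size=30)
    wa, wb = rng.uniform(0.5, 2, 30), rng.uniform(0.5, 2, 30)
    t1 = weighted_t_test(a, b, wa, wb)
    t2 = weighted_t_test(a, b, 2 * wa, 2 * wb)
    assert t1.p == pytest.approx(t2.p, rel=1e-12)
    assert t1.se == pytest.approx(t2.se, rel=1e-12)


def test_zero_weight_arm_errors():
    with pytest.raises(ValueError, match="zero total weight"):
        weighted_t_test([1, 2], [3, 4], [0, 0], [1, 1])


# --------------------------------------------------------------------------
# Spearman screen
# --------------------------------------------------------------------------

def test_spearman_self_and_monotone_transform():
    rng = np.random.default_rng(2)
    x = rng.normal(size=50)
    df = pd.DataFrame({"x": x, "expx": np.exp(x),
                       "y": rng.normal(size=50)})
    mat, flagged, retained = spearman_screen(df, threshold=0.7)
    assert mat.loc["x", "x"] == pytest.approx(1.0)
    assert mat.loc["x", "expx"] == pytest.approx(1.0)
    assert ("x", "expx", pytest.approx(1.0)) in [
        (a, b, pytest.approx(r)) for a, b, r in flagged] or flagged
    assert retained == MODEL_COVARIATES


def test_spearman_matches_scipy():
    rng = np.random.default_rng(3)
    df = pd.DataFrame(rng.normal(size=(20, 5)),
                      columns=list("abcde"))
    mat, _, _ = spearman_screen(df)
    expect = stats.spearmanr(df.to_numpy()).statistic
    assert np.allclose(mat.to_numpy(), expect, atol=1e-12)


def test_constant_column_gives_missing_rho():
    df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 2, 2, 2],
                       "c": [4.0, 3, 2, 1]})
    mat, _, _ = spearman_screen(df)
    assert np.isnan(mat.loc["a", "b"])
    assert mat.loc["a", "c"] == pytest.approx(-1.0)


# --------------------------------------------------------------------------
# weighted logistic model
# --------------------------------------------------------------------------

def _toy_cohort(rng, n=4000, p_t=0.3, or_true=2.0, base=0.1):
    t = (rng.random(n) < p_t).astype(float)
    logit0 = np.log(base / (1 - base))
    p = 1 / (1 + np.exp(-(logit0 + np.log(or_true) * t)))
    y = (rng.random(n) < p).astype(float)
    return pd.DataFrame({
        "grade": np.where(t == 1, "D", "C"),
        "outcome": y,
        "polygon_id": [f"g{i % 50}" for i in range(n)]})


def test_unadjusted_or_equals_cross_product_ratio():
    rng = np.random.default_rng(4)
    df = _toy_cohort(rng)
    w = pd.Series(1.0, index=df.index)
    res = fit_outcome_model(df, w, "outcome", "D", covariates=[],
                            cov_type="nonrobust")
    t, y = df["grade"] == "D", df["outcome"] == 1
    a, b = (t & y).sum(), (t & ~y).sum()
    c, d = (~t & y).sum(), (~t & ~y).sum()
    assert res.odds_ratio == pytest.approx(a * d / (b * c), rel=1e-6)


def test_half_weight_duplication_reproduces_estimate():
    rng = np.random.default_rng(5)
    df = _toy_cohort(rng, n=2000)
    w = pd.Series(1.0, index=df.index)
    res1 = fit_outcome_model(df, w, "outcome", "D", covariates=[],
                             cov_type="nonrobust")
    dup = pd.concat([df, df], ignore_index=True)
    w2 = pd.Series(0.5, index=dup.index)
    res2 = fit_outcome_model(dup, w2, "outcome", "D", covariates=[],
                             cov_type="nonrobust")
    assert res2.odds_ratio == pytest.approx(res1.odds_ratio, rel=1e-9)


def test_single_arm_errors():
    df = pd.DataFrame({"grade": ["C"] * 10, "outcome": [0, 1] * 5,
                       "polygon_id": ["p"] * 10})
    with pytest.raises(ValueError, match="both exposure levels"):
        fit_outcome_model(df, pd.Series(1.0, index=df.index), "outcome",
                          "D", covariates=[])


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def analysis(medium_study):
    cfg, data = medium_study
    return data, run_full_analysis(data.metrics, data.grades, data.cohort,
                                   seed=1, strata=("metro",))


def test_strata_partition_cohort(analysis):
    data, res = analysis
    df = res.results
    for (contrast, outcome), grp in df.groupby(["contrast", "outcome"]):
        all_n = grp.loc[grp["stratum"] == "all", "n_births"]
        strat = grp[grp["stratum"].str.startswith("metro:")]
        if len(all_n) == 1 and len(strat) == 3:
            assert strat["n_births"].sum() == all_n.iloc[0]


def test_results_have_valid_cis(analysis):
    _, res = analysis
    df = res.results
    assert (df["ci_low"] <= df["odds_ratio"]).all()
    assert (df["odds_ratio"] <= df["ci_high"]).all()
    assert (df["ci_low"] > 0).all()


def test_balance_tables_cover_seven_covariates(analysis):
    _, res = analysis
    for label, bal in res.balance.items():
        assert len(bal) == 7
        ok = bal["pre_ci_low"].notna()
        assert (bal.loc[ok, "pre_ci_low"] <= bal.loc[ok, "pre_diff"]).all()
        assert (bal.loc[ok, "pre_diff"] <= bal.loc[ok, "pre_ci_high"]).all()


def test_descriptive_and_prevalence_tables(analysis):
    data, res = analysis
    desc = res.descriptive
    assert {"race", "education", "payer", "maternal_age"} <= \
        set(desc["variable"])
    # explicit unknown levels are kept in descriptive tables
    assert "unknown" in set(desc.loc[desc["variable"] == "education",
                                     "level"])
    prev = res.prevalence
    assert prev["n"].sum() == len(data.cohort)
    assert ((prev["preterm"] >= 0) & (prev["preterm"] <= 100)).all()


def test_no_trim_uses_more_neighborhoods(medium_study):
    cfg, data = medium_study
    from holcbirths.inference import run_contrast
    _, b_trim, m_trim = run_contrast(data.metrics, data.grades, "D_vs_C",
                                     seed=1, trim=True)
    _, b_full, m_full = run_contrast(data.metrics, data.grades, "D_vs_C",
                                     seed=1, trim=False)
    assert len(b_full.retained) >= len(b_trim.retained)
    assert set(b_trim.retained) <= set(b_full.retained)


def test_tables_regenerate_identically(medium_study):
    cfg, data = medium_study
    r1 = run_full_analysis(data.metrics, data.grades, data.cohort, seed=4,
                           outcomes=("preterm",), strata=())
    r2 = run_full_analysis(data.metrics, data.grades, data.cohort, seed=4,
                           outcomes=("preterm",), strata=())
    pd.testing.assert_frame_equal(r1.results, r2.results)
    pd.testing.assert_frame_equal(r1.prevalence, r2.prevalence)
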