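"""Propensity ensemble, support trimming and optimal full matching."""

import numpy as np
import pandas as pd
import pytest

from holcbirths.matching import (CONTRASTS, ContrastSpec, MAHALANOBIS_COVARIATES,
                                 PropensityFit, assign_birth_weights,
                                 fit_propensity, full_match, no_trim,
                                 trim_support)

from _oracles import (brute_force_full_match_cost, mahalanobis_oracle,
                      random_match_instance)


def _toy_fit(ps, treated, ids=None):
    ids = ids or [f"u{i}" for i in range(len(ps))]
    return PropensityFit(
        contrast=ContrastSpec("D_vs_C"),
        propensity=pd.Series(ps, index=ids, dtype=float),
        treated=pd.Series(treated, index=ids, dtype=bool),
        oof_predictions=pd.DataFrame(index=ids),
        stack_weights=pd.Series(dtype=float),
        folds=pd.Series(0, index=ids))


def test_only_adjacent_contrasts_permitted():
    for ok in CONTRASTS:
        ContrastSpec(ok)
    with pytest.raises(ValueError):
        ContrastSpec("D_vs_A")


# --------------------------------------------------------------------------
# propensity ensemble
# --------------------------------------------------------------------------

def test_constant_covariates_give_constant_propensity(medium_study):
    _, data = medium_study
    metrics = data.metrics.copy()
    for c in metrics.columns:
        metrics[c] = 1.0
    fit = fit_propensity(metrics, data.grades, "D_vs_C", seed=0)
    frac = fit.treated.mean()
    assert np.allclose(fit.propensity, frac, atol=0.02)


def test_perfect_binary_covariate_beats_mean_model():
    rng = np.random.default_rng(0)
    n = 60
    ids = [f"u{i}" for i in range(n)]
    treated = np.array([True] * 30 + [False] * 30)
    metrics = pd.DataFrame({
        "flag": treated.astype(float),
        "noise": rng.normal(size=n)}, index=ids)
    grades = pd.Series(np.where(treated, "D", "C"), index=ids)
    fit = fit_propensity(metrics, grades, "D_vs_C", seed=1,
                         covariates=["flag", "noise"])
    ps = fit.propensity

    def logloss(p, y):
        p = np.clip(p, 1e-6, 1 - 1e-6)
        return -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))

    y = fit.treated.to_numpy().astype(float)
    assert logloss(ps.to_numpy(), y) < logloss(np.full(n, 0.5), y)
    assert ps[fit.treated].min() > 0.9
    assert ps[~fit.treated].max() < 0.1


def test_stack_weights_on_simplex(medium_study):
    _, data = medium_study
    for label in ("C_vs_B", "D_vs_C"):
        fit = fit_propensity(data.metrics, data.grades, label, seed=3)
        w = fit.stack_weights
        assert (w >= 0).all()
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert ((fit.propensity > 0) & (fit.propensity < 1)).all()


def test_missing_covariates_error(medium_study):
    _, data = medium_study
    metrics = data.metrics.copy()
    metrics.iloc[0, metrics.columns.get_loc("pct_radio")] = np.nan
    with pytest.raises(ValueError, match="missing covariate"):
        fit_propensity(metrics, data.grades, "D_vs_C")


# --------------------------------------------------------------------------
# trimming
# --------------------------------------------------------------------------

def test_identical_arm_distributions_trim_about_two_percent():
    rng = np.random.default_rng(5)
    n = 500
    ps = rng.uniform(0.1, 0.9, size=2 * n)
    fit = _toy_fit(ps, [True] * n + [False] * n)
    bounds = trim_support(fit)
    frac = 1 - len(bounds.retained) / (2 * n)
    assert 0.005 <= frac <= 0.04  # ~1% from each tail


def test_equal_propensities_trim_nothing():
    fit = _toy_fit([0.4] * 10, [True] * 5 + [False] * 5)
    bounds = trim_support(fit)
    assert len(bounds.retained) == 10
    assert len(bounds.trimmed) == 0


def test_trim_order_invariance():
    rng = np.random.default_rng(6)
    ps = rng.uniform(0, 1, 40)
    treated = rng.random(40) < 0.5
    treated[:2] = [True, False]
    fit = _toy_fit(ps, treated)
    perm = rng.permutation(40)
    fit2 = _toy_fit(ps[perm], treated[perm],
                    ids=[f"u{i}" for i in perm])
    b1, b2 = trim_support(fit), trim_support(fit2)
    assert set(b1.retained) == set(b2.retained)
    assert b1.lower == pytest.approx(b2.lower)


def test_monotone_trimming():
    """Shrinking the support window never adds neighborhoods."""
    rng = np.random.default_rng(7)
    ps = rng.uniform(0, 1, 60)
    fit = _toy_fit(ps, rng.random(60) < 0.5)
    bounds = trim_support(fit)
    inner = (fit.propensity >= bounds.lower + 0.05) & \
        (fit.propensity <= bounds.upper - 0.05)
    assert set(fit.propensity.index[inner]) <= set(bounds.retained)


# --------------------------------------------------------------------------
# full matching
# --------------------------------------------------------------------------

def test_degenerate_identical_units_all_weight_one():
    """2 treated + 2 controls, identical scores and covariates."""
    fit = _toy_fit([0.5] * 4, [True, True, False, False],
                   ids=["t1", "t2", "c1", "c2"])
    metrics = pd.DataFrame({c: [1.0] * 4 for c in MAHALANOBIS_COVARIATES},
                           index=["t1", "t2", "c1", "c2"])
    m = full_match(fit, no_trim(fit), metrics)
    assert m.total_distance == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(m.weights, 1.0)
    assert len(m.discarded) == 0
    for sub in m.subclasses:
        assert len(sub["treated"]) >= 1 and len(sub["control"]) >= 1


def test_full_match_equals_brute_force_small():
    """3+3 and random tiny instances match exhaustive enumeration."""
    rng = np.random.default_rng(11)
    for _ in range(25):
        fit, metrics = random_match_instance(rng)
        bounds = no_trim(fit)
        ps = fit.propensity
        caliper = 0.2 * np.std(ps.to_numpy(), ddof=1)
        t_ids = list(ps.index[fit.treated])
        c_ids = list(ps.index[~fit.treated])
        dist = mahalanobis_oracle(metrics.loc[t_ids].to_numpy(),
                                  metrics.loc[c_ids].to_numpy())
        expect, n_kept = brute_force_full_match_cost(
            ps[t_ids].to_numpy(), ps[c_ids].to_numpy(), dist, caliper)
        if not np.isfinite(expect):
            with pytest.raises(ValueError):
                full_match(fit, bounds, metrics)
            continue
        m = full_match(fit, bounds, metrics)
        assert m.total_distance == pytest.approx(expect, abs=1e-4)
        assert len(m.weights) == n_kept


def test_caliper_discards_far_control():
    """A control beyond the caliper from every treated unit gets weight 0
    and is logged."""
    ps = [0.50, 0.52, 0.51, 0.95]
    fit = _toy_fit(ps, [True, True, False, False],
                   ids=["t1", "t2", "c1", "far"])
    metrics = pd.DataFrame({c: [0.0, 0.1, 0.05, 3.0]
                            for c in MAHALANOBIS_COVARIATES},
                           index=["t1", "t2", "c1", "far"])
    m = full_match(fit, no_trim(fit), metrics)
    assert "far" in set(m.discarded["polygon_id"])
    assert "far" not in m.weights.index


def test_weight_invariants(medium_study):
    cfg, data = medium_study
    fit = fit_propensity(data.metrics, data.grades, "D_vs_C", seed=2)
    bounds = trim_support(fit)
    m = full_match(fit, bounds, data.metrics)
    tr = fit.treated
    t_w = [m.weights[i] for i in m.weights.index if tr[i]]
    assert np.allclose(t_w, 1.0)
    for sub in m.subclasses:
        n_t = len(sub["treated"])
        c_sum = sum(n_t / len(sub["control"]) for _ in sub["control"])
        assert c_sum == pytest.approx(n_t)
        assert (len(sub["treated"]) == 1) or (len(sub["control"]) == 1)
        ps = fit.propensity
        for t in sub["treated"]:
            for c in sub["control"]:
                assert abs(ps[t] - ps[c]) <= m.caliper + 1e-12


# --------------------------------------------------------------------------
# birth weights
# --------------------------------------------------------------------------

def test_birth_weight_propagation_and_conservation(medium_study):
    cfg, data = medium_study
    fit = fit_propensity(data.metrics, data.grades, "D_vs_C", seed=2)
    m = full_match(fit, trim_support(fit), data.metrics)
    cohort = data.cohort
    w = assign_birth_weights(m, cohort, normalize=False)
    counts = cohort.groupby("polygon_id").size()
    expect = sum(m.weights.get(pid, 0.0) * n for pid, n in counts.items())
    assert w.sum() == pytest.approx(expect)
    # all births in one matched neighborhood share its weight
    pid = m.weights.index[0]
    in_pid = cohort["polygon_id"] == pid
    if in_pid.any():
        assert np.allclose(w[in_pid], m.weights[pid])
    # unmatched neighborhoods get zero
    assert (w[~cohort["polygon_id"].isin(m.weights.index)] == 0).all()
    # permuting birth order leaves weights unchanged
    perm = cohort.sample(frac=1.0, random_state=3)
    w_perm = assign_birth_weights(m, perm, normalize=False)
    assert np.allclose(w_perm.to_numpy(),
                       w.loc[perm.index].to_numpy())


def test_normalized_weights_mean_one(medium_study):
    cfg, data = medium_study
    fit = fit_propensity(data.metrics, data.grades, "C_vs_B", seed=2)
    m = full_match(fit, trim_support(fit), data.metrics)
    w = assign_birth_weights(m, data.cohort, normalize=True)
    assert w[w > 0].mean() == pytest.approx(1.0)
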