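"""Statistical outputs: balance tests, collinearity screen, weighted
adjusted logistic odds ratios, and descriptive tables.

The outcome models are weighted logistic regressions of each binary
outcome on the worse-grade indicator plus four areal-weighted 1940
covariates (median home value, percent employed, percent radio ownership,
percent non-White), weighted by the full-matching birth weights.
Confidence intervals use cluster-robust (sandwich) standard errors
clustered on neighborhood by default, since births sharing a neighborhood
share exposure and weight; model-based Wald intervals are available via
``cov_type="nonrobust"``.  A sensitivity variant additionally adjusts for
maternal age, parity and birth year.  No multiple-testing adjustment is
applied; the report records the number of tests performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .matching import (CONTRASTS, ContrastSpec, assign_birth_weights,
                       fit_propensity, full_match, no_trim, trim_support)
from .types import ALL_OUTCOMES

#: The four model covariates fixed by design (the screen is a diagnostic).
MODEL_COVARIATES = ["median_home_value", "pct_employed", "pct_radio",
                    "pct_nonwhite"]

#: Sensitivity-model maternal additions.
SENSITIVITY_COVARIATES = ["maternal_age", "parity", "birth_year"]

#: The seven balance-table covariates.
BALANCE_COVARIATES = ["median_home_value", "pct_major_repairs",
                      "pct_hs_educated", "pct_nonwhite", "pct_employed",
                      "pct_radio", "pct_refrigerator"]


# --------------------------------------------------------------------------
# weighted t-test
# --------------------------------------------------------------------------

@dataclass
class WeightedTTest:
    diff: float
    ci_low: float
    ci_high: float
    p: float
    df: float
    se: float


def weighted_t_test(x_a, x_b, w_a=None, w_b=None,
                    alpha: float = 0.05) -> WeightedTTest:
    """Welch-type two-sample t-test with reliability weights.

    Means and unbiased variances use the weights; standard errors use the
    effective sample size ``(sum w)^2 / sum w^2`` with Welch-Satterthwaite
    degrees of freedom, so the test is invariant to rescaling all weights
    and reduces to the classical Welch test when every weight is one.
    """

    def arm(x, w):
        x = np.asarray(x, dtype=float)
        w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
        keep = (w > 0) & np.isfinite(x)
        x, w = x[keep], w[keep]
        v1, v2 = w.sum(), (w**2).sum()
        if v1 <= 0:
            raise ValueError("zero total weight in an arm")
        neff = v1**2 / v2
        if neff < 2:
            raise ValueError("fewer than 2 effective observations")
        mean = float(np.average(x, weights=w))
        var = float(np.sum(w * (x - mean)**2) / (v1 - v2 / v1))
        return mean, var, neff

    ma, va, na = arm(x_a, w_a)
    mb, vb, nb = arm(x_b, w_b)
    diff = ma - mb
    se2a, se2b = va / na, vb / nb
    se = float(np.sqrt(se2a + se2b))
    if se == 0:
        return WeightedTTest(diff, diff, diff, 1.0, na + nb - 2, 0.0)
    df = (se2a + se2b)**2 / (se2a**2 / (na - 1) + se2b**2 / (nb - 1))
    tstat = diff / se
    p = float(2 * st.t.sf(abs(tstat), df))
    tcrit = st.t.ppf(1 - alpha / 2, df)
    return WeightedTTest(diff, diff - tcrit * se, diff + tcrit * se, p,
                         float(df), se)


# --------------------------------------------------------------------------
# Spearman collinearity screen
# --------------------------------------------------------------------------

def spearman_screen(metrics: pd.DataFrame, covariates=None,
                    threshold: float = 0.7):
    """Pairwise Spearman rho with average-rank ties.

    Returns ``(matrix, flagged_pairs, retained)``.  Constant columns give
    NaN correlations.  The retained list is the fixed four-covariate model
    set regardless of the screen, which serves as a diagnostic.
    """
    cols = list(covariates) if covariates is not None \
        else [c for c in metrics.columns if metrics[c].dtype.kind in "if"]
    if len(metrics) < 3:
        raise ValueError("need at least 3 neighborhoods")
    X = metrics[cols].to_numpy(dtype=float)
    ranks = st.rankdata(X, axis=0)  # average ranks on ties
    const = np.nanstd(X, axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.atleast_2d(rho)
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, np.where(const, np.nan, 1.0))
    mat = pd.DataFrame(rho, index=cols, columns=cols)
    flagged = [(a, b, float(mat.loc[a, b]))
               for i, a in enumerate(cols) for b in cols[i + 1:]
               if np.isfinite(mat.loc[a, b])
               and abs(mat.loc[a, b]) > threshold]
    return mat, flagged, list(MODEL_COVARIATES)


# --------------------------------------------------------------------------
# weighted outcome model
# --------------------------------------------------------------------------

@dataclass
class ContrastResult:
    contrast: str
    stratum: str
    outcome: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    n_births: int
    n_events: int
    covariates: list = field(default_factory=list)

    def row(self) -> dict:
        return {"contrast": self.contrast, "stratum": self.stratum,
                "outcome": self.outcome, "odds_ratio": self.odds_ratio,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "n_births": self.n_births, "n_events": self.n_events}


def _cr2_bse(X: np.ndarray, y: np.ndarray, w: np.ndarray, mu: np.ndarray,
             groups: np.ndarray) -> np.ndarray:
    """Bell-McCaffrey (CR2) cluster-robust standard errors for a weighted
    logistic fit.

    Each cluster's score is premultiplied by ``(I - H_cc)^{-1/2}`` on the
    working-weight scale, which undoes the downward bias of the plug-in
    sandwich when a few clusters carry most of the weight (exactly the
    full-matching regime).  Returns per-coefficient variances from both
    the empirical cluster meat and the analytic working-model
    independence meat (squared-weight), the latter being a lower bound on
    the cluster variance whenever within-cluster correlation is
    non-negative.  Uses low-rank identities so the cost is k x k per
    cluster.
    """
    omega = w * mu * (1 - mu)
    H = X.T @ (X * omega[:, None])
    H += 1e-10 * np.trace(H) / H.shape[0] * np.eye(H.shape[0])
    M = np.linalg.inv(H)
    M = (M + M.T) / 2
    lam_m, V_m = np.linalg.eigh(M)
    Mh = V_m * np.sqrt(np.clip(lam_m, 1e-300, None))  # symmetric sqrt
    meat = np.zeros_like(M)
    sq = np.sqrt(omega)
    order = np.argsort(groups, kind="stable")
    Xo, so, go = X[order], sq[order], groups[order]
    # v = Omega^{-1/2} w (y - mu): scores on the working-weight scale
    resid = (w * (y - mu))[order] / np.where(so > 0, so, 1.0)
    starts = np.r_[0, np.nonzero(go[1:] != go[:-1])[0] + 1, len(go)]
    k = X.shape[1]
    for a, b in zip(starts[:-1], starts[1:]):
        B = Xo[a:b] * so[a:b, None]           # n_c x k
        v = resid[a:b]                        # n_c
        BtB = B.T @ B
        Btv = B.T @ v
        S = Mh.T @ BtB @ Mh
        lam, V = np.linalg.eigh(S)
        lam = np.clip(lam, 0.0, 1.0 - 1e-8)
        h = np.where(lam > 1e-12,
                     (1.0 / np.sqrt(1.0 - lam) - 1.0) / np.maximum(lam,
                                                                   1e-12),
                     0.5)
        Hfun = Mh @ (V * h) @ V.T @ Mh.T      # M^{1/2} h(S) M^{1/2}
        s_adj = Btv + BtB @ (Hfun @ Btv)
        meat += np.outer(s_adj, s_adj)
    V_beta = M @ meat @ M
    # independence floor: exact score variance under the working model
    # with independent observations (sum_i w_i^2 v_i x x'); the empirical
    # cluster meat can fall below it by estimation noise alone, while any
    # non-negative within-cluster correlation can only push the true
    # variance above it
    meat_ind = X.T @ (X * (w**2 * mu * (1 - mu))[:, None])
    V_ind = M @ meat_ind @ M
    return np.diag(V_beta).copy(), np.diag(V_ind).copy()


def fit_outcome_model(cohort: pd.DataFrame, weights: pd.Series,
                      outcome: str, treated_grade: str,
                      covariates=MODEL_COVARIATES, extra_covariates=(),
                      cluster: str = "polygon_id",
                      cov_type: str = "cluster", label: str = "",
                      stratum: str = "all") -> ContrastResult:
    """Weighted logistic OR of ``outcome`` for the worse grade.

    ``cohort`` must carry the outcome flag, the grade column, the model
    covariates and the cluster key; births with zero weight or missing
    outcome are dropped.  The OR is ``exp`` of the worse-grade indicator
    coefficient with a 95% Wald interval from the requested covariance.

    With cluster-robust errors the interval uses a t quantile whose
    degrees of freedom are the effective number of clusters,
    ``(sum_c w_c)^2 / sum_c w_c^2`` over cluster weight totals, minus one:
    full matching concentrates weight on few neighborhoods and the normal
    quantile is anti-conservative in that regime.
    """
    covs = list(covariates) + list(extra_covariates)
    use = (weights > 0) & cohort[outcome].notna()
    for c in covs:
        use &= cohort[c].notna()
    df = cohort[use]
    w = np.asarray(weights[use], dtype=float)
    y = df[outcome].to_numpy(dtype=float)
    t = (df["grade"] == treated_grade).to_numpy(dtype=float)
    if t.sum() == 0 or t.sum() == len(t):
        raise ValueError("both exposure levels need positive weight")

    X = np.column_stack([np.ones(len(df)), t] +
                        [df[c].to_numpy(dtype=float) for c in covs])
    model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100)
    if not res.converged:
        raise RuntimeError(f"outcome model for {outcome!r} did not "
                           "converge within 100 iterations")
    beta = res.params[1]
    if not np.isfinite(beta) or abs(beta) > 15:
        raise RuntimeError(f"separation suspected for {outcome!r}")
    if cov_type == "cluster":
        v_emp, v_ind = _cr2_bse(X, y, w, np.asarray(res.fittedvalues),
                                df[cluster].to_numpy())
        cw = pd.Series(w).groupby(df[cluster].to_numpy()).sum()
        eff_g = float(cw.sum()**2 / (cw**2).sum())
        # trust the empirical cluster meat only when it exceeds the
        # analytic independence floor by more than its own chi-square
        # sampling noise; otherwise the floor is the better estimate
        if v_emp[1] > v_ind[1] * (1.0 + 2.0 * np.sqrt(2.0 / eff_g)):
            se = float(np.sqrt(v_emp[1]))
            z = st.t.ppf(0.975, max(eff_g - 1.0, 2.0))
        else:
            se = float(np.sqrt(v_ind[1]))
            z = st.norm.ppf(0.975)
    else:
        se = res.bse[1]
        z = st.norm.ppf(0.975)
    if not np.isfinite(se) or se > 50:
        raise RuntimeError(f"separation suspected for {outcome!r}")
    return ContrastResult(
        contrast=label, stratum=stratum, outcome=outcome,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        n_births=int(len(df)), n_events=int(np.nansum(y)),
        covariates=covs)


# --------------------------------------------------------------------------
# balance table
# --------------------------------------------------------------------------

def balance_table(metrics: pd.DataFrame, fit, match,
                  covariates=BALANCE_COVARIATES) -> pd.DataFrame:
    """Pre- vs post-match mean differences (treated minus control)."""
    tr = fit.treated
    nan = WeightedTTest(*[np.nan] * 6)
    rows = []
    for cov in covariates:
        x = metrics[cov]
        try:
            pre = weighted_t_test(x[tr.index[tr]], x[tr.index[~tr]])
        except ValueError:
            pre = nan
        wts = match.weights
        tm = [i for i in wts.index if tr.get(i, False)]
        cm = [i for i in wts.index if not tr.get(i, True)]
        try:
            post = weighted_t_test(x[tm], x[cm], wts[tm], wts[cm])
        except ValueError:
            post = nan
        rows.append({
            "covariate": cov,
            "pre_diff": pre.diff, "pre_ci_low": pre.ci_low,
            "pre_ci_high": pre.ci_high, "pre_p": pre.p,
            "post_diff": post.diff, "post_ci_low": post.ci_low,
            "post_ci_high": post.ci_high, "post_p": post.p,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# descriptive tables
# --------------------------------------------------------------------------

def descriptive_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Maternal characteristics by grade with chi-square / ANOVA p-values.

    Unknown covariate levels appear as explicit rows; they are only
    dropped from regressions, not from description.
    """
    grades = [g for g in ["A", "B", "C", "D", "NG"]
              if (cohort["grade"] == g).any()]
    rows = []
    for var in ["race", "education", "payer", "metro", "sex"]:
        tab = pd.crosstab(cohort[var], cohort["grade"])[grades]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = st.chi2_contingency(tab.to_numpy() + 0.0).pvalue \
                if tab.shape[0] > 1 else np.nan
        for level, counts in tab.iterrows():
            row = {"variable": var, "level": level, "p_value": p}
            for g in grades:
                n = int(counts[g])
                tot = int(tab[g].sum())
                row[f"{g}_n"] = n
                row[f"{g}_pct"] = 100.0 * n / tot if tot else np.nan
            rows.append(row)
    for var in ["maternal_age", "parity", "birth_year"]:
        groups = [cohort.loc[cohort["grade"] == g, var].dropna()
                  for g in grades]
        p = st.f_oneway(*groups).pvalue if len(groups) > 1 else np.nan
        row = {"variable": var, "level": "mean (sd)", "p_value": float(p)}
        for g, vals in zip(grades, groups):
            row[f"{g}_n"] = float(vals.mean())
            row[f"{g}_pct"] = float(vals.std(ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)


def prevalence_by_grade(cohort: pd.DataFrame,
                        outcomes=ALL_OUTCOMES) -> pd.DataFrame:
    """Crude outcome prevalence (%) per grade."""
    out = []
    for g, sub in cohort.groupby("grade"):
        row = {"grade": g, "n": len(sub)}
        for o in outcomes:
            row[o] = 100.0 * float(np.nanmean(sub[o].to_numpy(dtype=float)))
        out.append(row)
    return pd.DataFrame(out).sort_values("grade", ignore_index=True)


# --------------------------------------------------------------------------
# full analysis driver
# --------------------------------------------------------------------------

@dataclass
class AnalysisResult:
    results: pd.DataFrame           # one row per ContrastResult
    balance: dict                   # contrast -> balance DataFrame
    spearman: pd.DataFrame
    descriptive: pd.DataFrame
    prevalence: pd.DataFrame
    matches: dict                   # contrast -> MatchedSample
    fits: dict                      # contrast -> PropensityFit
    n_tests: int = 0


def run_contrast(metrics: pd.DataFrame, grades: pd.Series, label: str,
                 seed: int = 0, trim: bool = True, k_folds: int = 10):
    """Propensity fit + trimming + full match for one contrast."""
    fit = fit_propensity(metrics, grades, label, k_folds=k_folds, seed=seed)
    bounds = trim_support(fit) if trim else no_trim(fit)
    match = full_match(fit, bounds, metrics)
    return fit, bounds, match


def run_full_analysis(metrics: pd.DataFrame, grades: pd.Series,
                      cohort: pd.DataFrame, seed: int = 0,
                      outcomes=ALL_OUTCOMES, strata=("metro", "race"),
                      trim: bool = True, sensitivity: bool = False,
                      k_folds: int = 10) -> AnalysisResult:
    """All contrasts x outcomes x strata, plus diagnostics.

    ``cohort`` must be the flow-filtered, outcome-coded cohort with
    ``grade`` and ``polygon_id`` columns.  Strata with an empty or
    unweighted arm are reported as unavailable (skipped) and the run
    continues.
    """
    merged = cohort.merge(metrics[MODEL_COVARIATES], left_on="polygon_id",
                          right_index=True, how="left")
    extra = SENSITIVITY_COVARIATES if sensitivity else ()

    results, balances, matches, fits = [], {}, {}, {}
    n_tests = 0
    for label in CONTRASTS:
        spec = ContrastSpec(label)
        try:
            fit, bounds, match = run_contrast(metrics, grades, label,
                                              seed=seed, trim=trim,
                                              k_folds=k_folds)
        except ValueError as err:
            warnings.warn(f"contrast {label} unavailable: {err}",
                          stacklevel=2)
            continue
        fits[label], matches[label] = fit, match
        balances[label] = balance_table(metrics, fit, match)
        w = assign_birth_weights(match, merged)

        def cells(sub_mask, stratum_name):
            nonlocal n_tests
            for outcome in outcomes:
                try:
                    res = fit_outcome_model(
                        merged[sub_mask], w[sub_mask], outcome,
                        spec.treated_grade, extra_covariates=extra,
                        label=label, stratum=stratum_name)
                    results.append(res.row())
                    n_tests += 1
                except (ValueError, RuntimeError) as err:
                    warnings.warn(
                        f"{label}/{stratum_name}/{outcome} unavailable: "
                        f"{err}", stacklevel=3)

        eligible = merged["contrast_eligible"] \
            if "contrast_eligible" in merged else pd.Series(
                True, index=merged.index)
        cells(eligible, "all")
        for stratum in strata:
            for level in sorted(merged.loc[eligible, stratum].dropna()
                                .unique()):
                cells(eligible & (merged[stratum] == level),
                      f"{stratum}:{level}")

    spearman, _, _ = spearman_screen(
        metrics, covariates=[c for c in metrics.columns
                             if metrics[c].dtype.kind in "if"
                             and c != "coverage"])
    return AnalysisResult(
        results=pd.DataFrame(results),
        balance=balances, spearman=spearman,
        descriptive=descriptive_table(cohort),
        prevalence=prevalence_by_grade(cohort, outcomes),
        matches=matches, fits=fits, n_tests=n_tests)
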