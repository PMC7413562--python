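"""Propensity-score full matching of adjacent HOLC grades.

For a contrast such as D vs C, the "treatment" is having received the
worse grade.  The neighborhood-level propensity of the worse grade given
the areal-weighted 1940 census covariates is estimated by a cross-
validated stacked ensemble of five learner families (grand mean,
linear-logistic, ridge-penalized logistic, adaptive piecewise-linear
hinge-spline logistic, and additive smooth-spline logistic) whose
non-negative stacking weights minimize out-of-fold log-loss.

Neighborhoods off the common support — propensity below the 1st
percentile of the better-graded arm or above the 99th percentile of the
worse-graded arm — are trimmed.  The remaining sample is fully matched:
admissible treated-control pairs must agree on the propensity within a
caliper of 0.2 SD of the score, pair cost is the Mahalanobis distance on
(percent non-White, median home value), and the optimal set of subclasses
(each one treated with several controls, or several treated with one
control) is found exactly as a minimum-cost flow in which every on-support
unit with an admissible partner is used at least once.  Subclass weights
(treated weight 1; controls share their subclass's treated count) are then
propagated to births by neighborhood of residence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler

__all__ = [
    "ContrastSpec", "CONTRASTS", "PropensityFit", "SupportBounds",
    "MatchedSample", "fit_propensity", "trim_support", "full_match",
    "assign_birth_weights", "COVARIATES_1940", "MAHALANOBIS_COVARIATES",
]

#: The three permitted adjacent-grade contrasts (worse grade = treated).
CONTRASTS = {"B_vs_A": ("B", "A"), "C_vs_B": ("C", "B"),
             "D_vs_C": ("D", "C")}

#: Full 1940 covariate set entering the propensity model.
COVARIATES_1940 = [
    "median_home_value", "pct_nonwhite", "pct_black",
    "pct_foreign_born_white", "pct_employed", "pct_radio",
    "pct_refrigerator", "pct_heating", "pct_major_repairs",
    "pct_hs_educated", "persons_per_housing_unit", "population_density",
    "total_pop",
]

#: Covariates for the within-caliper Mahalanobis metric.
MAHALANOBIS_COVARIATES = ["pct_nonwhite", "median_home_value"]

PS_CLIP = 1e-6
COST_SCALE = 10**6


@dataclass(frozen=True)
class ContrastSpec:
    """One adjacent-grade contrast; only the three listed pairs exist."""

    label: str

    def __post_init__(self):
        if self.label not in CONTRASTS:
            raise ValueError(f"unknown contrast {self.label!r}; "
                             f"permitted: {sorted(CONTRASTS)}")

    @property
    def treated_grade(self) -> str:
        return CONTRASTS[self.label][0]

    @property
    def control_grade(self) -> str:
        return CONTRASTS[self.label][1]


@dataclass
class PropensityFit:
    contrast: ContrastSpec
    propensity: pd.Series           # final stacked score per neighborhood
    treated: pd.Series              # boolean, worse grade
    oof_predictions: pd.DataFrame   # per-learner out-of-fold scores
    stack_weights: pd.Series        # non-negative, sums to 1
    folds: pd.Series
    covariates: list = field(default_factory=lambda: list(COVARIATES_1940))


@dataclass
class SupportBounds:
    lower: float                    # 1st pct of better-graded arm
    upper: float                    # 99th pct of worse-graded arm
    retained: pd.Index
    trimmed: pd.DataFrame           # id, arm, propensity of exclusions


@dataclass
class MatchedSample:
    contrast: ContrastSpec
    subclasses: list                # list of dicts {treated: [...], control: [...]}
    weights: pd.Series              # per matched neighborhood, > 0
    caliper: float
    total_distance: float
    discarded: pd.DataFrame         # units with no admissible partner


# --------------------------------------------------------------------------
# propensity ensemble
# --------------------------------------------------------------------------

def _hinge_features(X: np.ndarray, knots: list[np.ndarray]) -> np.ndarray:
    cols = [X]
    for j in range(X.shape[1]):
        for k in knots[j]:
            cols.append(np.maximum(X[:, j:j + 1] - k, 0.0))
            cols.append(np.maximum(k - X[:, j:j + 1], 0.0))
    return np.hstack(cols)


class _HingeLogit:
    """Adaptive piecewise-linear learner: L1-selected hinge bases."""

    def __init__(self, seed: int):
        self.seed = seed

    def fit(self, X, y):
        self.scaler = StandardScaler().fit(X)
        Z = self.scaler.transform(X)
        self.knots = [np.quantile(Z[:, j], [0.25, 0.5, 0.75])
                      for j in range(Z.shape[1])]
        F = _hinge_features(Z, self.knots)
        self.clf = LogisticRegression(penalty="l1", C=0.5,
                                      solver="liblinear",
                                      random_state=self.seed,
                                      max_iter=2000).fit(F, y)
        return self

    def predict_proba(self, X):
        F = _hinge_features(self.scaler.transform(X), self.knots)
        return self.clf.predict_proba(F)


class _MeanModel:
    def fit(self, X, y):
        self.p = float(np.mean(y))
        return self

    def predict_proba(self, X):
        p = np.full(len(X), self.p)
        return np.column_stack([1 - p, p])


def _learners(seed: int) -> dict:
    return {
        "mean": _MeanModel(),
        "glm": make_pipeline(
            StandardScaler(),
            LogisticRegression(penalty=None, solver="lbfgs",
                               max_iter=2000)),
        "ridge": make_pipeline(
            StandardScaler(),
            LogisticRegression(C=1.0, solver="lbfgs", max_iter=2000)),
        "hinge": _HingeLogit(seed),
        "spline": make_pipeline(
            StandardScaler(),
            SplineTransformer(degree=3, n_knots=5, extrapolation="linear"),
            LogisticRegression(C=0.5, solver="lbfgs", max_iter=2000)),
    }


def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, PS_CLIP, 1 - PS_CLIP)


def _stack_weights(oof: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Simplex-constrained weights minimizing log-loss of the blend."""
    m = oof.shape[1]

    def loss(w):
        p = _clip(oof @ w)
        return -float(np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    res = minimize(loss, np.full(m, 1.0 / m), method="SLSQP",
                   bounds=[(0.0, 1.0)] * m,
                   constraints=[{"type": "eq",
                                 "fun": lambda w: np.sum(w) - 1.0}],
                   options={"maxiter": 200, "ftol": 1e-10})
    w = np.clip(res.x, 0, None)
    return w / w.sum()


def fit_propensity(metrics: pd.DataFrame, grades: pd.Series,
                   contrast: ContrastSpec | str, k_folds: int = 10,
                   seed: int = 0,
                   covariates: list | None = None) -> PropensityFit:
    """Stacked-ensemble propensity of the worse grade for one contrast.

    ``metrics`` is the areal-weighted metrics table indexed by
    polygon_id; ``grades`` maps the same index to HOLC grades.  Only the
    contrast's two grades enter.  Missing covariate values are an error.
    """
    if isinstance(contrast, str):
        contrast = ContrastSpec(contrast)
    covariates = list(covariates or COVARIATES_1940)
    grades = grades.reindex(metrics.index)
    in_scope = grades.isin([contrast.treated_grade, contrast.control_grade])
    sub = metrics.loc[in_scope, covariates]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing covariate values: {bad}")
    y = (grades[in_scope] == contrast.treated_grade).to_numpy(dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both grades of the contrast must be present")
    X = sub.to_numpy(dtype=float)

    k = int(min(k_folds, y.sum(), len(y) - y.sum()))
    if k < 2:
        raise ValueError("need at least 2 neighborhoods per arm")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    names = list(_learners(seed))
    oof = np.zeros((len(y), len(names)))
    folds = np.zeros(len(y), dtype=int)
    for f, (tr, te) in enumerate(skf.split(X, y)):
        folds[te] = f
        models = _learners(seed)
        for j, name in enumerate(names):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                models[name].fit(X[tr], y[tr])
                oof[te, j] = _clip(models[name].predict_proba(X[te])[:, 1])

    w = _stack_weights(oof, y)

    final = _learners(seed)
    preds = np.zeros((len(y), len(names)))
    for j, name in enumerate(names):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final[name].fit(X, y)
            preds[:, j] = _clip(final[name].predict_proba(X)[:, 1])
    ps = _clip(preds @ w)

    idx = sub.index
    return PropensityFit(
        contrast=contrast,
        propensity=pd.Series(ps, index=idx, name="propensity"),
        treated=pd.Series(y.astype(bool), index=idx, name="treated"),
        oof_predictions=pd.DataFrame(oof, index=idx, columns=names),
        stack_weights=pd.Series(w, index=names, name="stack_weight"),
        folds=pd.Series(folds, index=idx, name="fold"),
        covariates=covariates)


# --------------------------------------------------------------------------
# support trimming
# --------------------------------------------------------------------------

def trim_support(fit: PropensityFit) -> SupportBounds:
    """Percentile-rule common support.

    Lower bound: 1st percentile of the propensity among better-graded
    (control) neighborhoods; upper: 99th percentile among worse-graded
    (treated) ones; anything outside [lower, upper] is excluded and
    logged.
    """
    ps, tr = fit.propensity, fit.treated
    if tr.all() or (~tr).all():
        raise ValueError("both arms must be non-empty")
    lower = float(np.quantile(ps[~tr], 0.01))
    upper = float(np.quantile(ps[tr], 0.99))
    if lower > upper:
        raise ValueError(f"empty common support for {fit.contrast.label}: "
                         f"lower {lower:.4f} > upper {upper:.4f}")
    keep = (ps >= lower) & (ps <= upper)
    trimmed = pd.DataFrame({
        "polygon_id": ps.index[~keep],
        "arm": np.where(tr[~keep], "treated", "control"),
        "propensity": ps[~keep].to_numpy(),
    })
    return SupportBounds(lower=lower, upper=upper,
                         retained=ps.index[keep].sort_values(),
                         trimmed=trimmed.reset_index(drop=True))


def no_trim(fit: PropensityFit) -> SupportBounds:
    """Degenerate bounds retaining everything (the unrestricted analysis)."""
    ps = fit.propensity
    return SupportBounds(lower=float(ps.min()), upper=float(ps.max()),
                         retained=ps.index.sort_values(),
                         trimmed=pd.DataFrame(
                             columns=["polygon_id", "arm", "propensity"]))


# --------------------------------------------------------------------------
# optimal full matching via minimum-cost flow
# --------------------------------------------------------------------------

def _mahalanobis_matrix(Xt: np.ndarray, Xc: np.ndarray,
                        pooled: np.ndarray) -> np.ndarray:
    cov = np.cov(pooled, rowvar=False)
    cov = np.atleast_2d(cov) + 1e-8 * np.eye(pooled.shape[1])
    inv = np.linalg.inv(cov)
    diff = Xt[:, None, :] - Xc[None, :, :]
    return np.sqrt(np.einsum("tcj,jk,tck->tc", diff, inv, diff))


def full_match(fit: PropensityFit, bounds: SupportBounds,
               metrics: pd.DataFrame, caliper_sd: float = 0.2
               ) -> MatchedSample:
    """Exact optimal full matching on the trimmed sample.

    Builds the bipartite graph of treated-control pairs within the
    propensity caliper (``caliper_sd`` times the SD of the score over the
    on-support sample) with Mahalanobis pair costs, discards units with no
    admissible partner, and solves a minimum-cost flow in which every
    remaining unit is used at least once and each admissible pair at most
    once.  With strictly positive pair costs (an epsilon is added to
    prefer fewer pairs among cost ties) every optimal solution is a union
    of stars, i.e. a valid full match; stars become the subclasses.
    """
    ps = fit.propensity.loc[bounds.retained]
    tr = fit.treated.loc[bounds.retained]
    t_ids = list(ps.index[tr])
    c_ids = list(ps.index[~tr])
    if len(t_ids) < 2 or len(c_ids) < 2:
        raise ValueError("need at least 2 neighborhoods per arm on support")
    caliper = float(caliper_sd * np.std(ps.to_numpy(), ddof=1))

    pst = ps[t_ids].to_numpy()
    psc = ps[c_ids].to_numpy()
    admissible = np.abs(pst[:, None] - psc[None, :]) <= caliper

    Xt = metrics.loc[t_ids, MAHALANOBIS_COVARIATES].to_numpy(dtype=float)
    Xc = metrics.loc[c_ids, MAHALANOBIS_COVARIATES].to_numpy(dtype=float)
    dist = _mahalanobis_matrix(Xt, Xc, np.vstack([Xt, Xc]))

    keep_t = admissible.any(axis=1)
    keep_c = admissible.any(axis=0)
    discarded = pd.DataFrame({
        "polygon_id": ([t for t, k in zip(t_ids, keep_t) if not k]
                       + [c for c, k in zip(c_ids, keep_c) if not k]),
        "arm": (["treated"] * int((~keep_t).sum())
                + ["control"] * int((~keep_c).sum())),
    })
    ti = np.nonzero(keep_t)[0]
    ci = np.nonzero(keep_c)[0]
    if len(ti) == 0 or len(ci) == 0:
        raise ValueError("caliper admits no matches")
    adm = admissible[np.ix_(ti, ci)]
    cost = dist[np.ix_(ti, ci)]

    G = nx.DiGraph()
    deg_t = adm.sum(axis=1)
    deg_c = adm.sum(axis=0)
    G.add_node("S", demand=len(ti))
    G.add_node("K", demand=-len(ci))
    for a in range(len(ti)):
        G.add_node(("t", a), demand=-1)
        G.add_edge("S", ("t", a), capacity=int(deg_t[a]) - 1, weight=0)
    for b in range(len(ci)):
        G.add_node(("c", b), demand=1)
        G.add_edge(("c", b), "K", capacity=int(deg_c[b]) - 1, weight=0)
    for a in range(len(ti)):
        for b in range(len(ci)):
            if adm[a, b]:
                G.add_edge(("t", a), ("c", b), capacity=1,
                           weight=int(round(cost[a, b] * COST_SCALE)) + 1)
    G.add_edge("K", "S", capacity=len(ti) * len(ci), weight=0)
    flow = nx.min_cost_flow(G)

    pairs = [(a, b) for a in range(len(ti))
             for b, f in flow[("t", a)].items() if f > 0
             for b in [b[1]]]
    # optimality with positive costs forbids edges whose endpoints both
    # have degree > 1, so the selected pairs form stars
    dt = np.zeros(len(ti), dtype=int)
    dc = np.zeros(len(ci), dtype=int)
    for a, b in pairs:
        dt[a] += 1
        dc[b] += 1
    assert all(dt[a] == 1 or dc[b] == 1 for a, b in pairs), \
        "flow solution is not a union of stars"

    subclasses = []
    centers_t = [a for a in range(len(ti)) if dt[a] > 1]
    centers_c = [b for b in range(len(ci)) if dc[b] > 1]
    used = set()
    for a in centers_t:
        members = [b for (aa, b) in pairs if aa == a]
        subclasses.append({"treated": [t_ids[ti[a]]],
                           "control": [c_ids[ci[b]] for b in members]})
        used.update((a, b) for b in members)
    for b in centers_c:
        members = [a for (a, bb) in pairs if bb == b]
        subclasses.append({"treated": [t_ids[ti[a]] for a in members],
                           "control": [c_ids[ci[b]]]})
        used.update((a, b) for a in members)
    for a, b in pairs:
        if (a, b) not in used:
            subclasses.append({"treated": [t_ids[ti[a]]],
                               "control": [c_ids[ci[b]]]})

    weights = {}
    for sub in subclasses:
        n_t, n_c = len(sub["treated"]), len(sub["control"])
        for t in sub["treated"]:
            weights[t] = weights.get(t, 0.0) + 1.0
        for c in sub["control"]:
            weights[c] = weights.get(c, 0.0) + n_t / n_c
    total = float(sum(cost[a, b] for a, b in pairs))

    subclasses.sort(key=lambda s: (s["treated"][0], s["control"][0]))
    return MatchedSample(
        contrast=fit.contrast, subclasses=subclasses,
        weights=pd.Series(weights, name="weight").sort_index(),
        caliper=caliper, total_distance=total,
        discarded=discarded)


# --------------------------------------------------------------------------
# propagation to births
# --------------------------------------------------------------------------

def assign_birth_weights(match: MatchedSample, cohort: pd.DataFrame,
                         normalize: bool = True) -> pd.Series:
    """Per-birth weight: each birth inherits its neighborhood's weight.

    Births in unmatched, trimmed or NG/outside neighborhoods get weight 0
    and drop out of the contrast's models.  With ``normalize`` the
    nonzero weights are rescaled to mean 1, which stabilizes the weighted
    GLM without changing point estimates.
    """
    w = cohort["polygon_id"].map(match.weights).fillna(0.0)
    if normalize and (w > 0).any():
        w = w / w[w > 0].mean()
    w.name = "birth_weight"
    return w
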