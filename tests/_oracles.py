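"""Independent brute-force oracles used by the test suite."""

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from holcbirths.matching import MAHALANOBIS_COVARIATES, PropensityFit


def random_match_instance(rng, max_t=4, max_c=4):
    """A random tiny matching problem as (fit-like, metrics) inputs."""
    from holcbirths.matching import ContrastSpec
    n_t = int(rng.integers(2, max_t + 1))
    n_c = int(rng.integers(2, max_c + 1))
    ids = [f"t{i}" for i in range(n_t)] + [f"c{j}" for j in range(n_c)]
    # two propensity clumps plus jitter: most pairs within a clump fall
    # inside the 0.2-SD caliper, cross-clump pairs usually outside it
    centers = rng.uniform(0.3, 0.7, size=2)
    ps = centers[rng.integers(0, 2, size=n_t + n_c)] \
        + rng.normal(0.0, 0.01, size=n_t + n_c)
    ps = np.clip(ps, 0.01, 0.99)
    treated = np.array([True] * n_t + [False] * n_c)
    X = rng.normal(0, 1, size=(n_t + n_c, 2))
    metrics = pd.DataFrame(X, index=ids, columns=MAHALANOBIS_COVARIATES)
    fit = PropensityFit(
        contrast=ContrastSpec("D_vs_C"),
        propensity=pd.Series(ps, index=ids),
        treated=pd.Series(treated, index=ids),
        oof_predictions=pd.DataFrame(index=ids),
        stack_weights=pd.Series(dtype=float),
        folds=pd.Series(0, index=ids))
    return fit, metrics


def brute_force_full_match_cost(ps_t, ps_c, dist, caliper):
    """Minimum total within-subclass distance by exhaustive enumeration.

    Enumerates every admissible-edge subset in which each unit with at
    least one admissible partner is used at least once; the optimum over
    these edge covers coincides with the optimum over full matches (an
    optimal cover never links two units that both have other links).
    Units with no admissible partner are excluded, mirroring the
    implementation's discard rule.  Returns (min_cost, n_retained).
    """
    adm = np.abs(ps_t[:, None] - ps_c[None, :]) <= caliper
    keep_t = adm.any(axis=1)
    keep_c = adm.any(axis=0)
    adm = adm[np.ix_(keep_t, keep_c)]
    d = dist[np.ix_(keep_t, keep_c)]
    edges = np.argwhere(adm)
    E = len(edges)
    if E == 0:
        return np.inf, 0
    assert E <= 20, "instance too large for enumeration"
    masks = np.arange(1, 1 << E, dtype=np.int64)
    bits = (masks[:, None] >> np.arange(E)) & 1
    feasible = np.ones(len(masks), dtype=bool)
    for a in range(adm.shape[0]):
        m = bits[:, edges[:, 0] == a].sum(axis=1)
        feasible &= m > 0
    for b in range(adm.shape[1]):
        m = bits[:, edges[:, 1] == b].sum(axis=1)
        feasible &= m > 0
    costs = bits @ d[edges[:, 0], edges[:, 1]]
    return float(costs[feasible].min()), int(keep_t.sum() + keep_c.sum())


def mahalanobis_oracle(Xt, Xc):
    """Pairwise Mahalanobis distances with the pooled-sample covariance."""
    pooled = np.vstack([Xt, Xc])
    cov = np.cov(pooled, rowvar=False) + 1e-8 * np.eye(pooled.shape[1])
    return cdist(Xt, Xc, metric="mahalanobis", VI=np.linalg.inv(cov))
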