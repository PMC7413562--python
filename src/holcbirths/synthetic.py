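"""Synthetic city and birth cohort generator.

The generator builds a caricature of the study setting that preserves the
features the downstream methods depend on:

* a rectangular grid of unit HOLC neighborhood cells with grades sampled
  from a configurable mix and spatially smoothed (neighboring cells tend to
  share a grade), split into metro bands with explicit map boundaries;
* a second rectangular tract grid, diagonally offset by a fraction of a
  cell so the two tessellations genuinely misalign, every HOLC cell fully
  covered and every interior cell cut by several tracts;
* 1940 tract count metrics drawn around area-weighted mixes of per-grade
  means, with subcounts drawn binomially from their totals so logical
  bounds hold by construction;
* a birth cohort placed uniformly within neighborhoods (choice weighted by
  per-grade birth intensity), with grade-dependent maternal demographics
  and binary outcome indicators drawn from logistic models whose log-odds
  combine a baseline, injected adjacent-grade effects (accumulated down
  the grade ladder, so each contrast's conditional log-OR equals exactly
  the injected value), confounding through the neighborhood's areal-
  weighted 1940 metrics, and optional maternal covariate terms.

Gestational age (days) and birth weight (grams) are synthesized
*conditionally on* the drawn indicators: very-preterm, preterm and term
births get ages in the matching day ranges, and VLBW/LBW births get
weights in the matching gram bins, while non-LBW weight increases with
gestational age with a sex-specific shift.  Downstream outcome coding
therefore recovers the injected indicators from the raw fields.

Everything is driven by ``numpy.random.default_rng`` seeded from the
config; a fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from scipy.special import expit
from shapely.geometry import box

from .apportion import apportion
from .config import (EDUCATION_LEVELS, FIELD_SPECS, PAYER_LEVELS,
                     RACE_LEVELS, SimConfig)
from .types import (BIRTH_COLUMNS, CityLayer, GRADES, GradedPolygon, Tract)

__all__ = ["generate_city", "generate_tract_metrics", "generate_births",
           "generate_study", "expected_marginal_prevalence"]


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    # independent, deterministic stream per pipeline stage
    return np.random.default_rng([int(config.seed) % (2**31), stage])


# --------------------------------------------------------------------------
# city geometry and grades
# --------------------------------------------------------------------------

def _metro_columns(config: SimConfig) -> list[str]:
    """Metro label per grid column (contiguous bands, left to right)."""
    labels, shares = zip(*config.metro_shares.items())
    edges = np.floor(np.cumsum(shares) * config.n_cols + 0.5).astype(int)
    edges[-1] = config.n_cols
    out, start = [], 0
    for lab, stop in zip(labels, edges):
        out.extend([lab] * max(0, stop - start))
        start = max(start, stop)
    return out[:config.n_cols]


def _smooth_grades(grades: np.ndarray, n_rows: int, n_cols: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Greedy pair swaps that raise same-grade adjacency.

    Swapping only permutes the sampled grades, so the marginal grade
    frequencies of the i.i.d. draw are preserved exactly.
    """
    g = grades.reshape(n_rows, n_cols).copy()

    def cell_score(r, c, val):
        s = 0
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < n_rows and 0 <= cc < n_cols and g[rr, cc] == val:
                s += 1
        return s

    n = n_rows * n_cols
    for _ in range(3 * n):
        i, j = rng.integers(0, n, size=2)
        r1, c1, r2, c2 = i // n_cols, i % n_cols, j // n_cols, j % n_cols
        a, b = g[r1, c1], g[r2, c2]
        if a == b:
            continue
        before = cell_score(r1, c1, a) + cell_score(r2, c2, b)
        g[r1, c1], g[r2, c2] = b, a
        after = cell_score(r1, c1, b) + cell_score(r2, c2, a)
        if after < before:  # revert
            g[r1, c1], g[r2, c2] = a, b
    return g.ravel()


def generate_city(config: SimConfig) -> CityLayer:
    """Build the HOLC grid, metro boundaries, and the offset tract grid.

    The tract grid uses the same 1x1 cells shifted by ``tract_offset`` in
    both directions and extended one cell outward, so the HOLC grid is
    fully covered and every interior HOLC cell is intersected by four
    tracts.  An offset of exactly 0 or 1 would make the grids coincide and
    is rejected as a degenerate overlay.
    """
    off = float(config.tract_offset)
    if not 0.0 < off < 1.0:
        raise ValueError("degenerate overlay: tract_offset must lie "
                         "strictly between 0 and one cell width")
    n_rows, n_cols = config.n_rows, config.n_cols
    rng = _rng(config, 1)

    metro_of_col = _metro_columns(config)
    grade_names = [g for g in GRADES if g in config.grade_probs]
    probs = np.array([config.grade_probs[g] for g in grade_names])
    flat = rng.choice(len(grade_names), size=n_rows * n_cols, p=probs)
    flat = _smooth_grades(flat, n_rows, n_cols, rng)

    holc = []
    for r in range(n_rows):
        for c in range(n_cols):
            holc.append(GradedPolygon(
                polygon_id=f"h{r:02d}c{c:02d}",
                grade=grade_names[flat[r * n_cols + c]],
                geometry=box(c, r, c + 1, r + 1),
                metro=metro_of_col[c]))

    boundaries = {}
    for metro in dict.fromkeys(metro_of_col):
        cols = [c for c, m in enumerate(metro_of_col) if m == metro]
        boundaries[metro] = box(min(cols), 0, max(cols) + 1, n_rows)

    tracts = []
    for r in range(-1, n_rows + 1):
        for c in range(-1, n_cols + 1):
            geom = box(c + off, r + off, c + 1 + off, r + 1 + off)
            # clip to the mapped area plus nothing: keep only tracts that
            # actually touch the HOLC grid interior
            if geom.intersection(box(0, 0, n_cols, n_rows)).area <= 0:
                continue
            tracts.append(Tract(tract_id=f"t{r + 1:02d}c{c + 1:02d}",
                                geometry=geom))
    return CityLayer(holc=holc, tracts=tracts, boundaries=boundaries)


# --------------------------------------------------------------------------
# 1940 tract metrics
# --------------------------------------------------------------------------

def _grade_shares(city: CityLayer) -> tuple[np.ndarray, list[str]]:
    """Per-tract area shares of each grade it overlaps (rows sum to 1)."""
    grade_names = list(GRADES)
    hgeoms = np.array([p.geometry for p in city.holc], dtype=object)
    hgrade = np.array([grade_names.index(p.grade) for p in city.holc])
    tgeoms = np.array([t.geometry for t in city.tracts], dtype=object)
    tree = shapely.STRtree(hgeoms)
    tj, hj = tree.query(tgeoms, predicate="intersects")
    areas = shapely.area(shapely.intersection(tgeoms[tj], hgeoms[hj]))
    shares = np.zeros((len(city.tracts), len(grade_names)))
    np.add.at(shares, (tj, hgrade[hj]), areas)
    tot = shares.sum(axis=1, keepdims=True)
    if (tot <= 0).any():
        bad = city.tracts[int(np.argmin(tot))].tract_id
        raise ValueError(f"tract {bad!r} touches no HOLC polygon")
    return shares / tot, grade_names


def _gaussian_field(points: np.ndarray, length_scale: float,
                    rng: np.random.Generator, n_modes: int = 32
                    ) -> np.ndarray:
    """Smooth unit-variance Gaussian surface via random Fourier features."""
    k = rng.normal(0.0, 1.0 / length_scale, size=(n_modes, 2))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n_modes)
    proj = points @ k.T + phi
    return np.sqrt(2.0 / n_modes) * np.cos(proj).sum(axis=1)


def _logit(p):
    p = np.clip(p, 1e-4, 1 - 1e-4)
    return np.log(p / (1 - p))


def _draw_count(rng, mean, cv):
    mean = np.asarray(mean, dtype=float)
    if cv <= 0:
        return np.rint(mean).astype(int)
    shape = 1.0 / cv**2
    vals = rng.gamma(shape, mean * cv**2)
    return np.rint(vals).astype(int)


def generate_tract_metrics(config: SimConfig, city: CityLayer) -> CityLayer:
    """Fill each tract's 1940 metrics in place (and return the city).

    Each tract's mean vector is the area-weighted mix of the per-grade
    means over the grades it overlaps; totals are drawn from a gamma
    distribution with the configured coefficient of variation (rounded to
    counts), and every subcount is drawn binomially from its total, so
    subcounts never exceed totals.
    """
    shares, grade_names = _grade_shares(city)
    present = {grade_names[k] for k in np.nonzero(shares.sum(axis=0))[0]}
    missing = present - set(config.metric_means_by_grade)
    if missing:
        raise KeyError("metric means missing for grades present in the "
                       f"city: {sorted(missing)}")

    keys = sorted(next(iter(config.metric_means_by_grade.values())))
    mean_mat = np.array([[config.metric_means_by_grade.get(g, {k: 0 for k in keys})[k]
                          for k in keys] for g in grade_names])
    mixed = shares @ mean_mat  # (n_tracts, n_keys)
    mix = {k: mixed[:, i] for i, k in enumerate(keys)}

    rng = _rng(config, 2)

    # latent smooth surfaces: spatially correlated within-grade
    # heterogeneity independent of grade (a shared "wealth" component plus
    # a metric-specific component, equal variance)
    if config.spatial_sd > 0:
        cent = np.array([[t.geometry.centroid.x, t.geometry.centroid.y]
                         for t in city.tracts])
        shared = _gaussian_field(cent, config.spatial_length, rng)
        for key in sorted(FIELD_SPECS):
            if key not in mix:
                continue
            transform, sd, wsign = FIELD_SPECS[key]
            own = _gaussian_field(cent, config.spatial_length, rng)
            f = config.spatial_sd * sd * np.sqrt(0.5) * (wsign * shared
                                                         + own)
            if transform == "log":
                mix[key] = mix[key] * np.exp(f)
            else:
                mix[key] = expit(_logit(mix[key]) + f)

    cv = config.metric_cv
    pop = _draw_count(rng, mix["total_pop"], cv)
    homes = _draw_count(rng, mix["total_homes"], cv)
    units = np.maximum(homes, _draw_count(rng, mix["housing_units"], cv))
    mhv = rng.gamma(1.0 / max(cv, 1e-9)**2,
                    mix["median_home_value"] * max(cv, 1e-9)**2) \
        if cv > 0 else mix["median_home_value"]

    def sub(total, frac_key):
        p = np.clip(mix[frac_key], 0, 1)
        return rng.binomial(total, p)

    nonwhite = sub(pop, "frac_nonwhite")
    white = pop - nonwhite
    black = sub(nonwhite, "frac_black")
    fbw = sub(white, "frac_foreign_born_white")
    employed = sub(pop, "frac_employed")
    radio = sub(homes, "frac_radio")
    fridge = sub(homes, "frac_refrigerator")
    heat = sub(homes, "frac_heating")
    repairs = sub(homes, "frac_major_repairs")

    edu_p = np.stack([np.clip(mix["frac_edu_no_hs"], 1e-12, None),
                      np.clip(mix["frac_edu_hs"], 1e-12, None),
                      np.clip(mix["frac_edu_college"], 1e-12, None)], axis=1)
    edu_p /= edu_p.sum(axis=1, keepdims=True)
    edu = np.array([rng.multinomial(pop[i], edu_p[i])
                    for i in range(len(pop))])

    for i, t in enumerate(city.tracts):
        t.metrics = dict(
            total_pop=int(pop[i]), white=int(white[i]),
            nonwhite=int(nonwhite[i]), foreign_born_white=int(fbw[i]),
            black=int(black[i]), employed=int(employed[i]),
            total_homes=int(homes[i]),
            homes_major_repairs=int(repairs[i]),
            homes_radio=int(radio[i]),
            homes_no_radio=int(homes[i] - radio[i]),
            homes_refrigerator=int(fridge[i]),
            homes_no_refrigerator=int(homes[i] - fridge[i]),
            homes_heating=int(heat[i]),
            homes_no_heating=int(homes[i] - heat[i]),
            edu_no_hs=int(edu[i, 0]), edu_hs=int(edu[i, 1]),
            edu_college=int(edu[i, 2]),
            housing_units=int(units[i]),
            median_home_value=float(mhv[i]),
        )
    return city


# --------------------------------------------------------------------------
# birth cohort
# --------------------------------------------------------------------------

def _categorical(rng, probs, levels, size):
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(levels), size=size, p=p)
    return np.asarray(levels, dtype=object)[idx]


def _confounder_values(config: SimConfig, city: CityLayer) -> pd.DataFrame:
    """Centered areal-weighted metrics per polygon for the outcome logits."""
    if not city.tracts or not city.tracts[0].metrics:
        raise ValueError("tract metrics not generated; run "
                         "generate_tract_metrics first")
    metrics = apportion(city.holc, city.tracts)
    cols = list(config.confounder_coefs)
    missing = set(cols) - set(metrics.columns)
    if missing:
        raise KeyError(f"confounder metrics not available: {sorted(missing)}")
    vals = metrics[cols].astype(float)
    return vals - vals.mean(axis=0)


def generate_births(config: SimConfig, city: CityLayer) -> pd.DataFrame:
    """Draw the synthetic birth cohort as a DataFrame (``BIRTH_COLUMNS``).

    A configurable fraction of births is placed outside every map boundary
    and another below 24 weeks of gestation, to exercise the downstream
    inclusion flow; births inside the city land uniformly within a
    neighborhood chosen with probability proportional to area times the
    per-grade birth intensity (NG neighborhoods included).
    """
    n = int(config.n_births)
    if n == 0:
        return pd.DataFrame(columns=list(BIRTH_COLUMNS))
    rng = _rng(config, 3)

    polys = city.holc
    intensity = np.array([config.birth_intensity_by_grade.get(p.grade, 0.0)
                          for p in polys])
    if (intensity < 0).any():
        raise ValueError("negative birth intensity")
    area = np.array([p.geometry.area for p in polys])
    psel = intensity * area
    psel = psel / psel.sum()

    n_out = int(round(config.frac_outside * n))
    n_in = n - n_out
    poly_idx = rng.choice(len(polys), size=n_in, p=psel)

    bounds = np.array([polys[i].geometry.bounds for i in poly_idx])
    x_in = rng.uniform(bounds[:, 0], bounds[:, 2])
    y_in = rng.uniform(bounds[:, 1], bounds[:, 3])
    # cells are axis-aligned boxes so bbox-uniform is polygon-uniform
    maxx = max(p.geometry.bounds[2] for p in polys)
    x_out = maxx + 1.0 + rng.uniform(0, 3, size=n_out)
    y_out = rng.uniform(0, config.n_rows, size=n_out)

    grade = np.array([polys[i].grade for i in poly_idx], dtype=object)
    metro = np.array([polys[i].metro for i in poly_idx], dtype=object)
    grade_all = np.concatenate([grade,
                                np.full(n_out, "outside", dtype=object)])
    metro_out = _categorical(rng, list(config.metro_shares.values()),
                             list(config.metro_shares), n_out)
    metro_all = np.concatenate([metro, metro_out])
    x = np.concatenate([x_in, x_out])
    y = np.concatenate([y_in, y_out])

    # maternal covariates, grade-dependent ("outside" uses the NG mix)
    race = np.empty(n, dtype=object)
    edu = np.empty(n, dtype=object)
    payer = np.empty(n, dtype=object)
    mat_age = np.empty(n)
    parity = np.empty(n, dtype=int)
    for g in list(GRADES) + ["outside"]:
        mask = grade_all == g
        m = int(mask.sum())
        if m == 0:
            continue
        spec = config.maternal_by_grade.get("NG" if g == "outside" else g)
        race[mask] = _categorical(rng, spec["race"], RACE_LEVELS, m)
        edu[mask] = _categorical(rng, spec["education"], EDUCATION_LEVELS, m)
        payer[mask] = _categorical(rng, spec["payer"], PAYER_LEVELS, m)
        mat_age[mask] = np.clip(
            rng.normal(spec["age_mean"], spec["age_sd"], size=m), 14, 55)
        parity[mask] = rng.poisson(spec["parity_mean"], size=m)

    sex = np.where(rng.random(n) < config.sex_male_prob, "male", "female")
    birth_year = rng.integers(2006, 2016, size=n)

    # confounder term (identical for every outcome)
    conf = _confounder_values(config, city)
    conf_term = np.zeros(n)
    pid = np.array([polys[i].polygon_id for i in poly_idx], dtype=object)
    for metric, coef in config.confounder_coefs.items():
        conf_term[:n_in] += coef * conf.loc[pid, metric].to_numpy()

    mat_term = np.zeros(n)
    for name, coef in config.maternal_coefs.items():
        if name == "maternal_age":
            mat_term += coef * (mat_age - 29.0)
        elif name == "parity":
            mat_term += coef * parity
        else:
            raise KeyError(f"unknown maternal coefficient {name!r}")

    cumeff = {
        out: np.array([config.cumulative_grade_effect(g, out)
                       for g in grade_all])
        for out in config.outcome_base_logodds
    }
    base = config.outcome_base_logodds
    coup = config.outcome_couplings

    def bern(logit):
        return rng.random(n) < expit(logit)

    z_pt = bern(base["preterm"] + cumeff["preterm"] + conf_term + mat_term)
    z_vpt = z_pt & bern(base["very_preterm"] + cumeff["very_preterm"]
                        + conf_term + mat_term)
    z_lbw = bern(base["lbw"] + cumeff["lbw"] + conf_term + mat_term
                 + coup.get(("lbw", "preterm"), 0.0) * z_pt)
    z_vlbw = z_lbw & bern(base["vlbw"] + cumeff["vlbw"] + conf_term
                          + coup.get(("vlbw", "very_preterm"), 0.0) * z_vpt)
    z_pm = bern(base["perinatal_mortality"] + cumeff["perinatal_mortality"]
                + conf_term + mat_term
                + coup.get(("perinatal_mortality", "preterm"), 0.0) * z_pt)
    z_nn = z_pm & bern(base["neonatal_mortality"]
                       + cumeff["neonatal_mortality"] + conf_term)

    # gestational age in days, consistent with the drawn indicators
    ga = np.rint(np.clip(rng.normal(276, 9, size=n), 259, 293)).astype(int)
    ga[z_pt & ~z_vpt] = rng.integers(224, 259, size=int((z_pt & ~z_vpt).sum()))
    ga[z_vpt] = rng.integers(168, 224, size=int(z_vpt.sum()))
    n_pre24 = int(round(config.frac_below_24wk * n))
    pre24_idx = rng.choice(n, size=n_pre24, replace=False)
    ga[pre24_idx] = rng.integers(100, 168, size=n_pre24)

    # birth weight in grams, consistent with LBW bins; non-LBW weight rises
    # with gestational age with a sex-specific shift
    wt = rng.normal(3300 + 15.0 * (ga - 276) + 120.0 * (sex == "male"),
                    350.0)
    wt = np.clip(wt, 2500, 5500)
    wt[z_lbw & ~z_vlbw] = rng.uniform(1500, 2500,
                                      size=int((z_lbw & ~z_vlbw).sum()))
    wt[z_vlbw] = rng.uniform(500, 1500, size=int(z_vlbw.sum()))
    wt = np.round(wt, 0)

    death = np.full(n, np.nan)
    death[z_nn] = rng.integers(0, 28, size=int(z_nn.sum()))
    death[z_pm & ~z_nn] = rng.integers(28, 366,
                                       size=int((z_pm & ~z_nn).sum()))
    elective = np.zeros(n, dtype=bool)
    n_el = int(round(config.frac_elective_abortion * n))
    cand = np.nonzero(~z_pm)[0]
    el_idx = rng.choice(cand, size=min(n_el, len(cand)), replace=False)
    elective[el_idx] = True
    death[el_idx] = 0

    n_miss = int(round(config.frac_missing_weight * n))
    miss_idx = rng.choice(n, size=n_miss, replace=False)
    wt[miss_idx] = np.nan

    df = pd.DataFrame({
        "birth_id": [f"b{i:07d}" for i in range(n)],
        "x": x, "y": y,
        "gest_age_days": ga,
        "birth_weight_g": wt,
        "sex": sex,
        "death_age_days": death,
        "elective_abortion": elective,
        "race": race,
        "maternal_age": np.round(mat_age, 1),
        "parity": parity,
        "education": edu,
        "payer": payer,
        "metro": metro_all,
        "birth_year": birth_year,
    })
    return df[list(BIRTH_COLUMNS)]


def generate_study(config: SimConfig) -> tuple[CityLayer, pd.DataFrame]:
    """City + metrics + cohort in one call."""
    city = generate_city(config)
    generate_tract_metrics(config, city)
    births = generate_births(config, city)
    return city, births


def expected_marginal_prevalence(config: SimConfig, city: CityLayer,
                                 outcome: str = "preterm") -> float:
    """Analytic marginal prevalence of an outcome among in-map births.

    Averages the logistic model over the neighborhood-selection
    distribution; valid when maternal coefficients are zero (the default),
    since then the linear predictor is constant within a neighborhood.
    Supports ``preterm``, ``lbw`` and ``perinatal_mortality`` (the coupled
    marginal outcomes).
    """
    if config.maternal_coefs:
        raise ValueError("analytic prevalence requires zero maternal "
                         "coefficients")
    polys = city.holc
    intensity = np.array([config.birth_intensity_by_grade.get(p.grade, 0.0)
                          for p in polys])
    area = np.array([p.geometry.area for p in polys])
    psel = intensity * area
    psel = psel / psel.sum()
    conf = _confounder_values(config, city)
    conf_term = np.zeros(len(polys))
    pid = [p.polygon_id for p in polys]
    for metric, coef in config.confounder_coefs.items():
        conf_term += coef * conf.loc[pid, metric].to_numpy()
    base = config.outcome_base_logodds
    cum = {out: np.array([config.cumulative_grade_effect(p.grade, out)
                          for p in polys])
           for out in base}
    p_pt = expit(base["preterm"] + cum["preterm"] + conf_term)
    if outcome == "preterm":
        per_poly = p_pt
    elif outcome == "lbw":
        c = config.outcome_couplings.get(("lbw", "preterm"), 0.0)
        eta = base["lbw"] + cum["lbw"] + conf_term
        per_poly = p_pt * expit(eta + c) + (1 - p_pt) * expit(eta)
    elif outcome == "perinatal_mortality":
        c = config.outcome_couplings.get(("perinatal_mortality", "preterm"),
                                         0.0)
        eta = base["perinatal_mortality"] + cum["perinatal_mortality"] \
            + conf_term
        per_poly = p_pt * expit(eta + c) + (1 - p_pt) * expit(eta)
    else:
        raise ValueError(f"no analytic form for {outcome!r}")
    return float(psel @ per_poly)
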