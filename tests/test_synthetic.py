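"""Synthetic city and cohort generator: geometry, determinism,
calibration of the injected outcome models."""

import io

import numpy as np
import pytest
from scipy import stats

from holcbirths import SimConfig
from holcbirths import io as hio
from holcbirths.apportion import apportion, compute_overlaps
from holcbirths.inference import weighted_t_test
from holcbirths.synthetic import (expected_marginal_prevalence,
                                  generate_births, generate_city,
                                  generate_study, generate_tract_metrics)


def _geojson_bytes(city):
    import json
    from shapely.geometry import mapping
    return (
        json.dumps([(p.polygon_id, p.grade, mapping(p.geometry))
                    for p in city.holc], sort_keys=True),
        json.dumps([(t.tract_id, t.metrics, mapping(t.geometry))
                    for t in city.tracts], sort_keys=True),
    )


def test_half_cell_offset_gives_quarter_overlaps():
    """On a 2x2 grid with 0.5 offset every cell meets 4 tracts at 0.25."""
    cfg = SimConfig(seed=0, n_cols=2, n_rows=2, tract_offset=0.5,
                    metro_shares={"LA": 1.0})
    city = generate_city(cfg)
    ov = compute_overlaps(city.holc, city.tracts)
    counts = ov.groupby("polygon_id").size()
    assert (counts == 4).all()
    assert np.allclose(ov["weight"], 0.25, atol=1e-12)


def test_degenerate_offset_rejected():
    for off in (0.0, 1.0):
        with pytest.raises(ValueError, match="degenerate overlay"):
            generate_city(SimConfig(seed=0, tract_offset=off))


def test_interior_cells_cut_by_multiple_tracts(small_city):
    ov = compute_overlaps(small_city.holc, small_city.tracts)
    counts = ov.groupby("polygon_id").size()
    assert (counts >= 2).all()  # interior cells actually get 4


def test_same_seed_byte_identical():
    cfg = SimConfig(seed=7, n_cols=6, n_rows=5, n_births=2000)
    a_city, a_births = generate_study(cfg)
    b_city, b_births = generate_study(SimConfig(seed=7, n_cols=6, n_rows=5,
                                                n_births=2000))
    assert _geojson_bytes(a_city) == _geojson_bytes(b_city)
    buf_a, buf_b = io.StringIO(), io.StringIO()
    hio.write_cohort_csv(a_births, buf_a)
    hio.write_cohort_csv(b_births, buf_b)
    assert buf_a.getvalue() == buf_b.getvalue()


def test_grade_frequencies_match_probs_over_seeds():
    """Smoothing permutes i.i.d. grades, so frequencies stay multinomial.

    Pooled over 50 seeds of a 10x10 grid, each grade's count must fall
    within the 99% binomial band around its probability.
    """
    probs = {"A": 0.10, "B": 0.20, "C": 0.35, "D": 0.30, "NG": 0.05}
    counts = {g: 0 for g in probs}
    n_seeds, cells = 50, 100
    for seed in range(n_seeds):
        city = generate_city(SimConfig(seed=seed, n_cols=10, n_rows=10,
                                       grade_probs=probs))
        for p in city.holc:
            counts[p.grade] += 1
    n = n_seeds * cells
    for g, p in probs.items():
        lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
        assert lo <= counts[g] <= hi, (g, counts[g], (lo, hi))


def test_subcounts_never_exceed_totals(small_city):
    for t in small_city.tracts:
        m = t.metrics
        assert 0 <= m["nonwhite"] <= m["total_pop"]
        assert 0 <= m["black"] <= m["nonwhite"]
        assert 0 <= m["foreign_born_white"] <= m["white"]
        for sub in ("homes_radio", "homes_refrigerator", "homes_heating",
                    "homes_major_repairs"):
            assert 0 <= m[sub] <= m["total_homes"]
        assert m["homes_radio"] + m["homes_no_radio"] == m["total_homes"]
        assert (m["edu_no_hs"] + m["edu_hs"] + m["edu_college"]
                == m["total_pop"])


def test_missing_grade_means_is_config_error(small_config):
    city = generate_city(small_config)
    cfg = SimConfig(seed=small_config.seed, n_cols=8, n_rows=6)
    del cfg.metric_means_by_grade["D"]
    with pytest.raises(KeyError, match="metric means missing"):
        generate_tract_metrics(cfg, city)


def test_home_value_halving_detectable_prematch():
    """Grade-D home value at half the grade-C mean gives a significantly
    negative pre-match mean difference at ~200 neighborhoods in nearly
    every seed."""
    hits, n_seeds = 0, 30
    for seed in range(n_seeds):
        cfg = SimConfig(seed=seed)
        cfg.metric_means_by_grade["D"]["median_home_value"] = \
            cfg.metric_means_by_grade["C"]["median_home_value"] / 2
        city = generate_city(cfg)
        generate_tract_metrics(cfg, city)
        metrics = apportion(city.holc, city.tracts)
        grades = {p.polygon_id: p.grade for p in city.holc}
        d = [metrics.loc[i, "median_home_value"]
             for i, g in grades.items() if g == "D"]
        c = [metrics.loc[i, "median_home_value"]
             for i, g in grades.items() if g == "C"]
        t = weighted_t_test(d, c)
        if t.diff < 0 and t.p < 0.05:
            hits += 1
    assert hits >= int(0.95 * n_seeds)


def test_null_city_has_equal_prevalence_across_grades():
    """No injected effects, no confounding: prevalence differences across
    grades stay within Monte-Carlo error."""
    cfg = SimConfig(seed=5, n_births=60_000, confounder_coefs={},
                    frac_outside=0.0)
    city, births = generate_study(cfg)
    from holcbirths.assignment import assign_grade
    asn = assign_grade(births, city)
    ok = births["gest_age_days"] >= 168
    pt = (births["gest_age_days"] < 259)[ok]
    by_grade = pt.groupby(asn["grade"][ok]).mean()
    pooled = pt.mean()
    for g in ("A", "B", "C", "D"):
        n_g = int((asn["grade"][ok] == g).sum())
        se = np.sqrt(pooled * (1 - pooled) / n_g)
        assert abs(by_grade[g] - pooled) < 4 * se


def test_injected_crude_odds_ratio_recovered():
    """log(0.93) on preterm for D vs C, confounders off: the crude odds
    ratio at n=500k matches 0.93 within 0.02 (direct Bernoulli check)."""
    cfg = SimConfig(seed=12, n_births=500_000, confounder_coefs={},
                    frac_outside=0.0,
                    grade_effect_logodds={"D_vs_C":
                                          {"preterm": float(np.log(0.93))}})
    city, births = generate_study(cfg)
    from holcbirths.assignment import assign_grade
    asn = assign_grade(births, city)
    ok = births["gest_age_days"] >= 168
    pt = (births["gest_age_days"] < 259)[ok]
    g = asn["grade"][ok]
    tab = {gr: (float(pt[g == gr].sum()), float((~pt[g == gr]).sum()))
           for gr in ("C", "D")}
    crude = (tab["D"][0] * tab["C"][1]) / (tab["D"][1] * tab["C"][0])
    assert crude == pytest.approx(0.93, abs=0.02)


def test_marginal_prevalence_matches_analytic():
    cfg = SimConfig(seed=9, n_births=100_000, frac_outside=0.0,
                    frac_below_24wk=0.0)
    city, births = generate_study(cfg)
    expected = expected_marginal_prevalence(cfg, city, "preterm")
    observed = float((births["gest_age_days"] < 259).mean())
    se = np.sqrt(expected * (1 - expected) / len(births))
    assert abs(observed - expected) <= 3 * se


def test_below_24_week_births_flagged_downstream():
    cfg = SimConfig(seed=4, n_cols=6, n_rows=5, n_births=4000,
                    frac_below_24wk=0.01)
    city, births = generate_study(cfg)
    from holcbirths.assignment import apply_inclusion_flow, assign_grade
    asn = assign_grade(births, city)
    cohort, flow = apply_inclusion_flow(births, asn)
    assert (cohort["gest_age_days"] >= 168).all()
    step = flow.set_index("step").loc["gestation under 24 weeks"]
    assert step["n_excluded"] >= int(0.005 * 4000)


def test_zero_births_is_empty_not_error(small_city):
    cfg = SimConfig(seed=0, n_cols=8, n_rows=6, n_births=0)
    births = generate_births(cfg, small_city)
    assert len(births) == 0
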