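"""Shared fixtures: small synthetic studies and geometric toys."""

import numpy as np
import pytest
from shapely.geometry import box

from holcbirths import SimConfig, generate_city, generate_tract_metrics
from holcbirths.pipeline import prepare_study
from holcbirths.types import CityLayer, GradedPolygon, Tract


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=20260929, n_cols=8, n_rows=6, n_births=6000)


@pytest.fixture(scope="session")
def small_city(small_config):
    city = generate_city(small_config)
    generate_tract_metrics(small_config, city)
    return city


@pytest.fixture(scope="session")
def small_study(small_config):
    return prepare_study(small_config)


@pytest.fixture(scope="session")
def medium_study():
    # default-scale city, modest cohort: used by matching/inference tests
    cfg = SimConfig(seed=7, n_births=30_000)
    return cfg, prepare_study(cfg)


@pytest.fixture()
def strip_layers():
    """The worked overlay: HOLC strip (0,0)-(10,1) split 20/80 by tracts."""
    holc = [GradedPolygon("h1", "C", box(0, 0, 10, 1), metro="LA")]
    tracts = [Tract("T1", box(0, 0, 2, 1)), Tract("T2", box(2, 0, 10, 1))]
    return holc, tracts


def make_metrics(rng, n=12, value=None):
    """Minimal tract metric dict with valid subcount structure."""
    total_pop = int(rng.integers(500, 5000))
    homes = int(rng.integers(100, 1500))
    nonwhite = int(rng.integers(0, total_pop + 1))
    edu = rng.multinomial(total_pop, [0.5, 0.35, 0.15])
    m = dict(
        total_pop=total_pop, nonwhite=nonwhite,
        white=total_pop - nonwhite,
        black=int(rng.integers(0, nonwhite + 1)),
        foreign_born_white=int(rng.integers(0, total_pop - nonwhite + 1)),
        employed=int(rng.integers(0, total_pop + 1)),
        total_homes=homes,
        homes_major_repairs=int(rng.integers(0, homes + 1)),
        homes_radio=int(rng.integers(0, homes + 1)),
        homes_refrigerator=int(rng.integers(0, homes + 1)),
        homes_heating=int(rng.integers(0, homes + 1)),
        edu_no_hs=int(edu[0]), edu_hs=int(edu[1]), edu_college=int(edu[2]),
        housing_units=homes + int(rng.integers(0, 100)),
        median_home_value=float(rng.uniform(2, 12)) if value is None
        else value,
    )
    m["homes_no_radio"] = homes - m["homes_radio"]
    m["homes_no_refrigerator"] = homes - m["homes_refrigerator"]
    m["homes_no_heating"] = homes - m["homes_heating"]
    return m
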