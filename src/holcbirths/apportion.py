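"""Areal apportionment of 1940 census tract metrics onto HOLC polygons.

The two polygon layers do not align, so each HOLC neighborhood is assigned
areal-weighted census measures: for every tract intersecting it, the
intersection area divided by the *HOLC polygon* area gives an overlap
weight, and each census metric is the weight-sum of the contributing tract
values.  Note the denominator: weights are shares of the target HOLC
polygon, not of the source tract, so a fully covered polygon has weights
summing to one and its weighted value is a convex combination of tract
values.  The same rule is applied uniformly to counts, to median home
value (yielding a weighted mean of tract medians) and to population
density (tract residents per tract area, then weighted).

Partly covered polygons are not renormalized; the coverage fraction is
reported per polygon instead.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely
from shapely.validation import make_valid

from .types import (DERIVED_RATE_FIELDS, GradedPolygon, Tract,
                    TRACT_COUNT_FIELDS, TRACT_VALUE_FIELDS)

#: Intersections smaller than this fraction of the HOLC polygon area are
#: treated as floating-point slivers and dropped.
SLIVER_REL_TOL = 1e-10

APPORTIONED_FIELDS = TRACT_COUNT_FIELDS + TRACT_VALUE_FIELDS + (
    "population_density",)


def _valid_geometry(geom, owner_id: str):
    if geom is None or geom.is_empty:
        raise ValueError(f"empty geometry for {owner_id!r}")
    if not geom.is_valid:
        geom = make_valid(geom)
        if not geom.is_valid or geom.is_empty:
            raise ValueError(f"unrepairable geometry for {owner_id!r}")
    if geom.area <= 0:
        raise ValueError(f"zero-area geometry for {owner_id!r}")
    return geom


def compute_overlaps(holc: list[GradedPolygon],
                     tracts: list[Tract]) -> pd.DataFrame:
    """Intersect the two layers and compute overlap weights.

    Returns one row per (HOLC polygon, tract) pair with positive
    intersection area: columns ``polygon_id, tract_id, overlap_area,
    weight`` where ``weight = overlap_area / area(HOLC polygon)``.
    Output rows are sorted by (polygon_id, tract_id), so the result does
    not depend on input record order.
    """
    if not holc or not tracts:
        raise ValueError("both layers must be non-empty")
    hgeoms = np.array([_valid_geometry(p.geometry, p.polygon_id)
                       for p in holc], dtype=object)
    tgeoms = np.array([_valid_geometry(t.geometry, t.tract_id)
                       for t in tracts], dtype=object)
    harea = shapely.area(hgeoms)

    tree = shapely.STRtree(tgeoms)
    hidx, tidx = tree.query(hgeoms, predicate="intersects")
    inter = shapely.intersection(hgeoms[hidx], tgeoms[tidx])
    areas = shapely.area(inter)
    weights = areas / harea[hidx]
    keep = weights > SLIVER_REL_TOL

    out = pd.DataFrame({
        "polygon_id": [holc[i].polygon_id for i in hidx[keep]],
        "tract_id": [tracts[j].tract_id for j in tidx[keep]],
        "overlap_area": areas[keep],
        "weight": weights[keep],
    })
    out = out.sort_values(["polygon_id", "tract_id"],
                          ignore_index=True)
    sums = out.groupby("polygon_id")["weight"].sum()
    if (sums > 1 + 1e-9).any():
        bad = sums[sums > 1 + 1e-9].index[0]
        raise ValueError(f"overlap weights exceed 1 for {bad!r}; "
                         "tract layer overlaps itself")
    return out


def tract_metrics_frame(tracts: list[Tract]) -> pd.DataFrame:
    """Tabulate tract metrics (one row per tract, plus tract area)."""
    rows = []
    for t in tracts:
        row = {"tract_id": t.tract_id, "tract_area": t.geometry.area}
        row.update(t.metrics)
        rows.append(row)
    return pd.DataFrame(rows).set_index("tract_id")


def apportion_metrics(overlaps: pd.DataFrame,
                      tract_metrics: pd.DataFrame) -> pd.DataFrame:
    """Areal-weight tract metrics onto HOLC polygons.

    ``tract_metrics`` is indexed by tract_id and must carry every count
    field, ``median_home_value`` and ``tract_area``.  Returns a DataFrame
    indexed by polygon_id with every apportioned metric, the derived rates,
    and a ``coverage`` column (sum of overlap weights).

    A rate whose weighted denominator is zero is recorded as NaN with a
    warning.
    """
    missing = set(overlaps["tract_id"]) - set(tract_metrics.index)
    if missing:
        raise KeyError(f"tracts without metrics: {sorted(missing)[:5]}")
    need = set(TRACT_COUNT_FIELDS) | set(TRACT_VALUE_FIELDS) | {"tract_area"}
    absent = need - set(tract_metrics.columns)
    if absent:
        raise KeyError(f"tract metric columns missing: {sorted(absent)}")

    tm = tract_metrics.loc[overlaps["tract_id"]].reset_index(drop=True)
    w = overlaps["weight"].to_numpy()
    contrib = pd.DataFrame({"polygon_id": overlaps["polygon_id"].to_numpy()})
    for f in TRACT_COUNT_FIELDS + TRACT_VALUE_FIELDS:
        contrib[f] = w * tm[f].to_numpy()
    contrib["population_density"] = (
        w * tm["total_pop"].to_numpy() / tm["tract_area"].to_numpy())
    contrib["coverage"] = w

    out = contrib.groupby("polygon_id", sort=True).sum()
    return add_derived_rates(out)


def add_derived_rates(metrics: pd.DataFrame) -> pd.DataFrame:
    """Attach derived percentage/ratio columns to apportioned metrics."""
    out = metrics.copy()

    def rate(num, den, scale=100.0):
        d = out[den].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(d > 0, scale * out[num].to_numpy(dtype=float) / d,
                         np.nan)
        if (d <= 0).any():
            warnings.warn(f"zero weighted denominator {den}; rate recorded "
                          "as missing", stacklevel=3)
        return r

    out["pct_nonwhite"] = rate("nonwhite", "total_pop")
    out["pct_black"] = rate("black", "total_pop")
    out["pct_foreign_born_white"] = rate("foreign_born_white", "total_pop")
    out["pct_employed"] = rate("employed", "total_pop")
    out["pct_radio"] = rate("homes_radio", "total_homes")
    out["pct_refrigerator"] = rate("homes_refrigerator", "total_homes")
    out["pct_heating"] = rate("homes_heating", "total_homes")
    out["pct_major_repairs"] = rate("homes_major_repairs", "total_homes")
    edu_total = (out["edu_no_hs"] + out["edu_hs"] + out["edu_college"])
    out["_edu_total"] = edu_total
    out["_edu_hs_plus"] = out["edu_hs"] + out["edu_college"]
    out["pct_hs_educated"] = rate("_edu_hs_plus", "_edu_total")
    out = out.drop(columns=["_edu_total", "_edu_hs_plus"])
    out["persons_per_housing_unit"] = rate("total_pop", "housing_units",
                                           scale=1.0)
    assert set(DERIVED_RATE_FIELDS) <= set(out.columns)
    return out


def apportion(holc: list[GradedPolygon],
              tracts: list[Tract]) -> pd.DataFrame:
    """Convenience: overlaps + apportionment in one call."""
    overlaps = compute_overlaps(holc, tracts)
    return apportion_metrics(overlaps, tract_metrics_frame(tracts))
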