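"""Point-in-polygon grade assignment and the inclusion/exclusion flow.

Each birth's planar coordinates are overlaid on the HOLC layer: a point
inside a graded polygon takes its grade; a point inside a metro's map
boundary but in no graded polygon is "NG" (inside the mapped city, never
appraised); anything else is "outside" and fully excluded.  A point on a
shared polygon edge is assigned to the polygon with the lexicographically
smallest ``polygon_id`` among those whose closed region contains it, which
makes assignment deterministic and independent of layer order.

The inclusion flow then applies, in fixed order: (1) drop births outside
the map boundary, (2) drop gestations under 168 days (24 weeks), (3) drop
births with unknown fields for the requested outcome set.  NG births
survive the flow for descriptive tables but are flagged ineligible for the
grade contrasts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely

from .types import CityLayer

MIN_GEST_DAYS = 168  # 24 weeks

#: Raw fields each outcome needs; a missing field makes the outcome unknown.
OUTCOME_SOURCE_FIELDS = {
    "preterm": ("gest_age_days",),
    "very_preterm": ("gest_age_days",),
    "lbw": ("birth_weight_g",),
    "vlbw": ("birth_weight_g",),
    "sga": ("birth_weight_g", "gest_age_days", "sex"),
    "perinatal_mortality": (),
    "neonatal_mortality": (),
}


def assign_grade(births: pd.DataFrame, layer: CityLayer) -> pd.DataFrame:
    """Assign every birth a polygon and grade (or NG / outside).

    Returns a DataFrame indexed like ``births`` with columns ``birth_id,
    polygon_id, grade``; ``polygon_id`` is empty for NG and outside
    births.  Births with missing coordinates are assigned "outside".
    """
    if not layer.holc:
        raise ValueError("empty HOLC layer")
    n = len(births)
    xs = births["x"].to_numpy(dtype=float)
    ys = births["y"].to_numpy(dtype=float)
    ok = np.isfinite(xs) & np.isfinite(ys)

    pts = shapely.points(np.where(ok, xs, 0.0), np.where(ok, ys, 0.0))
    order = np.argsort([p.polygon_id for p in layer.holc], kind="stable")
    polys = [layer.holc[i] for i in order]
    geoms = np.array([p.geometry for p in polys], dtype=object)

    tree = shapely.STRtree(geoms)
    pi, gi = tree.query(pts[ok], predicate="intersects")
    # polygons are id-sorted, so the min polygon index per point is the
    # lexicographic tie-break on shared edges
    best = {}
    for p, g in zip(pi, gi):
        if p not in best or g < best[p]:
            best[p] = g

    grade = np.full(n, "outside", dtype=object)
    polygon_id = np.full(n, "", dtype=object)
    ok_idx = np.nonzero(ok)[0]
    hit = np.array(sorted(best), dtype=int) if best else np.array([], int)
    for p in hit:
        g = best[p]
        grade[ok_idx[p]] = polys[g].grade
        polygon_id[ok_idx[p]] = polys[g].polygon_id

    # NG: inside some metro boundary but in no graded polygon
    unhit_local = np.setdiff1d(np.arange(int(ok.sum())), hit)
    if len(unhit_local) and layer.boundaries:
        bgeoms = np.array([layer.boundaries[m]
                           for m in sorted(layer.boundaries)], dtype=object)
        btree = shapely.STRtree(bgeoms)
        qi, _ = btree.query(pts[ok][unhit_local], predicate="intersects")
        grade[ok_idx[unhit_local[np.unique(qi)]]] = "NG"

    return pd.DataFrame({"birth_id": births["birth_id"].to_numpy(),
                         "polygon_id": polygon_id, "grade": grade},
                        index=births.index)


def apply_inclusion_flow(
        births: pd.DataFrame, assignments: pd.DataFrame,
        outcomes: tuple[str, ...] = ("preterm", "lbw", "sga",
                                     "perinatal_mortality"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the fixed exclusion sequence; return (cohort, flow table).

    The cohort gains ``grade``, ``polygon_id`` and ``contrast_eligible``
    columns (NG births are retained but ineligible).  The flow table has
    one row per step with ``step, n_excluded, n_remaining``.
    """
    if len(births) != len(assignments):
        raise ValueError("every birth needs an assignment")
    df = births.merge(assignments[["birth_id", "polygon_id", "grade"]],
                      on="birth_id", how="left", validate="one_to_one")
    steps = [("screened", 0, len(df))]

    keep = df["grade"] != "outside"
    steps.append(("outside map boundary", int((~keep).sum()),
                  int(keep.sum())))
    df = df[keep]

    keep = df["gest_age_days"].notna() & (df["gest_age_days"]
                                          >= MIN_GEST_DAYS)
    steps.append(("gestation under 24 weeks", int((~keep).sum()),
                  int(keep.sum())))
    df = df[keep]

    needed = sorted({f for o in outcomes
                     for f in OUTCOME_SOURCE_FIELDS[o]})
    keep = pd.Series(True, index=df.index)
    for f in needed:
        keep &= df[f].notna()
    steps.append(("unknown outcome fields", int((~keep).sum()),
                  int(keep.sum())))
    df = df[keep].copy()

    df["contrast_eligible"] = df["grade"].isin(["A", "B", "C", "D"])
    flow = pd.DataFrame(steps, columns=["step", "n_excluded", "n_remaining"])
    if flow["n_remaining"].iloc[-1] == 0:
        import warnings
        warnings.warn("inclusion flow removed every birth", stacklevel=2)
    return df.reset_index(drop=True), flow
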