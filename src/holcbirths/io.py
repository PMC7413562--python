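"""Reading and writing the pipeline's interchange formats.

Polygon layers travel as GeoJSON FeatureCollections (shapely geometries,
attributes in feature properties); the HOLC layer file also carries one
boundary feature per metro (``role: "boundary"``) defining the map extent
used for the NG/outside distinction.  Birth cohorts travel as CSV with the
column dictionary in :data:`holcbirths.types.BIRTH_COLUMNS`.

All writers emit deterministically ordered, plain-text output so reruns
under a fixed seed are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

from .types import CityLayer, GradedPolygon, Tract


def _feature(geom, properties: dict) -> dict:
    return {"type": "Feature", "geometry": mapping(geom),
            "properties": properties}


def write_holc_geojson(city: CityLayer, path) -> None:
    """HOLC polygons plus per-metro boundary features, one file."""
    feats = [_feature(p.geometry, {"role": "holc",
                                   "polygon_id": p.polygon_id,
                                   "grade": p.grade, "metro": p.metro})
             for p in city.holc]
    for metro in sorted(city.boundaries):
        feats.append(_feature(city.boundaries[metro],
                              {"role": "boundary", "metro": metro}))
    _dump({"type": "FeatureCollection", "features": feats}, path)


def write_tracts_geojson(tracts: list[Tract], path) -> None:
    feats = [_feature(t.geometry, {"tract_id": t.tract_id, **t.metrics})
             for t in tracts]
    _dump({"type": "FeatureCollection", "features": feats}, path)


def _dump(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True,
                                     separators=(",", ":")) + "\n")


def read_holc_geojson(path) -> CityLayer:
    """Read a HOLC layer file; tracts are loaded separately."""
    fc = json.loads(Path(path).read_text())
    holc, boundaries = [], {}
    for feat in fc["features"]:
        props = feat.get("properties", {})
        geom = shape(feat["geometry"])
        if props.get("role") == "boundary":
            boundaries[props["metro"]] = geom
        else:
            holc.append(GradedPolygon(polygon_id=props["polygon_id"],
                                      grade=props["grade"], geometry=geom,
                                      metro=props.get("metro", "")))
    ids = [p.polygon_id for p in holc]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate polygon_id in layer")
    return CityLayer(holc=holc, tracts=[], boundaries=boundaries)


def read_tracts_geojson(path) -> list[Tract]:
    fc = json.loads(Path(path).read_text())
    tracts = []
    for feat in fc["features"]:
        props = dict(feat.get("properties", {}))
        tid = props.pop("tract_id")
        tracts.append(Tract(tract_id=tid, geometry=shape(feat["geometry"]),
                            metrics=props))
    return tracts


def write_cohort_csv(births: pd.DataFrame, path) -> None:
    births.to_csv(path, index=False, float_format="%.6g",
                  lineterminator="\n")


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"birth_id": str})
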