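"""Core domain containers shared across the pipeline.

Polygon layers are lists of lightweight dataclasses wrapping shapely
geometries; tabular data (birth cohorts, overlap weights, areal-weighted
metrics) live in pandas DataFrames with documented column sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from shapely.geometry.base import BaseGeometry

#: HOLC security-map grades, best to worst, plus the "not graded" label.
GRADES = ("A", "B", "C", "D", "NG")

#: Grades eligible for adjacent-grade contrasts (NG is descriptive only).
CONTRAST_GRADES = ("A", "B", "C", "D")

#: Count-valued 1940 census attributes carried on each tract.
TRACT_COUNT_FIELDS = (
    "total_pop",
    "white",
    "nonwhite",
    "foreign_born_white",
    "black",
    "employed",
    "total_homes",
    "homes_major_repairs",
    "homes_radio",
    "homes_no_radio",
    "homes_refrigerator",
    "homes_no_refrigerator",
    "homes_heating",
    "homes_no_heating",
    "edu_no_hs",
    "edu_hs",
    "edu_college",
    "housing_units",
)

#: Non-count tract attributes.
TRACT_VALUE_FIELDS = ("median_home_value",)

#: Derived per-neighborhood rates computed after areal apportionment.
DERIVED_RATE_FIELDS = (
    "pct_nonwhite",
    "pct_black",
    "pct_foreign_born_white",
    "pct_employed",
    "pct_radio",
    "pct_refrigerator",
    "pct_heating",
    "pct_major_repairs",
    "pct_hs_educated",
    "persons_per_housing_unit",
    "population_density",
)

#: Columns a birth-cohort DataFrame must carry.
BIRTH_COLUMNS = (
    "birth_id",
    "x",
    "y",
    "gest_age_days",
    "birth_weight_g",
    "sex",
    "death_age_days",
    "elective_abortion",
    "race",
    "maternal_age",
    "parity",
    "education",
    "payer",
    "metro",
    "birth_year",
)

#: The seven binary perinatal outcomes, primary then secondary.
PRIMARY_OUTCOMES = ("preterm", "lbw", "sga", "perinatal_mortality")
SECONDARY_OUTCOMES = ("very_preterm", "vlbw", "neonatal_mortality")
ALL_OUTCOMES = PRIMARY_OUTCOMES + SECONDARY_OUTCOMES


@dataclass
class GradedPolygon:
    """A HOLC neighborhood polygon: the exposure unit."""

    polygon_id: str
    grade: str
    geometry: BaseGeometry
    metro: str = ""

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise ValueError(f"unknown grade {self.grade!r} for {self.polygon_id}")


@dataclass
class Tract:
    """A 1940 census tract polygon with count-valued metrics attached.

    ``metrics`` maps field name -> value; it is empty until the metric
    generator (or a GeoJSON loader) fills it.
    """

    tract_id: str
    geometry: BaseGeometry
    metrics: dict = field(default_factory=dict)


@dataclass
class CityLayer:
    """Both polygon layers of a study area plus per-metro map boundaries.

    ``boundaries`` maps metro label -> boundary polygon; a point inside a
    boundary but in no graded polygon is "not graded" (NG), a point outside
    every boundary is off the map entirely.
    """

    holc: list[GradedPolygon]
    tracts: list[Tract]
    boundaries: dict[str, BaseGeometry]

    def holc_by_id(self) -> dict[str, GradedPolygon]:
        return {p.polygon_id: p for p in self.holc}

    def grades(self) -> dict[str, str]:
        return {p.polygon_id: p.grade for p in self.holc}
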