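"""Simulation configuration for the synthetic study.

``SimConfig`` pins down every knob of the synthetic city and birth cohort:
grid geometry, grade mix, grade-dependent 1940 census metric means,
grade-dependent maternal demographics, and the outcome model (baseline
log-odds, injected adjacent-grade effects, confounding through the
areal-weighted 1940 metrics).

Defaults describe a mid-sized three-metro study area of 200 HOLC
neighborhoods in which worse-graded neighborhoods have lower median home
value, more non-White residents, fewer radios/refrigerators and more homes
needing major repair, and mothers who are younger, more often Hispanic or
Black, and less often college-educated.  Injected grade effects default to
zero (a null city); analyses inject effects explicitly via
``grade_effect_logodds``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .types import CONTRAST_GRADES, GRADES

#: Labels of the three adjacent-grade contrasts (worse grade listed first).
CONTRAST_LABELS = ("B_vs_A", "C_vs_B", "D_vs_C")

#: Per-grade mean 1940 tract metrics.  Counts are per-tract means; ``frac_*``
#: entries are proportions applied to the relevant total; home value is in
#: thousands of 1940 dollars.
DEFAULT_METRIC_MEANS = {
    "A": dict(total_pop=3500, housing_units=1100, total_homes=1000,
              median_home_value=8.0, frac_nonwhite=0.03, frac_black=0.30,
              frac_foreign_born_white=0.12, frac_employed=0.48,
              frac_radio=0.95, frac_refrigerator=0.78, frac_heating=0.90,
              frac_major_repairs=0.030, frac_edu_no_hs=0.33,
              frac_edu_hs=0.45, frac_edu_college=0.22),
    "B": dict(total_pop=3800, housing_units=1150, total_homes=1050,
              median_home_value=6.5, frac_nonwhite=0.05, frac_black=0.35,
              frac_foreign_born_white=0.14, frac_employed=0.46,
              frac_radio=0.93, frac_refrigerator=0.70, frac_heating=0.85,
              frac_major_repairs=0.045, frac_edu_no_hs=0.40,
              frac_edu_hs=0.43, frac_edu_college=0.17),
    "C": dict(total_pop=4200, housing_units=1200, total_homes=1100,
              median_home_value=5.2, frac_nonwhite=0.08, frac_black=0.40,
              frac_foreign_born_white=0.18, frac_employed=0.44,
              frac_radio=0.90, frac_refrigerator=0.62, frac_heating=0.80,
              frac_major_repairs=0.065, frac_edu_no_hs=0.47,
              frac_edu_hs=0.40, frac_edu_college=0.13),
    "D": dict(total_pop=4500, housing_units=1200, total_homes=1100,
              median_home_value=4.1, frac_nonwhite=0.12, frac_black=0.45,
              frac_foreign_born_white=0.22, frac_employed=0.42,
              frac_radio=0.87, frac_refrigerator=0.54, frac_heating=0.74,
              frac_major_repairs=0.090, frac_edu_no_hs=0.53,
              frac_edu_hs=0.37, frac_edu_college=0.10),
    "NG": dict(total_pop=4000, housing_units=1150, total_homes=1050,
               median_home_value=5.5, frac_nonwhite=0.07, frac_black=0.40,
               frac_foreign_born_white=0.16, frac_employed=0.45,
               frac_radio=0.91, frac_refrigerator=0.64, frac_heating=0.81,
               frac_major_repairs=0.060, frac_edu_no_hs=0.45,
               frac_edu_hs=0.41, frac_edu_college=0.14),
}

#: Maternal covariate distributions per grade.  Race probabilities cover
#: (hispanic, nh_api, nh_black, nh_other, nh_white); education covers
#: (no_hs, hs, associates, bachelors, masters_plus, unknown); payer covers
#: (private, medical, other, oop, unknown).
DEFAULT_MATERNAL = {
    "A": dict(race=(0.121, 0.211, 0.051, 0.049, 0.568), age_mean=33.8,
              age_sd=5.2, parity_mean=0.8,
              education=(0.020, 0.167, 0.043, 0.383, 0.354, 0.032),
              payer=(0.849, 0.089, 0.018, 0.041, 0.003)),
    "B": dict(race=(0.359, 0.181, 0.074, 0.041, 0.346), age_mean=31.2,
              age_sd=6.2, parity_mean=1.0,
              education=(0.140, 0.301, 0.051, 0.274, 0.205, 0.029),
              payer=(0.626, 0.327, 0.009, 0.036, 0.002)),
    "C": dict(race=(0.578, 0.138, 0.087, 0.027, 0.170), age_mean=28.8,
              age_sd=6.4, parity_mean=1.2,
              education=(0.296, 0.386, 0.043, 0.153, 0.095, 0.027),
              payer=(0.384, 0.572, 0.014, 0.028, 0.002)),
    "D": dict(race=(0.672, 0.097, 0.089, 0.026, 0.117), age_mean=28.2,
              age_sd=6.5, parity_mean=1.3,
              education=(0.365, 0.395, 0.036, 0.111, 0.068, 0.025),
              payer=(0.308, 0.653, 0.020, 0.016, 0.003)),
    "NG": dict(race=(0.567, 0.181, 0.046, 0.023, 0.183), age_mean=29.1,
               age_sd=6.3, parity_mean=1.1,
               education=(0.237, 0.404, 0.055, 0.183, 0.099, 0.021),
               payer=(0.460, 0.472, 0.024, 0.041, 0.002)),
}

RACE_LEVELS = ("hispanic", "nh_api", "nh_black", "nh_other", "nh_white")
EDUCATION_LEVELS = ("no_hs", "hs", "associates", "bachelors",
                    "masters_plus", "unknown")
PAYER_LEVELS = ("private", "medical", "other", "oop", "unknown")

#: Baseline log-odds of the outcome models.  ``very_preterm``, ``vlbw`` and
#: ``neonatal_mortality`` intercepts are conditional (on preterm, on LBW and
#: on perinatal death respectively); see the generator docs.
DEFAULT_BASE_LOGODDS = {
    "preterm": -2.376,            # ~8.5% marginal
    "very_preterm": -1.658,       # ~16% of preterm births
    "lbw": -3.320,                # ~3.5% among term births before coupling
    "vlbw": -1.992,               # ~12% of LBW births
    "perinatal_mortality": -5.293,  # ~0.5% before coupling
    "neonatal_mortality": 0.405,  # ~60% of perinatal deaths are neonatal
}

#: Cross-outcome couplings (log-odds added when the conditioning event
#: occurred) making short gestations lighter and riskier.
DEFAULT_COUPLINGS = {
    ("lbw", "preterm"): 2.5,
    ("vlbw", "very_preterm"): 1.5,
    ("perinatal_mortality", "preterm"): 1.5,
}

#: Log-odds of each outcome per unit of centered areal-weighted 1940 metric:
#: per thousand 1940 dollars of median home value and per percentage point
#: of non-White residents.  Applied to every outcome.
DEFAULT_CONFOUNDER_COEFS = {
    "median_home_value": -0.05,
    "pct_nonwhite": 0.012,
}

#: Relative births per unit area by grade (worse grades are denser).
DEFAULT_BIRTH_INTENSITY = {"A": 0.17, "B": 0.44, "C": 1.0, "D": 0.67,
                           "NG": 0.60}

#: Smooth within-grade heterogeneity of tract metric means: metric ->
#: (transform, sd, wealth_sign).  Each metric mean is modulated by a
#: Gaussian surface mixing a shared city-scale "wealth" field (sign given)
#: with a metric-specific independent field; ``log`` multiplies the mean by
#: exp(sd * field), ``logit`` shifts the fraction on the logit scale.
#: Real cities vary far more within a HOLC grade than adjacent grade means
#: differ, which is what gives adjacent-grade propensity distributions
#: their overlap.
FIELD_SPECS = {
    "median_home_value": ("log", 0.30, 1),
    "total_pop": ("log", 0.20, -1),
    "total_homes": ("log", 0.20, -1),
    "housing_units": ("log", 0.20, -1),
    "frac_nonwhite": ("logit", 0.55, -1),
    "frac_black": ("logit", 0.50, -1),
    "frac_foreign_born_white": ("logit", 0.50, -1),
    "frac_radio": ("logit", 0.50, 1),
    "frac_refrigerator": ("logit", 0.60, 1),
    "frac_heating": ("logit", 0.60, 1),
    "frac_major_repairs": ("logit", 0.60, -1),
    "frac_employed": ("logit", 0.30, 1),
    "frac_edu_college": ("logit", 0.50, 1),
    "frac_edu_no_hs": ("logit", 0.50, -1),
    "frac_edu_hs": ("logit", 0.20, 1),
}


def _check_probs(name: str, probs: dict | tuple, tol: float = 1e-9) -> None:
    vals = list(probs.values()) if isinstance(probs, dict) else list(probs)
    if any(v < 0 for v in vals):
        raise ValueError(f"{name} has negative entries")
    if abs(sum(vals) - 1.0) > tol:
        raise ValueError(f"{name} must sum to 1 (got {sum(vals)!r})")


@dataclass
class SimConfig:
    """All parameters of the synthetic city and cohort.

    Distances are in arbitrary planar units with HOLC cells of size 1x1;
    ``tract_offset`` is the diagonal shift of the tract grid and must lie
    strictly between 0 and 1 so the two tessellations genuinely misalign.
    """

    seed: int = 0
    n_cols: int = 20
    n_rows: int = 10
    grade_probs: dict = field(default_factory=lambda: {
        "A": 0.10, "B": 0.20, "C": 0.35, "D": 0.30, "NG": 0.05})
    tract_offset: float = 0.5
    metric_means_by_grade: dict = field(
        default_factory=lambda: {g: dict(v) for g, v in
                                 DEFAULT_METRIC_MEANS.items()})
    metric_cv: float = 0.15
    spatial_sd: float = 1.0        # scale of the latent wealth field
    spatial_length: float = 3.0    # field correlation length, in cells
    n_births: int = 20_000
    outcome_base_logodds: dict = field(
        default_factory=lambda: dict(DEFAULT_BASE_LOGODDS))
    grade_effect_logodds: dict = field(default_factory=dict)
    confounder_coefs: dict = field(
        default_factory=lambda: dict(DEFAULT_CONFOUNDER_COEFS))
    maternal_coefs: dict = field(default_factory=dict)
    maternal_by_grade: dict = field(
        default_factory=lambda: {g: dict(v) for g, v in
                                 DEFAULT_MATERNAL.items()})
    outcome_couplings: dict = field(
        default_factory=lambda: dict(DEFAULT_COUPLINGS))
    birth_intensity_by_grade: dict = field(
        default_factory=lambda: dict(DEFAULT_BIRTH_INTENSITY))
    metro_shares: dict = field(
        default_factory=lambda: {"LA": 0.60, "OAK": 0.25, "SF": 0.15})
    frac_outside: float = 0.02
    frac_below_24wk: float = 0.005
    frac_missing_weight: float = 0.002
    frac_elective_abortion: float = 0.001
    sex_male_prob: float = 0.512

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_cols < 2 or self.n_rows < 2:
            raise ValueError("grid must be at least 2x2")
        _check_probs("grade_probs", self.grade_probs)
        if set(self.grade_probs) - set(GRADES):
            raise ValueError("grade_probs has unknown grades")
        for g, means in self.metric_means_by_grade.items():
            if any(v < 0 for v in means.values()):
                raise ValueError(f"negative metric mean for grade {g}")
        if any(v < 0 for v in self.birth_intensity_by_grade.values()):
            raise ValueError("negative birth intensity")
        for lab in self.grade_effect_logodds:
            if lab not in CONTRAST_LABELS:
                raise ValueError(f"unknown contrast label {lab!r}")
        if self.n_births < 0:
            raise ValueError("n_births must be non-negative")
        _check_probs("metro_shares", self.metro_shares, tol=1e-6)

    def effect(self, contrast: str, outcome: str) -> float:
        """Injected conditional log-odds for one contrast and outcome."""
        return float(self.grade_effect_logodds.get(contrast, {})
                     .get(outcome, 0.0))

    def cumulative_grade_effect(self, grade: str, outcome: str) -> float:
        """Total log-odds shift of ``grade`` relative to grade A.

        Adjacent-contrast effects accumulate down the grade ladder, so the
        conditional log-odds difference between the two grades of any
        contrast equals exactly the injected value for that contrast.
        NG carries no grade effect.
        """
        if grade not in CONTRAST_GRADES:
            return 0.0
        total = 0.0
        ladder = ["B_vs_A", "C_vs_B", "D_vs_C"]
        upto = {"A": 0, "B": 1, "C": 2, "D": 3}[grade]
        for lab in ladder[:upto]:
            total += self.effect(lab, outcome)
        return total

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # YAML-safe coupling keys
        d["outcome_couplings"] = {f"{a}|{b}": v for (a, b), v in
                                  self.outcome_couplings.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "outcome_couplings" in d:
            d["outcome_couplings"] = {
                tuple(k.split("|")): v
                for k, v in d["outcome_couplings"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
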