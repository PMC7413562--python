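"""End-to-end drivers: synthetic study -> analysis cohort -> estimates."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .apportion import apportion
from .assignment import apply_inclusion_flow, assign_grade
from .config import SimConfig
from .inference import AnalysisResult, run_full_analysis
from .outcomes import code_outcomes
from .synthetic import generate_study
from .types import ALL_OUTCOMES, CityLayer


@dataclass
class StudyData:
    """Everything downstream of generation: the analysis-ready inputs."""

    city: CityLayer
    cohort: pd.DataFrame        # flow-filtered, outcome-coded
    flow: pd.DataFrame
    metrics: pd.DataFrame       # areal-weighted, indexed by polygon_id
    grades: pd.Series


def prepare_study(config: SimConfig,
                  outcomes=ALL_OUTCOMES) -> StudyData:
    """Generate a synthetic study and take it through assignment,
    inclusion flow, areal apportionment and outcome coding."""
    city, births = generate_study(config)
    assignments = assign_grade(births, city)
    cohort, flow = apply_inclusion_flow(births, assignments,
                                        outcomes=outcomes)
    cohort = code_outcomes(cohort)
    metrics = apportion(city.holc, city.tracts)
    grades = pd.Series(city.grades(), name="grade")
    return StudyData(city=city, cohort=cohort, flow=flow, metrics=metrics,
                     grades=grades)


def run_study(config: SimConfig, seed: int | None = None,
              outcomes=ALL_OUTCOMES, strata=("metro",),
              trim: bool = True, sensitivity: bool = False,
              k_folds: int = 10) -> tuple[StudyData, AnalysisResult]:
    """Full pipeline: simulate, prepare, match, and estimate.

    ``seed`` controls fold assignment in the propensity ensemble and
    defaults to the simulation seed.
    """
    data = prepare_study(config, outcomes=outcomes)
    seed = config.seed if seed is None else seed
    analysis = run_full_analysis(data.metrics, data.grades, data.cohort,
                                 seed=seed, outcomes=outcomes,
                                 strata=strata, trim=trim,
                                 sensitivity=sensitivity, k_folds=k_folds)
    return data, analysis
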