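"""Coding of the seven binary perinatal outcomes.

Definitions (gestational age in days, weight in grams):

* preterm / very preterm: live birth before 259 / 224 days (37 / 32
  completed weeks), among births at or beyond 168 days (24 weeks);
* LBW / VLBW: birth weight under 2500 / 1500 g;
* SGA: weight strictly below the sex-specific 10th percentile of weight
  for the completed gestational week, against a reference table;
* perinatal mortality: any recorded death that is not an elective
  abortion; neonatal mortality: death before 28 completed days of life.

The SGA reference can be loaded from a user-supplied ``(sex, week,
p10_grams)`` CSV or built empirically from a cohort: per-cell linear-
interpolation 10th percentiles, made monotone across weeks by isotonic
adjustment, with under-filled cells (< 100 births) unsupported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

PRETERM_DAYS = 259
VERY_PRETERM_DAYS = 224
LBW_GRAMS = 2500
VLBW_GRAMS = 1500
NEONATAL_DAYS = 28
MIN_DAYS = 168
SGA_WEEKS = range(24, 43)
MIN_CELL = 100


def _as_array(x):
    return np.atleast_1d(np.asarray(x, dtype=float))


def code_gestational(gest_age_days):
    """(preterm, very_preterm) flags; refuses gestations under 24 weeks."""
    d = _as_array(gest_age_days)
    if np.nanmin(d) < MIN_DAYS:
        raise ValueError("gestation under 168 days: record should have "
                         "been excluded upstream")
    preterm = d < PRETERM_DAYS
    very = d < VERY_PRETERM_DAYS
    if np.isscalar(gest_age_days):
        return bool(preterm[0]), bool(very[0])
    return preterm, very


def code_weight(birth_weight_g, gest_age_days):
    """(lbw, vlbw) flags; missing weight yields missing flags (NaN)."""
    w = _as_array(birth_weight_g)
    d = _as_array(gest_age_days)
    if np.nanmin(d) < MIN_DAYS:
        raise ValueError("gestation under 168 days: record should have "
                         "been excluded upstream")
    lbw = np.where(np.isnan(w), np.nan, (w < LBW_GRAMS).astype(float))
    vlbw = np.where(np.isnan(w), np.nan, (w < VLBW_GRAMS).astype(float))
    if np.isscalar(birth_weight_g):
        return (np.nan, np.nan) if np.isnan(lbw[0]) else (bool(lbw[0]),
                                                          bool(vlbw[0]))
    return lbw, vlbw


def code_mortality(death_age_days, elective_abortion, gest_age_days=None):
    """(perinatal, neonatal) flags.

    Perinatal mortality is any recorded death excluding elective
    abortions; neonatal mortality additionally requires death before 28
    completed days.
    """
    scalar = death_age_days is None or np.isscalar(death_age_days)
    if death_age_days is None:
        death_age_days = np.nan
    d = _as_array(death_age_days)
    el = np.atleast_1d(np.asarray(elective_abortion, dtype=bool))
    perinatal = np.isfinite(d) & ~el
    neonatal = perinatal & (d < NEONATAL_DAYS)
    if scalar:
        return bool(perinatal[0]), bool(neonatal[0])
    return perinatal, neonatal


@dataclass
class SgaReference:
    """Sex-specific 10th-percentile weight per completed gestational week.

    ``table`` maps (sex, week) -> grams; unsupported cells are absent.
    """

    table: dict = field(default_factory=dict)

    def lookup(self, sex, week):
        return self.table.get((sex, int(week)), np.nan)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sex": s, "week": w, "p10_grams": v}
                for (s, w), v in sorted(self.table.items())]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path) -> "SgaReference":
        df = pd.read_csv(path)
        return cls({(r.sex, int(r.week)): float(r.p10_grams)
                    for r in df.itertuples()})


def build_sga_reference(cohort: pd.DataFrame,
                        min_cell: int = MIN_CELL) -> SgaReference:
    """Empirical sex/week 10th percentiles from a coded-ready cohort.

    Uses the linear-interpolation quantile; percentiles are made
    non-decreasing across weeks within sex by isotonic regression and then
    strictly increasing by a microscopic (1e-6 g) tie-break, so the
    reference is a valid strictly-monotone growth curve.  Cells with fewer
    than ``min_cell`` births are unsupported.
    """
    ok = cohort["birth_weight_g"].notna() & cohort["gest_age_days"].notna()
    df = cohort.loc[ok, ["sex", "gest_age_days", "birth_weight_g"]].copy()
    df["week"] = (df["gest_age_days"] // 7).astype(int)
    table = {}
    for sex in sorted(df["sex"].unique()):
        sub = df[df["sex"] == sex]
        weeks, p10 = [], []
        for week in SGA_WEEKS:
            w = sub.loc[sub["week"] == week, "birth_weight_g"]
            if len(w) >= min_cell:
                weeks.append(week)
                p10.append(float(np.quantile(w, 0.10)))
        if not weeks:
            continue
        iso = IsotonicRegression(increasing=True).fit_transform(weeks, p10)
        for i in range(1, len(iso)):
            if iso[i] <= iso[i - 1]:
                iso[i] = iso[i - 1] + 1e-6
        table.update({(sex, wk): float(v) for wk, v in zip(weeks, iso)})
    return SgaReference(table)


def code_sga(birth_weight_g, sex, gest_age_days, ref: SgaReference):
    """SGA flag: weight strictly below the cell's 10th percentile.

    Unsupported (sex, week) cells or missing weight yield NaN.
    """
    w = _as_array(birth_weight_g)
    d = _as_array(gest_age_days)
    sexes = np.atleast_1d(np.asarray(sex, dtype=object))
    weeks = (d // 7).astype(int)
    cut = np.array([ref.lookup(s, wk) for s, wk in zip(sexes, weeks)])
    out = np.where(np.isnan(w) | np.isnan(cut), np.nan,
                   (w < cut).astype(float))
    if np.isscalar(birth_weight_g):
        return np.nan if np.isnan(out[0]) else bool(out[0])
    return out


def code_outcomes(cohort: pd.DataFrame,
                  ref: SgaReference | None = None) -> pd.DataFrame:
    """Append the seven outcome flag columns to a flow-filtered cohort.

    Flags are floats with NaN for missing; the implication lattice
    (very_preterm => preterm, vlbw => lbw, neonatal => perinatal) holds by
    definition.  If no SGA reference is given one is built from the cohort
    itself.
    """
    if ref is None:
        ref = build_sga_reference(cohort)
    out = cohort.copy()
    pt, vpt = code_gestational(out["gest_age_days"].to_numpy())
    out["preterm"] = pt.astype(float)
    out["very_preterm"] = vpt.astype(float)
    lbw, vlbw = code_weight(out["birth_weight_g"].to_numpy(),
                            out["gest_age_days"].to_numpy())
    out["lbw"] = lbw
    out["vlbw"] = vlbw
    out["sga"] = code_sga(out["birth_weight_g"].to_numpy(),
                          out["sex"].to_numpy(),
                          out["gest_age_days"].to_numpy(), ref)
    pm, nn = code_mortality(out["death_age_days"].to_numpy(),
                            out["elective_abortion"].to_numpy())
    out["perinatal_mortality"] = pm.astype(float)
    out["neonatal_mortality"] = nn.astype(float)
    return out
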