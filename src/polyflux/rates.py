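"""Growth and consumption/release (CORE) rate estimation from culture data.

Cells in batch culture grow exponentially, N(t) = N0 * exp(mu * t).  The
specific exchange rate of a metabolite follows from the net concentration
change in the supernatant divided by the biomass-time integral:

    q = dC [mM] * V [L] / ( AUC [cell*h] * w [gDW/cell] )   [mmol/gDW/hr]

with AUC the area under the (fitted) cell-number curve between the two
sampling times.  Secretion is positive, consumption negative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError

log = logging.getLogger(__name__)

#: default dry mass of one T cell, grams (configurable; ~30 pg/cell)
DEFAULT_DRY_WEIGHT_PER_CELL = 30e-12


@dataclass
class GrowthMeasurement:
    """Cell counts of one culture at >= 2 timepoints."""

    sample_id: str
    condition: str
    timepoints: list[float]  # hours
    counts: list[float]  # cells per culture
    culture_volume: float  # liters
    dry_weight_per_cell: float = DEFAULT_DRY_WEIGHT_PER_CELL  # grams

    def validate(self) -> None:
        v = []
        t, c = np.asarray(self.timepoints, float), np.asarray(self.counts, float)
        if len(t) < 2:
            v.append("need at least 2 timepoints")
        if len(t) != len(c):
            v.append("timepoints and counts differ in length")
        if np.any(np.diff(t) <= 0):
            v.append("timepoints must be strictly increasing")
        if np.any(c <= 0):
            v.append("counts must be positive")
        if self.culture_volume <= 0:
            v.append("culture_volume must be positive")
        if self.dry_weight_per_cell <= 0:
            v.append("dry_weight_per_cell must be positive")
        if v:
            raise ValidationError([f"growth {self.sample_id}: {x}" for x in v])


@dataclass
class SupernatantTimeCourse:
    """Concentrations (mM) of one metabolite in one culture's supernatant."""

    sample_id: str
    metabolite_id: str
    timepoints: list[float]  # hours
    concentrations: list[float]  # mM

    def validate(self) -> None:
        v = []
        if len(self.timepoints) < 2:
            v.append("need at least 2 timepoints")
        if any(c < 0 for c in self.concentrations):
            v.append("concentrations must be non-negative")
        if v:
            raise ValidationError(
                [f"timecourse {self.sample_id}/{self.metabolite_id}: {x}" for x in v]
            )


@dataclass
class ExchangeRateSet:
    """Specific exchange rates per metabolite (mmol/gDW/hr, secretion > 0).

    ``sem`` holds the standard error of the mean across replicates on
    condition-level aggregates (empty on per-sample sets).
    """

    sample_id: str
    condition: str
    rates: dict[str, float]
    sem: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        v = []
        for m, q in self.rates.items():
            if not math.isfinite(q):
                v.append(f"rate for {m!r} not finite")
        for m, s in self.sem.items():
            if s < 0:
                v.append(f"sem for {m!r} negative")
        if v:
            raise ValidationError(v)


def fit_growth_rate(g: GrowthMeasurement) -> float:
    """Specific growth rate mu (per hour) from an exponential fit.

    Two timepoints give the closed form ln(N2/N1)/(t2-t1); more give the
    least-squares slope of ln(counts) against time.  mu may be <= 0.
    """
    g.validate()
    t = np.asarray(g.timepoints, float)
    logn = np.log(np.asarray(g.counts, float))
    if len(t) == 2:
        return float((logn[1] - logn[0]) / (t[1] - t[0]))
    slope, _ = np.polyfit(t, logn, 1)
    return float(slope)


def _log_intercept(g: GrowthMeasurement, mu: float) -> float:
    """ln N at t=0 of the fitted exponential through the counts."""
    t = np.asarray(g.timepoints, float)
    logn = np.log(np.asarray(g.counts, float))
    return float(np.mean(logn - mu * t))


def cell_number_auc(g: GrowthMeasurement, mu: float, t1: float, t2: float) -> float:
    """Area under the fitted cell-number curve on [t1, t2], in cell*hours.

    Under N(t) = N0 exp(mu t) this is (N(t2) - N(t1)) / mu, with the
    continuous limit N * (t2 - t1) as mu -> 0.
    """
    if not t1 < t2:
        raise ValidationError(f"need t1 < t2, got ({t1}, {t2})")
    g.validate()
    a = _log_intercept(g, mu)
    if abs(mu) < 1e-12:
        return float(math.exp(a) * (t2 - t1))
    return float((math.exp(a + mu * t2) - math.exp(a + mu * t1)) / mu)


def cell_number_auc_trapezoid(g: GrowthMeasurement, t1: float, t2: float) -> float:
    """Trapezoidal AUC over the raw counts (fallback for non-exponential growth)."""
    t = np.asarray(g.timepoints, float)
    c = np.asarray(g.counts, float)
    grid = np.unique(np.clip(np.concatenate([[t1, t2], t]), t1, t2))
    vals = np.interp(grid, t, c)
    return float(np.trapezoid(vals, grid))


def estimate_exchange_rate(
    tc: SupernatantTimeCourse,
    g: GrowthMeasurement,
    mu: float | None = None,
    auc_method: str = "exponential",
) -> float:
    """Specific exchange rate (mmol/gDW/hr) of one metabolite for one sample.

    Net concentration change between the first and last supernatant
    timepoints, converted to mmol via the culture volume, divided by the
    grams-dry-weight-hours accumulated over the same window.  Sign follows
    the concentration change: secretion positive, consumption negative.
    """
    tc.validate()
    g.validate()
    if mu is None:
        mu = fit_growth_rate(g)
    t1, t2 = float(tc.timepoints[0]), float(tc.timepoints[-1])
    d_conc = float(tc.concentrations[-1]) - float(tc.concentrations[0])
    if auc_method == "trapezoid":
        auc = cell_number_auc_trapezoid(g, t1, t2)
    else:
        auc = cell_number_auc(g, mu, t1, t2)
    gdw_hours = auc * g.dry_weight_per_cell
    if gdw_hours <= 0:
        raise DegenerateInputError(
            f"zero biomass-time integral on [{t1}, {t2}] for {tc.sample_id}"
        )
    return d_conc * g.culture_volume / gdw_hours


def estimate_sample_rates(
    g: GrowthMeasurement,
    timecourses: list[SupernatantTimeCourse],
    auc_method: str = "exponential",
) -> tuple[float, ExchangeRateSet]:
    """Fit mu and compute every metabolite's exchange rate for one sample."""
    mu = fit_growth_rate(g)
    rates = {
        tc.metabolite_id: estimate_exchange_rate(tc, g, mu, auc_method=auc_method)
        for tc in timecourses
    }
    rs = ExchangeRateSet(sample_id=g.sample_id, condition=g.condition, rates=rates)
    rs.validate()
    return mu, rs


def aggregate_condition_rates(rate_sets: list[ExchangeRateSet]) -> ExchangeRateSet:
    """Condition-level mean and SEM (sd/sqrt(n)) per metabolite.

    Requires >= 2 replicates of a single condition; metabolites missing from
    any replicate are dropped with a warning.
    """
    if len(rate_sets) < 2:
        raise ValidationError("need >= 2 replicate samples to aggregate")
    conditions = {rs.condition for rs in rate_sets}
    if len(conditions) != 1:
        raise ValidationError(f"mixed conditions in aggregate: {sorted(conditions)}")
    common = set(rate_sets[0].rates)
    union = set(rate_sets[0].rates)
    for rs in rate_sets[1:]:
        common &= set(rs.rates)
        union |= set(rs.rates)
    for m in sorted(union - common):
        log.warning("metabolite %r missing from some replicates; dropped", m)
    n = len(rate_sets)
    rates, sem = {}, {}
    for m in sorted(common):
        vals = np.array([rs.rates[m] for rs in rate_sets])
        rates[m] = float(vals.mean())
        sem[m] = float(vals.std(ddof=1) / np.sqrt(n))
    out = ExchangeRateSet(
        sample_id=f"{rate_sets[0].condition}_aggregate",
        condition=rate_sets[0].condition, rates=rates, sem=sem,
    )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# CSV interfaces
# counts:          sample_id, condition, time_h, cells
# concentrations:  sample_id, metabolite, time_h, conc_mM
# rates out:       condition, metabolite, rate_mmol_gDW_h, sem


def read_growth_csv(path, culture_volume: float,
                    dry_weight_per_cell: float = DEFAULT_DRY_WEIGHT_PER_CELL
                    ) -> dict[str, GrowthMeasurement]:
    df = pd.read_csv(path)
    out = {}
    for sid, grp in df.groupby("sample_id"):
        grp = grp.sort_values("time_h")
        out[str(sid)] = GrowthMeasurement(
            sample_id=str(sid), condition=str(grp["condition"].iloc[0]),
            timepoints=grp["time_h"].tolist(), counts=grp["cells"].tolist(),
            culture_volume=culture_volume, dry_weight_per_cell=dry_weight_per_cell,
        )
    return out


def read_concentration_csv(path) -> dict[str, list[SupernatantTimeCourse]]:
    df = pd.read_csv(path)
    out: dict[str, list[SupernatantTimeCourse]] = {}
    for (sid, met), grp in df.groupby(["sample_id", "metabolite"]):
        grp = grp.sort_values("time_h")
        out.setdefault(str(sid), []).append(
            SupernatantTimeCourse(
                sample_id=str(sid), metabolite_id=str(met),
                timepoints=grp["time_h"].tolist(),
                concentrations=grp["conc_mM"].tolist(),
            )
        )
    return out


def write_rates_csv(path, rate_sets: list[ExchangeRateSet]) -> None:
    rows = [
        {"condition": rs.condition, "sample_id": rs.sample_id, "metabolite": m,
         "rate_mmol_gDW_h": q, "sem": rs.sem.get(m, float("nan"))}
        for rs in rate_sets for m, q in sorted(rs.rates.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rates_csv(path) -> list[ExchangeRateSet]:
    df = pd.read_csv(path)
    out = []
    for (cond, sid), grp in df.groupby(["condition", "sample_id"]):
        rates = dict(zip(grp["metabolite"], grp["rate_mmol_gDW_h"]))
        sem = {
            m: float(s) for m, s in zip(grp["metabolite"], grp["sem"])
            if math.isfinite(s)
        }
        out.append(ExchangeRateSet(sample_id=str(sid), condition=str(cond),
                                   rates=rates, sem=sem))
    return out
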