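"""Cohort relative survival (Ederer-2) and Weibull mixture-cure fitting.

Relative survival RS(t) is the ratio of the observed actuarial cumulative
survival of the patient cohort to the cumulative expected survival of a
comparable general-population group. Expected survival follows the Ederer-2
convention: at each annual interval the expected probability is averaged
over the patients still at risk at the interval start, matched on sex,
attained age and calendar year.

The cure model is RS(t) = c + (1 - c) * exp(-(lambda * t) ** gamma): a
fraction ``c`` experiences no excess mortality, the rest have Weibull excess
time-to-death. It is fitted to annual cumulative RS by weighted nonlinear
least squares (inverse-variance weights) with a small multistart grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date
from itertools import product
from typing import Iterable

import numpy as np
from scipy.optimize import least_squares

from previndex.registry import (
    LifeTable,
    PatientRecord,
    completed_years,
    ltfu_age_band,
    period_of,
)

logger = logging.getLogger(__name__)

#: band scheme used when no cancer-specific strata are configured
DEFAULT_BANDS = "0-59/60-74/75+"


@dataclass
class SurvivalCurve:
    """Annual cumulative relative survival for one stratum."""

    sex: str
    site: str
    age_band: str
    period: int | None
    t: np.ndarray  # 1..T (years since diagnosis)
    rs: np.ndarray
    se: np.ndarray
    n_risk: np.ndarray  # at risk entering each interval
    n_patients: int


@dataclass
class CureModelParams:
    """Fitted Weibull mixture-cure parameters for one stratum."""

    sex: str
    site: str
    age_band: str
    cure_fraction: float
    shape: float
    scale: float
    converged: bool
    ssr: float

    def to_dict(self) -> dict:
        return {
            "sex": self.sex, "site": self.site, "age_band": self.age_band,
            "cure_fraction": self.cure_fraction, "shape": self.shape,
            "scale": self.scale, "converged": self.converged, "ssr": self.ssr,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CureModelParams":
        return cls(
            sex=d["sex"], site=d["site"], age_band=d["age_band"],
            cure_fraction=float(d["cure_fraction"]), shape=float(d["shape"]),
            scale=float(d["scale"]), converged=bool(d["converged"]),
            ssr=float(d["ssr"]),
        )


def predict_relative_survival(params: CureModelParams, t) -> np.ndarray:
    """Evaluate the mixture-cure relative survival at time(s) ``t`` (years)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    c, g, lam = params.cure_fraction, params.shape, params.scale
    out = c + (1.0 - c) * np.exp(-((lam * t) ** g))
    return float(out) if out.ndim == 0 else out


def _band_of(age_dx: int, bands: str) -> str:
    if bands == "all":
        return "all"
    if bands == DEFAULT_BANDS:
        return ltfu_age_band(age_dx)
    raise ValueError(f"unknown band scheme {bands!r}")


def relative_survival_ederer2(
    records: Iterable[PatientRecord],
    life_table: LifeTable,
    max_time: int = 35,
    bands: str = DEFAULT_BANDS,
    by_period: bool = False,
    period_width: int = 5,
    min_patients: int = 10,
) -> list[SurvivalCurve]:
    """Ederer-2 cohort relative survival on annual intervals, per stratum.

    Strata are (sex, site, age band[, 5-year period of diagnosis]). Deaths
    use the actuarial estimator with withdrawals half-exposed; strata with
    fewer than ``min_patients`` are omitted with a warning.
    """
    groups: dict[tuple, list[PatientRecord]] = {}
    for r in records:
        key = (
            r.sex,
            r.site,
            _band_of(r.age_dx, bands),
            period_of(r.date_dx.year, period_width) if by_period else None,
        )
        groups.setdefault(key, []).append(r)

    curves: list[SurvivalCurve] = []
    for key in sorted(groups, key=str):
        recs = groups[key]
        if len(recs) < min_patients:
            logger.warning("stratum %s omitted: only %d patients", key, len(recs))
            continue
        curve = _ederer2_curve(recs, life_table, key, max_time)
        if curve is not None:
            curves.append(curve)
    return curves


def _ederer2_curve(
    recs: list[PatientRecord],
    life_table: LifeTable,
    key: tuple,
    max_time: int,
) -> SurvivalCurve | None:
    sex = key[0]
    dead = np.array([r.vital_status == "dead" for r in recs])
    age_dx = np.array([r.age_dx for r in recs])
    year_dx = np.array([r.date_dx.year for r in recs])

    t_exit = np.array([completed_years(r.date_dx, r.date_end) for r in recs])
    T = int(min(max_time, t_exit.max() + 1))
    if T < 1:
        return None
    os_cum, es_cum = 1.0, 1.0
    rs = np.empty(T)
    se = np.empty(T)
    n_risk = np.empty(T, dtype=int)
    greenwood = 0.0
    for t in range(T):
        at_risk = t_exit >= t
        n_t = int(at_risk.sum())
        n_risk[t] = n_t
        if n_t == 0:
            rs, se, n_risk = rs[:t], se[:t], n_risk[:t]
            break
        deaths = int((dead & (t_exit == t)).sum())
        withdrawals = int(((~dead) & (t_exit == t)).sum())
        eff = n_t - withdrawals / 2.0
        q = deaths / eff if eff > 0 else 0.0
        os_cum *= max(1.0 - q, 0.0)
        exp_p = float(
            np.mean(
                life_table.annual_survival(sex, age_dx[at_risk] + t, year_dx[at_risk] + t)
            )
        )
        es_cum *= exp_p
        if eff > deaths and deaths > 0:
            greenwood += deaths / (eff * (eff - deaths))
        rs[t] = os_cum / es_cum if es_cum > 0 else np.nan
        se[t] = (os_cum * math.sqrt(greenwood)) / es_cum if es_cum > 0 else np.nan
    if len(rs) == 0:
        return None
    return SurvivalCurve(
        sex=sex, site=key[1], age_band=key[2], period=key[3],
        t=np.arange(1, len(rs) + 1, dtype=float),
        rs=rs, se=se, n_risk=n_risk, n_patients=len(recs),
    )


# multistart grid for the cure fit; paper-silent robustness choice
_STARTS = list(product((0.1, 0.5, 0.9), (0.5, 1.0, 2.0), (0.1, 0.5, 1.0)))
_BOUNDS = ([0.0, 0.05, 1e-4], [1.0, 10.0, 10.0])


class CureFitError(RuntimeError):
    """The mixture-cure fit failed to converge from every start."""


def fit_weibull_cure(curve: SurvivalCurve, min_points: int = 5) -> CureModelParams:
    """Weighted nonlinear least-squares fit of the mixture-cure model.

    Weights are inverse variances of RS(t); intervals with zero standard
    error (no deaths yet) get the weight of the smallest positive one.
    """
    t, rs, se = curve.t, curve.rs, curve.se
    ok = np.isfinite(rs) & np.isfinite(se)
    t, rs, se = t[ok], rs[ok], se[ok]
    if len(t) < min_points:
        raise CureFitError(
            f"stratum ({curve.sex}, {curve.site}, {curve.age_band}): "
            f"only {len(t)} usable RS points (< {min_points})"
        )
    pos = se[se > 0]
    floor = pos.min() if len(pos) else 1.0
    w = 1.0 / np.maximum(se, floor) ** 2
    sw = np.sqrt(w / w.max())

    def resid(p):
        c, g, lam = p
        return sw * (c + (1.0 - c) * np.exp(-((lam * t) ** g)) - rs)

    best = None
    for start in _STARTS:
        try:
            res = least_squares(resid, start, bounds=_BOUNDS, xtol=1e-12, ftol=1e-12)
        except ValueError:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise CureFitError(
            f"cure model did not converge for stratum "
            f"({curve.sex}, {curve.site}, {curve.age_band})"
        )
    c, g, lam = best.x
    return CureModelParams(
        sex=curve.sex, site=curve.site, age_band=curve.age_band,
        cure_fraction=float(c), shape=float(g), scale=float(lam),
        converged=True, ssr=float(2.0 * best.cost),
    )


def fit_cure_by_band(
    records: Iterable[PatientRecord],
    life_table: LifeTable,
    max_time: int = 35,
    bands: str = DEFAULT_BANDS,
    pooled_fallback: bool = True,
) -> dict[tuple[str, str, str], CureModelParams]:
    """Fit cure models per (sex, site, age band); failed strata are skipped.

    With ``pooled_fallback`` an additional all-ages fit per (sex, site) is
    stored under band ``"all"``, used downstream when a band's own fit is
    missing or did not converge.
    """
    out: dict[tuple[str, str, str], CureModelParams] = {}
    band_sets = [bands] + (["all"] if pooled_fallback and bands != "all" else [])
    for scheme in band_sets:
        for curve in relative_survival_ederer2(records, life_table, max_time, scheme):
            try:
                params = fit_weibull_cure(curve)
            except CureFitError as exc:
                logger.warning("%s", exc)
                continue
            out[(curve.sex, curve.site, curve.age_band)] = params
    return out
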