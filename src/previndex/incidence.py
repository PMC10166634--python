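"""Logistic age-cohort incidence models.

Incidence rates by 5-year age group and 5-year period of diagnosis are fit
with binomial logistic regression on an age term plus nonparametric 10-year
birth-cohort effects (reference cohort coefficient fixed at 0). The age
dependence is either log-linear on the logit scale ("exponential") or a
six-degree polynomial in a centred and scaled age variable; models are
compared by AIC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from previndex.registry import (
    PatientRecord,
    PopulationTable,
    assign_age_group,
    ages_in_group,
    group_labels,
    parse_age_group,
    MODEL_SCHEME,
)

logger = logging.getLogger(__name__)

AGE_FORMS = ("exponential", "poly6")


@dataclass
class IncidenceTable:
    """Case counts and person-year denominators per modelling cell."""

    df: pd.DataFrame  # sex site age_group period_start count person_years

    def __post_init__(self):
        required = {"sex", "site", "age_group", "period_start", "count",
                    "person_years"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"incidence table missing columns: {sorted(missing)}")
        if (self.df["count"] > self.df["person_years"]).any():
            raise ValueError("incidence counts exceed person-year denominators")

    def with_midpoints(self) -> pd.DataFrame:
        df = self.df.copy()
        mids = []
        for g in df["age_group"]:
            lo, hi = parse_age_group(g)
            mids.append(lo + 2.5 if hi is None else (lo + hi + 1) / 2.0)
        df["age_mid"] = mids
        df["period_mid"] = df["period_start"] + 2.5
        df["cohort"] = df["period_mid"] - df["age_mid"]
        return df


def tabulate_incidence(
    records: Iterable[PatientRecord],
    population: PopulationTable,
    year_range: tuple[int, int],
    period_width: int = 5,
    period_anchor: int = 1980,
    grouping: str = MODEL_SCHEME,
) -> IncidenceTable:
    """Cross-tabulate diagnoses and person-years by age group and period.

    ``year_range`` is the inclusive (first, last) calendar-year window of
    registration; diagnoses and denominators outside it are excluded.
    """
    y0, y1 = year_range
    counts: dict[tuple[str, str, str, int], int] = {}
    sites = set()
    sexes = set()
    for r in records:
        y = r.date_dx.year
        if not y0 <= y <= y1:
            continue
        period = period_anchor + ((y - period_anchor) // period_width) * period_width
        key = (r.sex, r.site, assign_age_group(r.age_dx, grouping), period)
        counts[key] = counts.get(key, 0) + 1
        sites.add(r.site)
        sexes.add(r.sex)

    first = period_anchor + ((y0 - period_anchor) // period_width) * period_width
    periods = list(range(first, y1 + 1, period_width))
    rows = []
    for sex in sorted(sexes):
        for site in sorted(sites):
            for g in group_labels(grouping):
                ages = ages_in_group(g, population.max_age)
                for p in periods:
                    years = [y for y in range(p, p + period_width) if y0 <= y <= y1]
                    py = population.person_years(sex, ages, years)
                    if py <= 0:
                        continue
                    rows.append(
                        (sex, site, g, p, counts.get((sex, site, g, p), 0), py)
                    )
    return IncidenceTable(
        pd.DataFrame(
            rows,
            columns=["sex", "site", "age_group", "period_start", "count",
                     "person_years"],
        )
    )


@dataclass
class IncidenceModelParams:
    """Fitted logistic age-cohort model for one (sex, site)."""

    sex: str
    site: str
    age_form: str
    age_coefs: np.ndarray  # intercept + age term(s) on scaled age
    age_center: float
    age_scale: float
    cohort_decades: np.ndarray  # sorted decade start years; first is reference
    cohort_coefs: np.ndarray  # aligned with cohort_decades; first is 0
    llf: float
    aic: float
    deviance: float
    n_params: int
    bse: np.ndarray | None = None
    converged: bool = True

    def linear_predictor(self, age, cohort_year) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        x = (age - self.age_center) / self.age_scale
        eta = np.zeros(np.broadcast(x, np.asarray(cohort_year)).shape, dtype=float)
        for k, b in enumerate(self.age_coefs):
            eta = eta + b * x**k
        dec = (np.asarray(cohort_year, dtype=int) // 10) * 10
        idx = np.clip(
            np.searchsorted(self.cohort_decades, dec, side="right") - 1,
            0, len(self.cohort_decades) - 1,
        )
        return eta + self.cohort_coefs[idx]

    def to_dict(self) -> dict:
        return {
            "sex": self.sex, "site": self.site, "age_form": self.age_form,
            "age_coefs": list(map(float, self.age_coefs)),
            "age_center": self.age_center, "age_scale": self.age_scale,
            "cohort_decades": list(map(int, self.cohort_decades)),
            "cohort_coefs": list(map(float, self.cohort_coefs)),
            "llf": self.llf, "aic": self.aic, "deviance": self.deviance,
            "n_params": self.n_params, "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IncidenceModelParams":
        return cls(
            sex=d["sex"], site=d["site"], age_form=d["age_form"],
            age_coefs=np.asarray(d["age_coefs"], dtype=float),
            age_center=float(d["age_center"]), age_scale=float(d["age_scale"]),
            cohort_decades=np.asarray(d["cohort_decades"], dtype=int),
            cohort_coefs=np.asarray(d["cohort_coefs"], dtype=float),
            llf=float(d["llf"]), aic=float(d["aic"]),
            deviance=float(d["deviance"]), n_params=int(d["n_params"]),
            converged=bool(d["converged"]),
        )


class IncidenceFitError(RuntimeError):
    pass


def fit_logistic_age_cohort(
    table: IncidenceTable, age_form: str = "poly6"
) -> list[IncidenceModelParams]:
    """Fit one logistic age-cohort model per (sex, site) in the table."""
    if age_form not in AGE_FORMS:
        raise ValueError(f"age_form must be one of {AGE_FORMS}")
    df = table.with_midpoints()
    out = []
    for (sex, site), sub in df.groupby(["sex", "site"]):
        try:
            out.append(_fit_one(sub, sex, site, age_form))
        except IncidenceFitError as exc:
            logger.warning("%s; stratum excluded", exc)
    return out


def _fit_one(sub: pd.DataFrame, sex: str, site: str, age_form: str) -> IncidenceModelParams:
    sub = sub[sub["person_years"] > 0].copy()
    if sub.empty:
        raise IncidenceFitError(f"no cells to fit for ({sex}, {site})")
    amin, amax = sub["age_mid"].min(), sub["age_mid"].max()
    center = (amin + amax) / 2.0
    scale = max((amax - amin) / 2.0, 1.0)
    x = (sub["age_mid"].to_numpy() - center) / scale
    degree = 1 if age_form == "exponential" else 6
    X_age = np.column_stack([x**k for k in range(degree + 1)])

    decades = np.sort(np.unique((sub["cohort"].to_numpy().astype(int) // 10) * 10))
    dec = (sub["cohort"].to_numpy().astype(int) // 10) * 10
    X_coh = np.zeros((len(sub), len(decades) - 1))
    for j, d in enumerate(decades[1:]):
        X_coh[:, j] = (dec == d).astype(float)

    X = np.column_stack([X_age, X_coh])
    y = sub["count"].to_numpy() / sub["person_years"].to_numpy()
    try:
        model = sm.GLM(
            y, X, family=sm.families.Binomial(),
            var_weights=sub["person_years"].to_numpy(),
        )
        fit = model.fit(maxiter=200)
    except Exception as exc:  # separation / perfect fit
        raise IncidenceFitError(f"logistic fit failed for ({sex}, {site}): {exc}")
    # empty corner cells can push fitted logits to ~ +/-100 harmlessly; only
    # catastrophic IRLS divergence (|eta| in the thousands) is rejected
    eta = X @ fit.params
    if not np.all(np.isfinite(fit.params)) or np.abs(eta).max() > 1e3:
        raise IncidenceFitError(
            f"diverged fit for ({sex}, {site}); "
            "likely separation in sparse cells"
        )
    if not getattr(fit, "converged", True):
        raise IncidenceFitError(f"IRLS did not converge for ({sex}, {site})")

    k = X.shape[1]
    cohort_coefs = np.concatenate([[0.0], fit.params[degree + 1:]])
    return IncidenceModelParams(
        sex=sex, site=site, age_form=age_form,
        age_coefs=np.asarray(fit.params[: degree + 1]),
        age_center=center, age_scale=scale,
        cohort_decades=decades, cohort_coefs=cohort_coefs,
        llf=float(fit.llf), aic=float(-2.0 * fit.llf + 2.0 * k),
        deviance=float(fit.deviance), n_params=k,
        bse=np.asarray(fit.bse), converged=bool(fit.converged),
    )


def predict_incidence(params: IncidenceModelParams, age, cohort_year) -> np.ndarray:
    """Predicted annual incidence rate in (0, 1).

    Cohorts outside the fitted range use the nearest estimated cohort effect
    (constant extrapolation).
    """
    out = expit(params.linear_predictor(age, cohort_year))
    return float(out) if out.ndim == 0 else out


def compare_aic(
    fits: Sequence[IncidenceModelParams],
) -> tuple[IncidenceModelParams, pd.DataFrame]:
    """Select the model with the lowest AIC; ties go to fewer parameters."""
    if not fits:
        raise ValueError("no fits to compare")
    table = pd.DataFrame(
        [
            {"sex": f.sex, "site": f.site, "age_form": f.age_form,
             "n_params": f.n_params, "llf": f.llf, "aic": f.aic}
            for f in fits
        ]
    )
    order = sorted(range(len(fits)), key=lambda i: (fits[i].aic, fits[i].n_params))
    return fits[order[0]], table
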