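"""Completeness indexes and complete-prevalence estimation.

The completeness index R at duration ``d`` is the ratio of limited-duration
prevalence to complete prevalence; complete prevalence is estimated by
dividing observed prevalence at the maximum available duration by the
corresponding R. Three interchangeable index sources are implemented:

- **empirical**: ratios of observed prevalent counts at two durations from a
  long-series prevalence table;
- **model**: reconstruction of prevalent mass from a fitted logistic
  age-cohort incidence model, a Weibull mixture-cure relative-survival model
  and general-population expected survival, accumulated over a lifelong
  yearly lookback;
- **external**: a pre-computed index table loaded from CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from previndex.incidence import IncidenceModelParams, predict_incidence
from previndex.registry import (
    EMPIRICAL_SCHEME,
    MODEL_SCHEME,
    LifeTable,
    PopulationTable,
    PrevalenceTable,
    assign_age_group,
    group_labels,
    ltfu_age_band,
)
from previndex.survival import CureModelParams, predict_relative_survival

logger = logging.getLogger(__name__)

_CLIP_TOL = 1e-9


class CompletenessIndexError(ValueError):
    pass


@dataclass
class CompletenessIndex:
    """R values in (0, 1] keyed by (sex, site, age group, duration).

    Duration ``d`` refers to ``d``-year limited-duration prevalence
    (completed durations strictly below ``d``).
    """

    method: str  # empirical | model | external
    index_date: date
    values: pd.DataFrame  # sex site age_group duration R
    grouping: str = MODEL_SCHEME

    def __post_init__(self):
        required = {"sex", "site", "age_group", "duration", "R"}
        missing = required - set(self.values.columns)
        if missing:
            raise ValueError(f"index table missing columns: {sorted(missing)}")
        bad = self.values[(self.values["R"] <= 0) | (self.values["R"] > 1 + _CLIP_TOL)]
        if len(bad):
            raise CompletenessIndexError(
                f"{len(bad)} R values outside (0,1]; first: {bad.iloc[0].to_dict()}"
            )
        self.values = self.values.copy()
        self.values["R"] = self.values["R"].clip(upper=1.0)
        self._check_monotone()
        self._lookup = {
            (r.sex, r.site, r.age_group, int(r.duration)): float(r.R)
            for r in self.values.itertuples(index=False)
        }

    def _check_monotone(self):
        viol = []
        for key, sub in self.values.groupby(["sex", "site", "age_group"]):
            r = sub.sort_values("duration")["R"].to_numpy()
            if np.any(np.diff(r) < -1e-9):
                viol.append(key)
        if viol:
            logger.warning(
                "R not non-decreasing in duration for %d cells: %s",
                len(viol), viol[:5],
            )

    def lookup(self, sex: str, site: str, age_group: str, duration: int) -> float | None:
        return self._lookup.get((sex, site, age_group, int(duration)))

    def max_duration(self) -> int:
        return int(self.values["duration"].max())


# ---------------------------------------------------------------------------
# empirical index
# ---------------------------------------------------------------------------

def empirical_R(
    prevalence: PrevalenceTable, max_duration: int | None = None
) -> CompletenessIndex:
    """Empirical R = N(<=d) / N(<=max_duration) from long-series prevalence.

    Uses the wide empirical age grouping (0-29, 5-year, 80+); cells with a
    zero denominator are omitted with a warning.
    """
    max_duration = prevalence.max_duration if max_duration is None else max_duration
    if max_duration > prevalence.max_duration:
        raise CompletenessIndexError(
            f"max_duration {max_duration} exceeds the table's "
            f"{prevalence.max_duration}"
        )
    prev = prevalence.regrouped(EMPIRICAL_SCHEME)
    denom = prev.cumulative(max_duration).set_index(["sex", "site", "age_group"])[
        "count"
    ]
    rows = []
    skipped = 0
    for d in range(1, max_duration + 1):
        num = prev.cumulative(d).set_index(["sex", "site", "age_group"])["count"]
        for key, nd in denom.items():
            if nd <= 0:
                skipped += 1
                continue
            rows.append((*key, d, float(num.get(key, 0.0)) / float(nd)))
    if skipped:
        logger.warning("empirical index: %d zero-denominator cells omitted", skipped)
    df = pd.DataFrame(rows, columns=["sex", "site", "age_group", "duration", "R"])
    df = df[df["R"] > 0]
    return CompletenessIndex(
        method="empirical",
        index_date=prevalence.index_date,
        values=df.reset_index(drop=True),
        grouping=EMPIRICAL_SCHEME,
    )


# ---------------------------------------------------------------------------
# model-based index
# ---------------------------------------------------------------------------

def _as_incidence_fn(inc) -> Callable:
    if isinstance(inc, IncidenceModelParams):
        return lambda age, cohort: predict_incidence(inc, age, cohort)
    return inc


def _as_survival_fn(cure) -> Callable:
    if isinstance(cure, Mapping):
        def fn(t, age_dx):
            band = ltfu_age_band(int(age_dx))
            params = cure.get(band) or cure.get("all")
            if params is None:
                raise CompletenessIndexError(
                    f"no converged survival fit for age band {band!r} "
                    "and no pooled fallback"
                )
            return predict_relative_survival(params, t)
        return fn
    if isinstance(cure, CureModelParams):
        return lambda t, age_dx: predict_relative_survival(cure, t)
    return cure


def model_based_R(
    incidence,
    cure,
    life_table: LifeTable,
    index_date: date,
    sex: str,
    site: str,
    durations: Iterable[int] = range(1, 36),
    a_min: int = 0,
    max_age: int = 99,
    population: PopulationTable | None = None,
    group: bool = True,
    grouping: str = MODEL_SCHEME,
) -> CompletenessIndex:
    """Model-based completeness index for one (sex, site).

    For each single age ``a`` at the index date, the modelled prevalent mass
    at duration up to ``d`` accumulates, over completed durations ``t``,
    incidence at age ``a - t - 1`` for the birth cohort ``index_year - a``,
    relative survival of the cure model at ``t + 1/2`` and expected
    (general-population) survival to the index date; complete prevalence
    uses the lifelong lookback to ``a_min``. R is the ratio of the two,
    optionally averaged over 5-year age groups with population weights.

    ``incidence`` is an :class:`IncidenceModelParams` or ``f(age, cohort)``;
    ``cure`` is a mapping age-band -> :class:`CureModelParams`, a single
    params object, or ``f(t, age_dx)``.
    """
    inc_fn = _as_incidence_fn(incidence)
    rs_fn = _as_survival_fn(cure)
    index_year = index_date.year
    durations = sorted(set(int(d) for d in durations))
    d_top = durations[-1]

    rows = []
    single: dict[int, np.ndarray] = {}  # age -> R at each requested duration
    for a in range(a_min + 1, max_age + 1):
        d_max = a - a_min  # lifelong lookback
        t = np.arange(d_max)  # completed durations
        age_dx = a - t - 1
        inc = np.array(
            [float(inc_fn(int(ad), index_year - a)) for ad in age_dx]
        )
        rs = np.array([float(rs_fn(ti + 0.5, int(ad))) for ti, ad in zip(t, age_dx)])
        sstar = _expected_survival_to_index(life_table, sex, a, t, index_year)
        mass = inc * rs * sstar
        cum = np.cumsum(mass)
        total = cum[-1]
        if total <= 0:
            continue
        r_at = np.array(
            [cum[min(d, d_max) - 1] / total for d in durations]
        )
        if np.any(r_at > 1 + _CLIP_TOL):
            raise CompletenessIndexError(
                f"model R exceeds 1 beyond tolerance at age {a}: max {r_at.max()}"
            )
        single[a] = np.clip(r_at, None, 1.0)

    if not group:
        for a, r_at in single.items():
            for d, r in zip(durations, r_at):
                rows.append((sex, site, str(a), d, r))
        df = pd.DataFrame(rows, columns=["sex", "site", "age_group", "duration", "R"])
        return CompletenessIndex("model", index_date, df, grouping="single_year")

    weights: dict[int, float] = {}
    if population is not None:
        w = population.single_age_counts(sex, index_year)
        for a in single:
            weights[a] = float(w[a]) if a < len(w) else 0.0
    for g in group_labels(grouping):
        ages = [a for a in single if assign_age_group(a, grouping) == g]
        if not ages:
            continue
        wsum = sum(weights.get(a, 1.0) for a in ages)
        if wsum <= 0:
            wts = {a: 1.0 for a in ages}
            wsum = float(len(ages))
        else:
            wts = {a: weights.get(a, 1.0) for a in ages}
        r_group = sum(single[a] * wts[a] for a in ages) / wsum
        for d, r in zip(durations, r_group):
            rows.append((sex, site, g, d, float(min(r, 1.0))))
    df = pd.DataFrame(rows, columns=["sex", "site", "age_group", "duration", "R"])
    return CompletenessIndex("model", index_date, df, grouping=grouping)


def _expected_survival_to_index(
    life_table: LifeTable, sex: str, a: int, t: np.ndarray, index_year: int
) -> np.ndarray:
    """Expected survival from (mid-year) diagnosis to the index date.

    For completed duration ``t`` the patient was diagnosed in calendar year
    ``index_year - t - 1`` at age ``a - t - 1`` (uniform within-year timing):
    ``t`` whole year-grid survival factors plus half the final year before
    the index date, approximated as ``(1 + p) / 2``.
    """
    out = np.empty(len(t))
    for i, ti in enumerate(t):
        age0 = a - ti - 1
        y0 = index_year - ti - 1
        js = np.arange(ti)
        s = float(
            np.prod(
                life_table.annual_survival(sex, np.maximum(age0 + js, 0), y0 + js)
            )
        )
        p_last = life_table.annual_survival(
            sex, max(age0 + ti, 0), y0 + ti
        )
        out[i] = s * (1.0 + p_last) / 2.0
    return out


# ---------------------------------------------------------------------------
# applying indexes
# ---------------------------------------------------------------------------

def complete_prevalence(
    prevalence: PrevalenceTable,
    index: CompletenessIndex,
    strict: bool = True,
) -> pd.DataFrame:
    """Complete prevalence per (sex, site, age group).

    Divides observed prevalence at the table's maximum duration by the
    corresponding R; the prevalence table is regrouped onto the index's age
    grouping when needed. Returns columns
    ``sex, site, age_group, observed, R, complete``.
    """
    d_max = prevalence.max_duration
    if index.max_duration() < d_max:
        raise CompletenessIndexError(
            f"index covers durations up to {index.max_duration()}, "
            f"need {d_max}"
        )
    prev = (
        prevalence.regrouped(index.grouping)
        if index.grouping in (MODEL_SCHEME, EMPIRICAL_SCHEME)
        else prevalence
    )
    obs = prev.cumulative(d_max)
    rows = []
    for r in obs.itertuples(index=False):
        R = index.lookup(r.sex, r.site, r.age_group, d_max)
        if R is None or R <= 0:
            if r.count == 0:
                logger.warning(
                    "empty cell with missing R: %s", (r.sex, r.site, r.age_group)
                )
                rows.append((r.sex, r.site, r.age_group, 0.0, np.nan, 0.0))
                continue
            msg = (
                f"missing or zero R for nonzero cell "
                f"({r.sex}, {r.site}, {r.age_group}, d={d_max})"
            )
            if strict:
                raise CompletenessIndexError(msg)
            logger.warning("%s; cell dropped", msg)
            continue
        rows.append((r.sex, r.site, r.age_group, float(r.count), R, float(r.count) / R))
    return pd.DataFrame(
        rows, columns=["sex", "site", "age_group", "observed", "R", "complete"]
    )


def extend_prevalence(n_d1: float, r_d1: float, r_d2: float) -> float:
    """Estimate prevalence at duration d2 from observed prevalence at d1.

    N(d2) = N(d1) / (R(d1) / R(d2)).
    """
    if r_d1 <= 0 or r_d2 <= 0:
        raise CompletenessIndexError("R values must be positive")
    return n_d1 * r_d2 / r_d1


def extend_prevalence_table(
    prevalence: PrevalenceTable,
    index: CompletenessIndex,
    d1: int,
    d2: int,
    strict: bool = True,
) -> pd.DataFrame:
    """Per-cell extension of d1-year prevalence to duration d2."""
    if d2 < d1:
        raise ValueError("d2 must be >= d1")
    prev = (
        prevalence.regrouped(index.grouping)
        if index.grouping in (MODEL_SCHEME, EMPIRICAL_SCHEME)
        else prevalence
    )
    obs = prev.cumulative(d1)
    rows = []
    for r in obs.itertuples(index=False):
        if r.count == 0:
            rows.append((r.sex, r.site, r.age_group, 0.0, 0.0))
            continue
        r1 = index.lookup(r.sex, r.site, r.age_group, d1)
        r2 = index.lookup(r.sex, r.site, r.age_group, d2)
        if r1 is None or r2 is None:
            msg = (
                f"missing R for cell ({r.sex}, {r.site}, {r.age_group}), "
                f"durations {d1}/{d2}"
            )
            if strict:
                raise CompletenessIndexError(msg)
            logger.warning("%s; cell dropped", msg)
            continue
        rows.append(
            (r.sex, r.site, r.age_group, float(r.count),
             extend_prevalence(float(r.count), r1, r2))
        )
    return pd.DataFrame(
        rows, columns=["sex", "site", "age_group", "observed", "estimated"]
    )


# ---------------------------------------------------------------------------
# external index tables
# ---------------------------------------------------------------------------

def load_external_index(path, index_date: date = date(2013, 1, 1)) -> CompletenessIndex:
    """Load a pre-computed index table (CSV: sex,site,age_group,duration,R)."""
    df = pd.read_csv(path)
    required = {"sex", "site", "age_group", "duration", "R"}
    missing = required - set(df.columns)
    if missing:
        raise CompletenessIndexError(f"{path}: missing columns {sorted(missing)}")
    grouping = MODEL_SCHEME
    groups = set(df["age_group"].astype(str))
    if "0-29" in groups or "80+" in groups:
        grouping = EMPIRICAL_SCHEME
    return CompletenessIndex(
        method="external",
        index_date=index_date,
        values=df[["sex", "site", "age_group", "duration", "R"]],
        grouping=grouping,
    )


def write_index(index: CompletenessIndex, path) -> None:
    df = index.values.copy()
    df["method"] = index.method
    df = df.sort_values(["sex", "site", "age_group", "duration"], kind="mergesort")
    df.to_csv(path, index=False, float_format="%.10g")
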