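"""Registry microsimulator and brute-force prevalence truth oracle.

The simulator draws individual cancer diagnoses from a logistic age-cohort
incidence surface, cause-specific death times from a Weibull mixture cure
model, other-cause death times from a general-population life table
(independent competing risks), and loss to follow-up from an independent
exponential censoring time. Time runs on a yearly grid with uniform
within-year event timing; everything is reproducible from a seed.

It returns both the *observed* records (follow-up censored at loss or at the
index date) and *truth* records carrying exact death information, so that
downstream estimates can be scored against an exact enumeration of complete
prevalence (:func:`true_prevalence`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from previndex.registry import (
    AGE_BANDS,
    MODEL_SCHEME,
    LifeTable,
    PatientRecord,
    PopulationTable,
    PrevalenceTable,
    assign_age_group,
    completed_years,
    ltfu_age_band,
)

# ---------------------------------------------------------------------------
# scenario description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeProfile:
    """Age dependence of incidence on the logit scale.

    ``loglinear``: logit rate = coeffs[0] + coeffs[1] * age.
    ``poly``: logit rate = sum_k coeffs[k] * x**k with x = (age - 50) / 50.
    """

    kind: str
    coeffs: tuple[float, ...]

    def logit(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        if self.kind == "loglinear":
            b0, b1 = self.coeffs
            return b0 + b1 * age
        if self.kind == "poly":
            x = (age - 50.0) / 50.0
            return sum(c * x**k for k, c in enumerate(self.coeffs))
        raise ValueError(f"unknown age-profile kind {self.kind!r}")


@dataclass(frozen=True)
class SiteScenario:
    """Generative truth for one cancer site.

    ``cohort_effects`` maps decade-of-birth start years to additive logit
    offsets; decades outside the mapped range use the nearest mapped decade
    (constant extrapolation). ``cure_fraction`` is per age-at-diagnosis band.
    ``period_scale_drift`` optionally multiplies the Weibull scale per 5-year
    period of diagnosis (a simple survival period effect).
    """

    site: str
    age_profile: AgeProfile
    cohort_effects: dict[int, float] = field(default_factory=dict)
    cure_fraction: dict[str, float] = field(
        default_factory=lambda: {b: 0.5 for b in AGE_BANDS}
    )
    weibull_shape: float = 1.0
    weibull_scale: float = 0.5
    period_scale_drift: dict[int, float] | None = None
    min_age_dx: int = 0
    max_age_dx: int = 99
    sexes: tuple[str, ...] = ("male", "female")

    def __post_init__(self):
        for band, c in self.cure_fraction.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"cure fraction for band {band} outside [0,1]: {c}")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")

    def cohort_effect(self, birth_year) -> np.ndarray:
        birth_year = np.asarray(birth_year)
        if not self.cohort_effects:
            return np.zeros(birth_year.shape, dtype=float)
        decades = np.array(sorted(self.cohort_effects))
        effects = np.array([self.cohort_effects[d] for d in decades])
        dec = (np.asarray(birth_year, dtype=int) // 10) * 10
        idx = np.clip(np.searchsorted(decades, dec, side="right") - 1, 0, len(decades) - 1)
        return effects[idx]

    def incidence_rate(self, age, birth_year) -> np.ndarray:
        """Annual diagnosis probability at a given age for a birth cohort."""
        age = np.asarray(age, dtype=float)
        rate = expit(self.age_profile.logit(age) + self.cohort_effect(birth_year))
        rate = np.where((age < self.min_age_dx) | (age > self.max_age_dx), 0.0, rate)
        if np.any(rate > 1.0):
            raise ValueError("incidence rate above 1")
        return rate

    def scale_at(self, year_dx) -> np.ndarray:
        lam = np.full(np.shape(np.asarray(year_dx)), self.weibull_scale, dtype=float)
        if self.period_scale_drift:
            periods = np.array(sorted(self.period_scale_drift))
            mult = np.array([self.period_scale_drift[p] for p in periods])
            pstart = 1980 + ((np.asarray(year_dx, dtype=int) - 1980) // 5) * 5
            idx = np.clip(np.searchsorted(periods, pstart, side="right") - 1, 0, len(periods) - 1)
            lam = lam * mult[idx]
        return lam

    def cause_survival(self, t, age_dx: int, year_dx: int | None = None) -> np.ndarray:
        """Cause-specific (net) survival implied by the cure model."""
        c = self.cure_fraction[ltfu_age_band(age_dx)]
        lam = self.weibull_scale
        if self.period_scale_drift and year_dx is not None:
            lam = float(self.scale_at(year_dx))
        t = np.asarray(t, dtype=float)
        return c + (1.0 - c) * np.exp(-((lam * t) ** self.weibull_shape))


@dataclass
class SimulationConfig:
    """Microsimulation settings.

    The simulation starts ``sim_start_year`` (default: 60 years before the
    index date) so that complete prevalence is fully covered; registration
    typically starts later, and records diagnosed before registration are
    dropped by :func:`truncate_to_registration`.
    """

    registration_start_year: int
    index_date: date = date(2013, 1, 1)
    sim_start_year: int | None = None
    population_per_age: float = 2000.0
    max_age: int = 99
    loss_rate: float = 0.002
    life_table: LifeTable | None = None
    registry_id: str = "SYN"

    def __post_init__(self):
        if self.sim_start_year is None:
            self.sim_start_year = self.index_date.year - 60
        if not (self.sim_start_year <= self.registration_start_year < self.index_date.year):
            raise ValueError(
                "require sim_start_year <= registration_start_year < index year"
            )


def make_life_table(
    year_min: int,
    year_max: int,
    max_age: int = 99,
    makeham: float = 1e-4,
    gompertz_a: float = 5e-5,
    gompertz_b: float = 0.09,
) -> LifeTable:
    """Synthetic Gompertz-Makeham life table, constant over calendar years."""
    ages = np.arange(max_age + 1)
    hazard = makeham + gompertz_a * np.exp(gompertz_b * ages)
    surv = np.exp(-hazard)
    rows = []
    for sex in ("male", "female"):
        for year in range(year_min, year_max + 1):
            for age, p in zip(ages, surv):
                rows.append((sex, int(age), int(year), float(p)))
    return LifeTable(
        pd.DataFrame(rows, columns=["sex", "age", "year", "annual_survival"])
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedRegistry:
    """Output of one microsimulation run.

    ``records`` carry observed follow-up (losses censor); ``truth_records``
    carry exact death information with no loss to follow-up. Both include all
    diagnoses since the simulation start; restrict to the registration window
    with :func:`truncate_to_registration`.
    """

    records: list[PatientRecord]
    truth_records: list[PatientRecord]
    population: PopulationTable
    life_table: LifeTable
    config: SimulationConfig
    scenario: SiteScenario

    @property
    def observed(self) -> list[PatientRecord]:
        return truncate_to_registration(
            self.records, self.config.registration_start_year
        )


def _float_year_to_date(t: float) -> date:
    year = int(math.floor(t))
    day = int((t - year) * 365)
    return date(year, 1, 1) + timedelta(days=min(day, 364))


def simulate_registry(
    scenario: SiteScenario,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SimulatedRegistry:
    """Simulate one registry for one site scenario."""
    index_year = config.index_date.year
    years = np.arange(config.sim_start_year, index_year)
    ages = np.arange(config.max_age + 1)
    life_table = config.life_table or make_life_table(
        config.sim_start_year, index_year, config.max_age
    )

    pop_rows = []
    for sex in scenario.sexes:
        for year in years:
            pop_rows.append((sex, "0-%d" % config.max_age, int(year),
                             config.population_per_age * len(ages)))
    population = PopulationTable(
        pd.DataFrame(pop_rows, columns=["sex", "age_group", "year", "count"]),
        max_age=config.max_age,
    )

    all_sex: list[np.ndarray] = []
    all_age: list[np.ndarray] = []
    all_year: list[np.ndarray] = []
    for s_idx, sex in enumerate(scenario.sexes):
        age_grid, year_grid = np.meshgrid(ages, years, indexing="ij")
        birth = year_grid - age_grid
        rates = scenario.incidence_rate(age_grid, birth)
        n = np.full(rates.shape, config.population_per_age)
        counts = rng.binomial(n.astype(int), rates)
        a_idx, y_idx = np.nonzero(counts)
        reps = counts[a_idx, y_idx]
        all_sex.append(np.full(int(reps.sum()), s_idx, dtype=int))
        all_age.append(np.repeat(ages[a_idx], reps))
        all_year.append(np.repeat(years[y_idx], reps))

    sex_idx = np.concatenate(all_sex) if all_sex else np.array([], dtype=int)
    age_dx = np.concatenate(all_age) if all_age else np.array([], dtype=int)
    year_dx = np.concatenate(all_year) if all_year else np.array([], dtype=int)
    n_cases = len(age_dx)

    time_dx = year_dx + rng.uniform(size=n_cases)

    # cause-specific death time: cured -> infinite; else Weibull(shape, scale)
    c_by_band = np.array([scenario.cure_fraction[b] for b in AGE_BANDS])
    band_idx = np.where(age_dx < 60, 0, np.where(age_dx < 75, 1, 2))
    cured = rng.uniform(size=n_cases) < c_by_band[band_idx]
    lam = np.asarray(scenario.scale_at(year_dx), dtype=float)
    u = rng.uniform(size=n_cases)
    with np.errstate(divide="ignore"):
        t_cause = np.where(
            cured, np.inf, (-np.log(u)) ** (1.0 / scenario.weibull_shape) / lam
        )

    # other-cause death on a yearly grid from the life table
    t_other = np.full(n_cases, np.inf)
    alive = np.ones(n_cases, dtype=bool)
    max_steps = index_year - config.sim_start_year + 1
    grids = {s: life_table.grid(sex) for s, sex in enumerate(scenario.sexes)}
    for k in range(max_steps):
        active = alive & (year_dx + k < index_year)
        if not active.any():
            break
        p = np.empty(int(active.sum()))
        act_idx = np.nonzero(active)[0]
        for s_idx in np.unique(sex_idx[act_idx]):
            mat, age0, year0 = grids[s_idx]
            sel = sex_idx[act_idx] == s_idx
            rows = np.clip(age_dx[act_idx][sel] + k - age0, 0, mat.shape[0] - 1)
            cols = np.clip(year_dx[act_idx][sel] + k - year0, 0, mat.shape[1] - 1)
            p[sel] = mat[rows, cols]
        die = rng.uniform(size=len(act_idx)) >= p
        died_idx = act_idx[die]
        t_other[died_idx] = k + rng.uniform(size=len(died_idx))
        alive[died_idx] = False

    t_loss = (
        rng.exponential(1.0 / config.loss_rate, size=n_cases)
        if config.loss_rate > 0
        else np.full(n_cases, np.inf)
    )

    t_death = np.minimum(t_cause, t_other)
    abs_death = time_dx + t_death
    abs_loss = time_dx + t_loss
    t_index = float(index_year)

    records: list[PatientRecord] = []
    truth_records: list[PatientRecord] = []
    for i in range(n_cases):
        sex = scenario.sexes[sex_idx[i]]
        pid = f"{scenario.site}-{sex[0]}-{i:07d}"
        d_dx = _float_year_to_date(time_dx[i])
        dead_before_index = abs_death[i] < t_index
        if dead_before_index:
            d_death = _float_year_to_date(abs_death[i])
            if d_death < d_dx:
                d_death = d_dx
        else:
            d_death = None
        truth_records.append(
            PatientRecord(
                person_id=pid, sex=sex, site=scenario.site, date_dx=d_dx,
                age_dx=int(age_dx[i]),
                vital_status="dead" if dead_before_index else "alive",
                date_end=d_death if dead_before_index else config.index_date,
            )
        )
        lost_first = abs_loss[i] < min(abs_death[i], t_index)
        if lost_first:
            d_end = _float_year_to_date(abs_loss[i])
            if d_end < d_dx:
                d_end = d_dx
            status = "lost"
        elif dead_before_index:
            d_end, status = d_death, "dead"
        else:
            d_end, status = config.index_date, "alive"
        records.append(
            PatientRecord(
                person_id=pid, sex=sex, site=scenario.site, date_dx=d_dx,
                age_dx=int(age_dx[i]), vital_status=status, date_end=d_end,
            )
        )

    return SimulatedRegistry(
        records=records,
        truth_records=truth_records,
        population=population,
        life_table=life_table,
        config=config,
        scenario=scenario,
    )


# ---------------------------------------------------------------------------
# truth oracle and truncation
# ---------------------------------------------------------------------------

def true_prevalence(
    records: Iterable[PatientRecord],
    index_date: date,
    max_duration: int | None = None,
    grouping: str = MODEL_SCHEME,
    registry_id: str = "",
) -> PrevalenceTable:
    """Exact enumeration of prevalent cases from truth records.

    Requires records with exact death information (no loss to follow-up):
    a person is prevalent iff diagnosed strictly before the index date and
    not dead before it.
    """
    cells: dict[tuple[str, str, str, int], float] = {}
    max_seen = 0
    for r in records:
        if r.vital_status == "lost":
            raise ValueError(
                "true_prevalence requires truth records without loss to follow-up"
            )
        if r.date_dx >= index_date:
            continue
        if r.vital_status == "dead" and r.date_end < index_date:
            continue
        d = completed_years(r.date_dx, index_date)
        if max_duration is not None and d >= max_duration:
            continue
        max_seen = max(max_seen, d)
        age_prev = r.age_dx + d
        key = (r.sex, r.site, assign_age_group(age_prev, grouping), d)
        cells[key] = cells.get(key, 0.0) + 1.0
    df = pd.DataFrame(
        [(s, si, g, d, c) for (s, si, g, d), c in sorted(cells.items())],
        columns=["sex", "site", "age_group", "duration", "count"],
    )
    return PrevalenceTable(
        index_date=index_date,
        counts=df,
        max_duration=max_duration if max_duration is not None else max_seen + 1,
        registry_id=registry_id,
        grouping=grouping,
    )


def true_completeness_ratio(
    records: Iterable[PatientRecord],
    index_date: date,
    durations: Sequence[int],
    grouping: str = MODEL_SCHEME,
    age_convention: str = "model",
) -> pd.DataFrame:
    """Brute-force completeness ratios N(<=d) / N(complete) from truth records.

    ``age_convention`` controls the age-at-prevalence bookkeeping:
    ``"counting"`` matches the counting method (age at diagnosis plus
    completed duration); ``"model"`` adds one further year, matching the
    model-based index convention in which a patient at prevalence age ``a``
    with completed duration ``t`` was diagnosed at age ``a - t - 1``.
    Returns columns ``sex, site, age_group, duration, R, n``.
    """
    if age_convention not in ("counting", "model"):
        raise ValueError(f"unknown age convention {age_convention!r}")
    shift = 1 if age_convention == "model" else 0
    rows = []
    for r in records:
        if r.vital_status == "lost":
            raise ValueError("truth records required (no loss to follow-up)")
        if r.date_dx >= index_date:
            continue
        if r.vital_status == "dead" and r.date_end < index_date:
            continue
        d = completed_years(r.date_dx, index_date)
        rows.append((r.sex, r.site, r.age_dx + d + shift, d))
    df = pd.DataFrame(rows, columns=["sex", "site", "age_prev", "duration"])
    df["age_group"] = [assign_age_group(a, grouping) for a in df["age_prev"]]
    out = []
    for (sex, site, g), sub in df.groupby(["sex", "site", "age_group"]):
        n = len(sub)
        for d in durations:
            out.append((sex, site, g, int(d), float((sub["duration"] < d).mean()), n))
    return pd.DataFrame(
        out, columns=["sex", "site", "age_group", "duration", "R", "n"]
    )


def truncate_to_registration(
    records: Iterable[PatientRecord], registration_start_year: int
) -> list[PatientRecord]:
    """Drop records diagnosed before the registration start (pure filter)."""
    start = date(registration_start_year, 1, 1)
    return [r for r in records if r.date_dx >= start]


# ---------------------------------------------------------------------------
# default scenario library
# ---------------------------------------------------------------------------

def _bimodal_poly(peak1: float, peak2: float, depth: float, level: float) -> AgeProfile:
    # quartic with maxima of the logit near the two peak ages
    x1 = (peak1 - 50.0) / 50.0
    x2 = (peak2 - 50.0) / 50.0
    quartic = np.polynomial.polynomial.polyfromroots([x1, x1, x2, x2])
    coeffs = tuple(level - depth * quartic)
    return AgeProfile("poly", coeffs)


def pancreas_like() -> SiteScenario:
    """Late onset, low survival."""
    return SiteScenario(
        site="pancreas_like",
        age_profile=AgeProfile("loglinear", (-14.0, 0.095)),
        cohort_effects={},
        cure_fraction={"0-59": 0.10, "60-74": 0.07, "75+": 0.05},
        weibull_shape=1.1,
        weibull_scale=0.9,
        min_age_dx=30,
    )


def breast_like() -> SiteScenario:
    """Late onset (rise to a broad plateau), high survival."""
    return SiteScenario(
        site="breast_like",
        age_profile=AgeProfile("poly", _peak_poly(peak=67.0, width=31.0, level=-6.3)),
        cohort_effects={},
        cure_fraction={"0-59": 0.65, "60-74": 0.60, "75+": 0.50},
        weibull_shape=1.1,
        weibull_scale=0.13,
        min_age_dx=25,
        sexes=("female",),
    )


def testis_like() -> SiteScenario:
    """Early onset, high survival, rising in recent cohorts."""
    coeffs = _peak_poly(peak=32.0, width=16.0, level=-7.6)
    return SiteScenario(
        site="testis_like",
        age_profile=AgeProfile("poly", coeffs),
        cohort_effects={1930: 0.0, 1950: 0.15, 1970: 0.35, 1990: 0.45},
        cure_fraction={"0-59": 0.90, "60-74": 0.85, "75+": 0.80},
        weibull_shape=1.2,
        weibull_scale=0.35,
        min_age_dx=15,
        sexes=("male",),
    )


def _peak_poly(peak: float, width: float, level: float) -> tuple[float, ...]:
    # concave quadratic in x = (age-50)/50 peaking at the given age
    xp = (peak - 50.0) / 50.0
    w = width / 50.0
    k = 1.0 / (w * w)
    # level - k*(x - xp)^2  expanded in powers of x
    return (level - k * xp * xp, 2.0 * k * xp, -k)


def bimodal_like() -> SiteScenario:
    """Bimodal age-at-onset (juvenile and late peaks), medium-high survival."""
    return SiteScenario(
        site="bimodal_like",
        age_profile=_bimodal_poly(peak1=18.0, peak2=68.0, depth=18.0, level=-8.2),
        cohort_effects={1930: 0.0, 1960: 0.1},
        cure_fraction={"0-59": 0.60, "60-74": 0.50, "75+": 0.40},
        weibull_shape=1.1,
        weibull_scale=0.45,
        min_age_dx=5,
    )


SCENARIO_LIBRARY: dict[str, Callable[[], SiteScenario]] = {
    "pancreas_like": pancreas_like,
    "breast_like": breast_like,
    "testis_like": testis_like,
    "bimodal_like": bimodal_like,
}


def get_scenario(name: str) -> SiteScenario:
    try:
        return SCENARIO_LIBRARY[name]()
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIO_LIBRARY)}"
        ) from None
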