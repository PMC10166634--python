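"""Core registry domain types, age/duration conventions and tabular I/O.

Conventions used throughout the package:

- dates are handled at day resolution (``datetime.date``);
- "years since diagnosis" is the number of *completed* years between the
  diagnosis date and the prevalence index date (floor of anniversary years);
- a patient diagnosed exactly on the index date is **not** prevalent;
- ``d``-year limited-duration prevalence counts patients with completed
  duration strictly below ``d`` (i.e. diagnosed within the past ``d`` years).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from datetime import date
from typing import Iterable

import numpy as np
import pandas as pd

SEXES = ("male", "female")
VITAL_STATUSES = ("alive", "dead", "lost")

#: age-grouping scheme identifiers
MODEL_SCHEME = "model_5y_85plus"  # 0-4, 5-9, ..., 80-84, 85+
EMPIRICAL_SCHEME = "empirical_wide"  # 0-29, 30-34, ..., 75-79, 80+

DAYS_PER_YEAR = 365.2425


class DataConsistencyError(ValueError):
    """Raised when input records are mutually inconsistent."""


class RegistryReadError(ValueError):
    """Raised when a delimited-text input fails validation.

    Carries a per-row error report (``.row_errors`` is a list of
    ``(line_number, message)`` pairs; line numbers refer to the file,
    header included).
    """

    def __init__(self, message: str, row_errors: list[tuple[int, str]] | None = None):
        self.row_errors = row_errors or []
        details = "".join(f"\n  line {ln}: {msg}" for ln, msg in self.row_errors)
        super().__init__(message + details)


# ---------------------------------------------------------------------------
# date / duration helpers
# ---------------------------------------------------------------------------

def completed_years(start: date, end: date) -> int:
    """Whole years elapsed between two dates (anniversary-based floor)."""
    if end < start:
        raise ValueError(f"end date {end} precedes start date {start}")
    years = end.year - start.year
    if (end.month, end.day) < (start.month, start.day):
        years -= 1
    return years


def elapsed_years(start: date, end: date) -> float:
    """Elapsed time between two dates in (fractional) years."""
    if end < start:
        raise ValueError(f"end date {end} precedes start date {start}")
    return (end - start).days / DAYS_PER_YEAR


# ---------------------------------------------------------------------------
# age groupings
# ---------------------------------------------------------------------------

def assign_age_group(age: int, scheme: str = MODEL_SCHEME) -> str:
    """Map an age at the prevalence date to its group label.

    ``model_5y_85plus``: 5-year groups with terminal ``85+``.
    ``empirical_wide``: extremes collapsed to ``0-29`` and ``80+``,
    5-year groups in between.
    """
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    if scheme == MODEL_SCHEME:
        if age >= 85:
            return "85+"
        lo = (age // 5) * 5
        return f"{lo}-{lo + 4}"
    if scheme == EMPIRICAL_SCHEME:
        if age < 30:
            return "0-29"
        if age >= 80:
            return "80+"
        lo = (age // 5) * 5
        return f"{lo}-{lo + 4}"
    raise ValueError(f"unknown age grouping scheme: {scheme!r}")


def group_labels(scheme: str = MODEL_SCHEME) -> list[str]:
    """All group labels of a scheme, in ascending age order."""
    if scheme == MODEL_SCHEME:
        return [f"{lo}-{lo + 4}" for lo in range(0, 85, 5)] + ["85+"]
    if scheme == EMPIRICAL_SCHEME:
        return ["0-29"] + [f"{lo}-{lo + 4}" for lo in range(30, 80, 5)] + ["80+"]
    raise ValueError(f"unknown age grouping scheme: {scheme!r}")


_GROUP_RE = re.compile(r"^(\d+)(?:-(\d+)|\+)?$")


def parse_age_group(label: str) -> tuple[int, int | None]:
    """Parse an age-group label into (low, high-inclusive); open top -> None.

    Accepts ``"40-44"``, ``"85+"`` and single ages like ``"42"``.
    """
    m = _GROUP_RE.match(label.strip())
    if not m:
        raise ValueError(f"cannot parse age-group label {label!r}")
    lo = int(m.group(1))
    if label.strip().endswith("+"):
        return lo, None
    hi = m.group(2)
    return lo, int(hi) if hi is not None else lo


def ages_in_group(label: str, max_age: int = 99) -> range:
    lo, hi = parse_age_group(label)
    return range(lo, (max_age if hi is None else min(hi, max_age)) + 1)


def regroup_label(label: str, to_scheme: str) -> str:
    """Map a group label onto a (coarser or equal) scheme via its lowest age."""
    lo, hi = parse_age_group(label)
    target = assign_age_group(lo, to_scheme)
    tlo, thi = parse_age_group(target)
    if hi is None:
        hi_eff = lo
    else:
        hi_eff = hi
    if thi is not None and hi_eff > thi:
        raise ValueError(
            f"group {label!r} straddles boundaries of scheme {to_scheme!r}"
        )
    return target


def ltfu_age_band(age_dx: int) -> str:
    """Age-at-diagnosis band used for loss-to-follow-up / survival strata."""
    if age_dx < 0:
        raise ValueError(f"age must be non-negative, got {age_dx}")
    if age_dx < 60:
        return "0-59"
    if age_dx < 75:
        return "60-74"
    return "75+"


AGE_BANDS = ("0-59", "60-74", "75+")


def period_of(year: int, width: int = 5, anchor: int = 1980) -> int:
    """Start year of the diagnosis period containing ``year``."""
    return anchor + ((year - anchor) // width) * width


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class PatientRecord:
    """One tumour registration.

    ``date_end`` is the date of death, last contact, or administrative
    censoring (the prevalence index date for patients known alive).
    """

    person_id: str
    sex: str
    site: str
    date_dx: date
    age_dx: int
    vital_status: str
    date_end: date

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.vital_status not in VITAL_STATUSES:
            raise ValueError(f"unknown vital status {self.vital_status!r}")
        if self.age_dx < 0:
            raise ValueError(f"negative age at diagnosis: {self.age_dx}")
        if self.date_end < self.date_dx:
            raise ValueError(
                f"date_end {self.date_end} precedes date_dx {self.date_dx} "
                f"for person {self.person_id!r}"
            )


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Tabular view of patient records (one row per record)."""
    rows = [
        (r.person_id, r.sex, r.site, r.date_dx, r.age_dx, r.vital_status, r.date_end)
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "person_id", "sex", "site", "date_dx", "age_dx",
            "vital_status", "date_end",
        ],
    )


class LifeTable:
    """General-population annual survival probabilities.

    Keyed by (sex, single-year age, calendar year); lookups clamp the age to
    the table's top age and the calendar year to the covered range.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"sex", "age", "year", "annual_survival"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"life table missing columns: {sorted(missing)}")
        bad = df[(df["annual_survival"] <= 0) | (df["annual_survival"] > 1)]
        if len(bad):
            raise ValueError(
                f"life table has {len(bad)} probabilities outside (0,1]; "
                f"first offending row: {bad.iloc[0].to_dict()}"
            )
        self._df = df.copy()
        self._grids: dict[str, tuple[np.ndarray, int, int]] = {}
        for sex, sub in df.groupby("sex"):
            if sex not in SEXES:
                raise ValueError(f"unknown sex {sex!r} in life table")
            piv = sub.pivot_table(
                index="age", columns="year", values="annual_survival"
            )
            piv = piv.reindex(
                index=range(int(piv.index.min()), int(piv.index.max()) + 1),
                columns=range(int(piv.columns.min()), int(piv.columns.max()) + 1),
            )
            if piv.isna().any().any():
                raise ValueError(
                    f"life table grid for sex {sex!r} has gaps: a dense "
                    "(single-year age x calendar year) grid is required"
                )
            self._grids[sex] = (
                piv.to_numpy(dtype=float),
                int(piv.index.min()),
                int(piv.columns.min()),
            )

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.copy()

    def grid(self, sex: str) -> tuple[np.ndarray, int, int]:
        """(matrix[age, year], min_age, min_year) for vectorised lookups."""
        if sex not in self._grids:
            raise KeyError(f"no life-table entries for sex {sex!r}")
        return self._grids[sex]

    def annual_survival(self, sex: str, age, year):
        """Annual survival probability; scalar or vectorised over age/year."""
        mat, age0, year0 = self.grid(sex)
        a = np.clip(np.asarray(age, dtype=int) - age0, 0, mat.shape[0] - 1)
        y = np.clip(np.asarray(year, dtype=int) - year0, 0, mat.shape[1] - 1)
        out = mat[a, y]
        return float(out) if out.ndim == 0 else out


class PopulationTable:
    """Person counts by sex, age group and calendar year.

    Age groups may be single ages (``"42"``), closed ranges (``"40-44"``) or
    open-topped (``"85+"``); counts are spread uniformly across single ages
    when single-age resolution is required.
    """

    def __init__(self, df: pd.DataFrame, max_age: int = 99):
        required = {"sex", "age_group", "year", "count"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"population table missing columns: {sorted(missing)}")
        if (df["count"] < 0).any():
            raise ValueError("population table has negative counts")
        self.max_age = max_age
        self._df = df.copy()
        self._df["age_group"] = self._df["age_group"].astype(str)
        self._single: dict[tuple[str, int], np.ndarray] = {}

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def years(self) -> list[int]:
        return sorted(self._df["year"].unique())

    def single_age_counts(self, sex: str, year: int) -> np.ndarray:
        """Counts by single year of age 0..max_age (uniform within groups)."""
        years = self.years
        if not years:
            raise ValueError("empty population table")
        year = int(np.clip(year, min(years), max(years)))
        key = (sex, year)
        if key in self._single:
            return self._single[key]
        out = np.zeros(self.max_age + 1)
        sub = self._df[(self._df["sex"] == sex) & (self._df["year"] == year)]
        for _, row in sub.iterrows():
            ages = ages_in_group(row["age_group"], self.max_age)
            if len(ages) == 0:
                continue
            out[list(ages)] += row["count"] / len(ages)
        self._single[key] = out
        return out

    def person_years(self, sex: str, ages: Iterable[int], years: Iterable[int]) -> float:
        total = 0.0
        idx = [a for a in ages if 0 <= a <= self.max_age]
        for y in years:
            total += float(self.single_age_counts(sex, y)[idx].sum())
        return total


@dataclass
class PrevalenceTable:
    """Prevalent-case counts by age-at-prevalence group and whole-year duration.

    ``counts`` has columns ``sex, site, age_group, duration, count``; counts
    may be fractional (lost-to-follow-up patients contribute survival-weighted
    fractions). Duration ``d`` rows hold patients with completed duration
    exactly ``d``; the ``d``-year limited-duration prevalence is the sum of
    rows with duration `< d`.
    """

    index_date: date
    counts: pd.DataFrame
    max_duration: int
    registry_id: str = ""
    grouping: str = MODEL_SCHEME

    def __post_init__(self):
        required = {"sex", "site", "age_group", "duration", "count"}
        missing = required - set(self.counts.columns)
        if missing:
            raise ValueError(f"prevalence counts missing columns: {sorted(missing)}")
        if (self.counts["count"] < 0).any():
            raise ValueError("prevalence table has negative counts")
        if len(self.counts) and (self.counts["duration"] > self.max_duration).any():
            raise ValueError("prevalence table has durations beyond max_duration")

    def cumulative(self, d: int) -> pd.DataFrame:
        """Limited-duration prevalence at duration ``d`` per (sex, site, group)."""
        sub = self.counts[self.counts["duration"] < d]
        out = (
            sub.groupby(["sex", "site", "age_group"], as_index=False)["count"]
            .sum()
        )
        return out

    def total(self, d: int | None = None) -> float:
        d = self.max_duration if d is None else d
        return float(self.counts.loc[self.counts["duration"] < d, "count"].sum())

    def regrouped(self, to_scheme: str) -> "PrevalenceTable":
        """Collapse age groups onto a coarser scheme."""
        if to_scheme == self.grouping:
            return self
        df = self.counts.copy()
        df["age_group"] = [regroup_label(g, to_scheme) for g in df["age_group"]]
        df = df.groupby(["sex", "site", "age_group", "duration"], as_index=False)[
            "count"
        ].sum()
        return replace(self, counts=df, grouping=to_scheme)


# ---------------------------------------------------------------------------
# first-primary filtering
# ---------------------------------------------------------------------------

def first_primary_filter(records: Iterable[PatientRecord]) -> list[PatientRecord]:
    """Keep one record per (person, site): the earliest diagnosis.

    Records of the same person at different sites are all retained. Two
    records for the same (person, site, diagnosis date) with conflicting
    follow-up data raise :class:`DataConsistencyError`. The result is
    sorted, so the operation is order-independent and idempotent.
    """
    best: dict[tuple[str, str], PatientRecord] = {}
    for r in records:
        key = (r.person_id, r.site)
        cur = best.get(key)
        if cur is None or r.date_dx < cur.date_dx:
            best[key] = r
        elif r.date_dx == cur.date_dx and r != cur:
            raise DataConsistencyError(
                f"conflicting records for person {r.person_id!r}, site "
                f"{r.site!r}, diagnosed {r.date_dx}"
            )
    return sorted(
        best.values(), key=lambda r: (r.person_id, r.site, r.date_dx)
    )


# ---------------------------------------------------------------------------
# I/O  (comma-separated UTF-8, ISO-8601 dates)
# ---------------------------------------------------------------------------

REGISTRY_COLUMNS = [
    "person_id", "sex", "site", "date_dx", "age_dx", "vital_status", "date_end",
]


def _parse_iso_date(text: str) -> date:
    try:
        return date.fromisoformat(text.strip())
    except ValueError as exc:
        raise ValueError(f"unparsable ISO date {text!r}") from exc


def read_registry(path) -> list[PatientRecord]:
    """Read patient records from CSV, with a per-row error report on failure."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise RegistryReadError(f"{path}: missing columns {missing}")
    records: list[PatientRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            records.append(
                PatientRecord(
                    person_id=row.person_id,
                    sex=row.sex,
                    site=row.site,
                    date_dx=_parse_iso_date(row.date_dx),
                    age_dx=int(row.age_dx),
                    vital_status=row.vital_status,
                    date_end=_parse_iso_date(row.date_end),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append((line, str(exc)))
    if errors:
        raise RegistryReadError(f"{path}: {len(errors)} invalid rows", errors)
    return records


def write_registry(records: Iterable[PatientRecord], path) -> None:
    df = records_to_frame(records)
    df["date_dx"] = df["date_dx"].map(lambda d: d.isoformat())
    df["date_end"] = df["date_end"].map(lambda d: d.isoformat())
    df.to_csv(path, index=False)


def read_life_table(path) -> LifeTable:
    df = pd.read_csv(path)
    return LifeTable(df)


def write_life_table(table: LifeTable, path) -> None:
    table.frame.to_csv(path, index=False)


def read_population(path, max_age: int = 99) -> PopulationTable:
    df = pd.read_csv(path)
    return PopulationTable(df, max_age=max_age)


def write_population(table: PopulationTable, path) -> None:
    table.frame.to_csv(path, index=False)


def write_prevalence(table: PrevalenceTable, path) -> None:
    df = table.counts.copy()
    df.insert(0, "registry_id", table.registry_id)
    df.insert(1, "index_date", table.index_date.isoformat())
    df["max_duration"] = table.max_duration
    df["grouping"] = table.grouping
    df = df.sort_values(["sex", "site", "age_group", "duration"], kind="mergesort")
    df.to_csv(path, index=False, float_format="%.10g")


def read_prevalence(path) -> PrevalenceTable:
    df = pd.read_csv(path)
    required = {
        "registry_id", "index_date", "sex", "site", "age_group",
        "duration", "count", "max_duration", "grouping",
    }
    missing = required - set(df.columns)
    if missing:
        raise RegistryReadError(f"{path}: missing columns {sorted(missing)}")
    meta_cols = ["registry_id", "index_date", "max_duration", "grouping"]
    for c in meta_cols:
        if df[c].nunique() > 1:
            raise RegistryReadError(f"{path}: column {c!r} is not constant")
    return PrevalenceTable(
        index_date=_parse_iso_date(str(df["index_date"].iloc[0])),
        counts=df[["sex", "site", "age_group", "duration", "count"]].copy(),
        max_duration=int(df["max_duration"].iloc[0]),
        registry_id=str(df["registry_id"].iloc[0]),
        grouping=str(df["grouping"].iloc[0]),
    )
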