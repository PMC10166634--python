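"""Limited-duration prevalence at an index date (the counting method).

Patients known alive at the index date count 1; patients dead before it
count 0; patients lost to follow-up contribute the product of annual
conditional survival probabilities from the year of loss to the index date,
taken from the patient cohort's own actuarial life table stratified by sex,
grouped age at diagnosis (0-59, 60-74, 75+), site and 5-year period of
diagnosis. Sparse strata fall back to coarser pooling in a fixed order:
drop period, then drop the age band, then pool sites.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date
from typing import Iterable

import numpy as np
import pandas as pd

from previndex.registry import (
    MODEL_SCHEME,
    PatientRecord,
    PrevalenceTable,
    assign_age_group,
    completed_years,
    ltfu_age_band,
    period_of,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LtfuStrata:
    """Stratification for loss-to-follow-up survival weights."""

    period_width: int = 5
    period_anchor: int = 1980

    def key(self, record: PatientRecord) -> tuple[str, str, str, int]:
        return (
            record.sex,
            ltfu_age_band(record.age_dx),
            record.site,
            period_of(record.date_dx.year, self.period_width, self.period_anchor),
        )


class StratumExposureError(ValueError):
    """No exposure available for a needed survival interval, even pooled."""


def _actuarial_table(t_exit: np.ndarray, dead: np.ndarray) -> np.ndarray:
    """Annual conditional survival by the actuarial (life-table) method.

    ``t_exit`` is the completed-year interval of exit; ``dead`` marks death
    exits (everything else is a withdrawal, counted as half-exposed in its
    exit interval). Returns an array of conditional survival probabilities
    per interval [t, t+1); NaN where effective exposure is 0.
    """
    if len(t_exit) == 0:
        return np.empty(0)
    t_exit = np.asarray(t_exit, dtype=int)
    t_max = int(t_exit.max())
    probs = np.empty(t_max + 1)
    n_total = len(t_exit)
    exited_before = 0
    deaths = np.bincount(t_exit[dead], minlength=t_max + 1)
    withdrawals = np.bincount(t_exit[~dead], minlength=t_max + 1)
    for t in range(t_max + 1):
        n_t = n_total - exited_before
        eff = n_t - withdrawals[t] / 2.0
        if eff <= 0:
            probs[t] = np.nan
        else:
            probs[t] = 1.0 - deaths[t] / eff
        exited_before += deaths[t] + withdrawals[t]
    return np.clip(probs, 0.0, 1.0, out=probs)


class LtfuSurvival:
    """Annual conditional survival of the patient cohort, with pooled fallback.

    ``lookup(stratum, t)`` cascades through pooling levels
    (sex, band, site, period) -> (sex, band, site) -> (sex, site) -> (sex,)
    until an interval with positive exposure is found.
    """

    _LEVELS = (
        (0, 1, 2, 3),
        (0, 1, 2),
        (0, 2),
        (0,),
    )

    def __init__(self, records: Iterable[PatientRecord], index_date: date,
                 strata: LtfuStrata | None = None):
        strata = strata or LtfuStrata()
        self.strata = strata
        t_exit, dead, keys = [], [], []
        for r in records:
            if r.date_dx >= index_date:
                continue
            t_exit.append(completed_years(r.date_dx, r.date_end))
            dead.append(r.vital_status == "dead")
            keys.append(strata.key(r))
        t_exit = np.asarray(t_exit, dtype=int)
        dead = np.asarray(dead, dtype=bool)
        self._tables: dict[tuple, np.ndarray] = {}
        for level in self._LEVELS:
            groups: dict[tuple, list[int]] = {}
            for i, k in enumerate(keys):
                sub = tuple(k[j] for j in level)
                groups.setdefault(sub, []).append(i)
            for sub, idx in groups.items():
                idx = np.asarray(idx)
                self._tables[(level, sub)] = _actuarial_table(t_exit[idx], dead[idx])

    def lookup(self, stratum: tuple[str, str, str, int], t: int,
               carry_forward: bool = False) -> float:
        """Annual conditional survival at interval ``t`` with pooled fallback.

        With ``carry_forward``, an interval beyond the last one with positive
        exposure (even fully pooled) reuses the nearest earlier pooled value
        instead of raising; the counting method uses this for patients lost
        to follow-up whose duration outruns the cohort's observed follow-up.
        """
        for level in self._LEVELS:
            sub = tuple(stratum[j] for j in level)
            table = self._tables.get((level, sub))
            if table is not None and t < len(table) and not math.isnan(table[t]):
                return float(table[t])
        if carry_forward:
            sub = tuple(stratum[j] for j in self._LEVELS[-1])
            table = self._tables.get((self._LEVELS[-1], sub))
            if table is not None:
                for tt in range(min(t, len(table) - 1), -1, -1):
                    if not math.isnan(table[tt]):
                        logger.warning(
                            "exposure exhausted for %s at interval %d; "
                            "carrying forward interval %d", stratum, t, tt,
                        )
                        return float(table[tt])
        raise StratumExposureError(
            f"no exposure for stratum {stratum} at interval {t}, "
            "even after pooling"
        )

    def annual_survival(self, record: PatientRecord, t: int) -> float:
        return self.lookup(self.strata.key(record), t)


def cohort_life_table_survival(
    records: Iterable[PatientRecord],
    index_date: date,
    strata: LtfuStrata | None = None,
) -> LtfuSurvival:
    """Actuarial survival of the patient cohort for LTFU weighting."""
    return LtfuSurvival(records, index_date, strata)


def count_limited_duration_prevalence(
    records: Iterable[PatientRecord],
    index_date: date,
    ltfu_survival: LtfuSurvival | None = None,
    grouping: str = MODEL_SCHEME,
    max_duration: int | None = None,
    registry_id: str = "",
) -> PrevalenceTable:
    """Limited-duration prevalence at the index date by the counting method.

    ``records`` must already be first-primary filtered and truncated to the
    registration window. When ``ltfu_survival`` is None it is computed from
    the records themselves.
    """
    records = list(records)
    has_lost = any(r.vital_status == "lost" for r in records)
    if has_lost and ltfu_survival is None:
        ltfu_survival = cohort_life_table_survival(records, index_date)

    cells: dict[tuple[str, str, str, int], float] = {}
    max_seen = 0
    for r in records:
        if r.date_dx >= index_date:
            continue
        if r.vital_status == "lost" and r.date_end >= index_date:
            raise ValueError(
                f"record {r.person_id!r} is lost to follow-up but its "
                f"end date {r.date_end} is not before the index date"
            )
        d = completed_years(r.date_dx, index_date)
        if max_duration is not None and d >= max_duration:
            continue
        if r.vital_status == "dead":
            if r.date_end < index_date:
                continue
            weight = 1.0  # death recorded on/after index date: alive at index
        elif r.vital_status == "alive":
            weight = 1.0
        else:  # lost
            t_lost = completed_years(r.date_dx, r.date_end)
            weight = 1.0
            stratum = ltfu_survival.strata.key(r)
            for t in range(min(t_lost, d), d):
                weight *= ltfu_survival.lookup(stratum, t, carry_forward=True)
        max_seen = max(max_seen, d)
        age_prev = r.age_dx + d
        key = (r.sex, r.site, assign_age_group(age_prev, grouping), d)
        cells[key] = cells.get(key, 0.0) + weight

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
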