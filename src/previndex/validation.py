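"""Validation and comparison statistics for complete-prevalence estimates.

APRD is the weighted average of absolute percent relative differences
between estimated and observed prevalence across registries (absolute values
prevent under- and over-estimates from cancelling); PRD is the signed
analogue used to compare two complete-prevalence estimates, weighted by
resident population, so compensation can occur.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from previndex.completeness import (
    CompletenessIndex,
    complete_prevalence,
    extend_prevalence_table,
)
from previndex.registry import PrevalenceTable

logger = logging.getLogger(__name__)

#: registration-length groups used when comparing methods
LENGTH_GROUPS = ((10, 14), (15, 19), (20, 24), (25, 35))


def assign_length_group(years: int) -> str | None:
    for lo, hi in LENGTH_GROUPS:
        if lo <= years <= hi:
            return f"{lo}-{hi} y"
    return None


def aprd(
    observed: Mapping[str, float],
    estimated: Mapping[str, float],
    weights: Mapping[str, float] | None = None,
) -> float:
    """Weighted average absolute percent relative difference (percent).

    ``observed`` and ``estimated`` map registry ids to prevalent counts;
    weights default to each registry's share of observed cases and are
    normalised internally.
    """
    keys = sorted(observed)
    if sorted(estimated) != keys:
        raise ValueError("observed and estimated registries do not match")
    obs = np.array([observed[k] for k in keys], dtype=float)
    est = np.array([estimated[k] for k in keys], dtype=float)
    if np.any(obs <= 0):
        bad = [k for k, o in zip(keys, obs) if o <= 0]
        raise ValueError(f"observed counts must be positive; offending: {bad}")
    if weights is None:
        w = obs / obs.sum()
    else:
        w = np.array([weights[k] for k in keys], dtype=float)
        if w.sum() <= 0:
            raise ValueError("weights must sum to a positive value")
        w = w / w.sum()
    return float(np.sum(np.abs(est - obs) / obs * w) * 100.0)


def prd(
    alternative: Mapping[str, float],
    standard: Mapping[str, float],
    population_weights: Mapping[str, float],
) -> float:
    """Signed weighted average percent relative difference (percent)."""
    keys = sorted(standard)
    if sorted(alternative) != keys:
        raise ValueError("alternative and standard registries do not match")
    std = np.array([standard[k] for k in keys], dtype=float)
    alt = np.array([alternative[k] for k in keys], dtype=float)
    if np.any(std <= 0):
        bad = [k for k, s in zip(keys, std) if s <= 0]
        raise ValueError(f"standard estimates must be positive; offending: {bad}")
    w = np.array([population_weights[k] for k in keys], dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must sum to a positive value")
    w = w / w.sum()
    return float(np.sum((alt - std) / std * w) * 100.0)


@dataclass
class ValidationResult:
    """Truncation-validation output: APRD per (sex, site, truncation)."""

    aprd_table: pd.DataFrame  # sex site truncation aprd n_registries
    per_registry: pd.DataFrame  # sex site registry truncation observed estimated


def truncation_validation(
    prevalence_tables: Mapping[str, PrevalenceTable],
    index: CompletenessIndex,
    truncations: Sequence[int] = (5, 10, 15),
    target: int = 20,
) -> ValidationResult:
    """Validate an index by artificially truncating observed prevalence.

    For each registry (each with at least ``target`` years of registration),
    observed prevalence is truncated at each duration in ``truncations``,
    extended to ``target`` years via the index ratio R(d1)/R(target), and
    compared with the observed ``target``-year prevalence; discrepancies are
    aggregated per (sex, site) with registry case-share weights.
    """
    per_rows = []
    for reg_id, table in sorted(prevalence_tables.items()):
        if table.max_duration < target:
            raise ValueError(
                f"registry {reg_id!r} has only {table.max_duration} years "
                f"of registration (< {target})"
            )
        grouped = (
            table.regrouped(index.grouping)
            if index.grouping != table.grouping and index.grouping != "single_year"
            else table
        )
        obs20 = grouped.cumulative(target)
        obs_by = obs20.groupby(["sex", "site"])["count"].sum()
        for d1 in truncations:
            if d1 > target:
                raise ValueError(f"truncation {d1} exceeds target {target}")
            ext = extend_prevalence_table(table, index, d1, target, strict=False)
            est_by = ext.groupby(["sex", "site"])["estimated"].sum() if len(ext) else {}
            for (sex, site), n_obs in obs_by.items():
                est = float(est_by.get((sex, site), 0.0)) if len(ext) else 0.0
                per_rows.append((sex, site, reg_id, int(d1), float(n_obs), est))
    per = pd.DataFrame(
        per_rows,
        columns=["sex", "site", "registry", "truncation", "observed", "estimated"],
    )

    rows = []
    for (sex, site, d1), sub in per.groupby(["sex", "site", "truncation"]):
        sub = sub[sub["observed"] > 0]
        dropped = per[
            (per["sex"] == sex) & (per["site"] == site)
            & (per["truncation"] == d1) & (per["observed"] <= 0)
        ]
        if len(dropped):
            logger.warning(
                "APRD (%s, %s, d1=%s): %d registries with zero observed "
                "prevalence dropped", sex, site, d1, len(dropped),
            )
        if sub.empty:
            continue
        value = aprd(
            dict(zip(sub["registry"], sub["observed"])),
            dict(zip(sub["registry"], sub["estimated"])),
        )
        rows.append((sex, site, int(d1), value, len(sub)))
    return ValidationResult(
        aprd_table=pd.DataFrame(
            rows, columns=["sex", "site", "truncation", "aprd", "n_registries"]
        ),
        per_registry=per,
    )


@dataclass
class ComparisonResult:
    """Method-comparison output: PRD per (sex, site, registration-length group)."""

    prd_table: pd.DataFrame  # sex site length_group method prd n_registries
    per_registry: pd.DataFrame


def compare_methods(
    prevalence_tables: Mapping[str, PrevalenceTable],
    indexes: Mapping[str, CompletenessIndex],
    registration_lengths: Mapping[str, int],
    population_weights: Mapping[str, float],
    standard: str = "model",
) -> ComparisonResult:
    """Compare complete-prevalence estimates from alternative indexes.

    Complete prevalence is computed per registry at its maximum observed
    duration with each index; signed PRD of each alternative against the
    standard is aggregated per (sex, site, registration-length group) with
    resident-population weights.
    """
    if standard not in indexes:
        raise ValueError(f"standard method {standard!r} not among indexes")
    per_rows = []
    for reg_id, table in sorted(prevalence_tables.items()):
        group = assign_length_group(registration_lengths[reg_id])
        if group is None:
            logger.warning(
                "registry %s (length %s) outside length groups; skipped",
                reg_id, registration_lengths[reg_id],
            )
            continue
        for method, index in indexes.items():
            comp = complete_prevalence(table, index, strict=False)
            by = comp.groupby(["sex", "site"])["complete"].sum()
            for (sex, site), value in by.items():
                per_rows.append(
                    (sex, site, reg_id, group, method, float(value),
                     float(population_weights[reg_id]))
                )
    per = pd.DataFrame(
        per_rows,
        columns=["sex", "site", "registry", "length_group", "method",
                 "complete", "population"],
    )

    rows = []
    alternatives = [m for m in indexes if m != standard]
    for (sex, site, group), sub in per.groupby(["sex", "site", "length_group"]):
        std = sub[sub["method"] == standard].set_index("registry")
        for method in alternatives:
            alt = sub[sub["method"] == method].set_index("registry")
            common = sorted(set(std.index) & set(alt.index))
            common = [r for r in common if std.loc[r, "complete"] > 0]
            if not common:
                continue
            value = prd(
                {r: alt.loc[r, "complete"] for r in common},
                {r: std.loc[r, "complete"] for r in common},
                {r: std.loc[r, "population"] for r in common},
            )
            rows.append((sex, site, group, method, value, len(common)))
    return ComparisonResult(
        prd_table=pd.DataFrame(
            rows,
            columns=["sex", "site", "length_group", "method", "prd", "n_registries"],
        ),
        per_registry=per,
    )
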