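"""End-to-end orchestration of the synthetic estimation/validation pipeline.

A run simulates an estimation pool of long-running registries plus separate
validation/comparison registries, counts limited-duration prevalence, fits
the survival and incidence models, builds completeness indexes (model-based
and empirical), estimates complete prevalence with each method, and runs the
truncation-validation and method-comparison experiments. Everything is
deterministic given (config, seed): the global seed is fanned out into
per-stage substreams, and all artifacts are plain CSV plus a JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from previndex import __version__
from previndex.completeness import (
    CompletenessIndex,
    complete_prevalence,
    empirical_R,
    load_external_index,
    model_based_R,
    write_index,
)
from previndex.counting import count_limited_duration_prevalence
from previndex.incidence import (
    IncidenceModelParams,
    IncidenceTable,
    fit_logistic_age_cohort,
    tabulate_incidence,
)
from previndex.registry import PrevalenceTable, write_prevalence
from previndex.simulate import (
    SimulatedRegistry,
    SimulationConfig,
    get_scenario,
    make_life_table,
    simulate_registry,
)
from previndex.survival import CureModelParams, fit_cure_by_band
from previndex.validation import compare_methods, truncation_validation

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RegistryDef:
    id: str
    registration_start: int
    population_per_age: float | None = None


@dataclass
class RunConfig:
    seed: int
    scenarios: list[str]
    estimation_registries: list[RegistryDef]
    validation_registries: list[RegistryDef] = field(default_factory=list)
    comparison_registries: list[RegistryDef] = field(default_factory=list)
    index_year: int = 2013
    population_per_age: float = 500.0
    loss_rate: float = 0.002
    age_form: str = "poly6"
    durations_max: int = 35
    truncations: list[int] = field(default_factory=lambda: [5, 10, 15])
    validation_target: int = 20
    methods: list[str] = field(default_factory=lambda: ["model", "empirical"])
    external_index: str | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory for simulation runs")
        all_regs = self.all_registries()
        ids = [r.id for r in all_regs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate registry ids")
        for r in all_regs:
            if r.registration_start >= self.index_year:
                raise ValueError(
                    f"registry {r.id}: registration start "
                    f"{r.registration_start} not before index year"
                )
        for d1 in self.truncations:
            if d1 > self.validation_target:
                raise ValueError(
                    f"truncation {d1} exceeds validation target "
                    f"{self.validation_target}"
                )
        for r in self.validation_registries:
            if self.index_year - r.registration_start < self.validation_target:
                raise ValueError(
                    f"validation registry {r.id}: registration length "
                    f"shorter than the validation target"
                )

    def all_registries(self) -> list[RegistryDef]:
        return (
            self.estimation_registries
            + self.validation_registries
            + self.comparison_registries
        )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def regs(key):
            return [RegistryDef(**r) for r in d.get(key, [])]

        return cls(
            seed=d["seed"],
            scenarios=list(d["scenarios"]),
            estimation_registries=regs("estimation_registries"),
            validation_registries=regs("validation_registries"),
            comparison_registries=regs("comparison_registries"),
            index_year=d.get("index_year", 2013),
            population_per_age=d.get("population_per_age", 500.0),
            loss_rate=d.get("loss_rate", 0.002),
            age_form=d.get("age_form", "poly6"),
            durations_max=d.get("durations_max", 35),
            truncations=list(d.get("truncations", [5, 10, 15])),
            validation_target=d.get("validation_target", 20),
            methods=list(d.get("methods", ["model", "empirical"])),
            external_index=d.get("external_index"),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "scenarios": self.scenarios,
            "estimation_registries": [vars(r) for r in self.estimation_registries],
            "validation_registries": [vars(r) for r in self.validation_registries],
            "comparison_registries": [vars(r) for r in self.comparison_registries],
            "index_year": self.index_year,
            "population_per_age": self.population_per_age,
            "loss_rate": self.loss_rate,
            "age_form": self.age_form,
            "durations_max": self.durations_max,
            "truncations": self.truncations,
            "validation_target": self.validation_target,
            "methods": self.methods,
            "external_index": self.external_index,
        }


def _registry_rng(seed: int, reg_id: str, scenario: str) -> np.random.Generator:
    """Deterministic per-(registry, scenario) substream from the global seed."""
    digest = hashlib.sha256(f"{seed}|{reg_id}|{scenario}".encode()).digest()
    return np.random.default_rng(
        np.random.SeedSequence([seed, int.from_bytes(digest[:8], "big")])
    )


def simulate_all(config: RunConfig) -> dict[str, list[SimulatedRegistry]]:
    """Simulate every (registry, scenario) pair; keyed by registry id."""
    life_table = make_life_table(config.index_year - 60, config.index_year)
    sims: dict[str, list[SimulatedRegistry]] = {}
    for reg in config.all_registries():
        sim_cfg = SimulationConfig(
            registration_start_year=reg.registration_start,
            index_date=date(config.index_year, 1, 1),
            sim_start_year=config.index_year - 60,
            population_per_age=reg.population_per_age or config.population_per_age,
            loss_rate=config.loss_rate,
            life_table=life_table,
            registry_id=reg.id,
        )
        sims[reg.id] = [
            simulate_registry(
                get_scenario(name), sim_cfg, _registry_rng(config.seed, reg.id, name)
            )
            for name in config.scenarios
        ]
    return sims


def count_all(
    config: RunConfig, sims: Mapping[str, list[SimulatedRegistry]]
) -> dict[str, PrevalenceTable]:
    """Limited-duration prevalence per registry (all scenarios pooled)."""
    index_date = date(config.index_year, 1, 1)
    tables: dict[str, PrevalenceTable] = {}
    for reg in config.all_registries():
        records = [r for sim in sims[reg.id] for r in sim.observed]
        length = config.index_year - reg.registration_start
        tables[reg.id] = count_limited_duration_prevalence(
            records, index_date,
            max_duration=min(length, config.durations_max),
            registry_id=reg.id,
        )
    return tables


def fit_models(
    config: RunConfig, sims: Mapping[str, list[SimulatedRegistry]]
) -> tuple[dict, dict]:
    """Fit cure and incidence models on the pooled estimation registries."""
    est_ids = [r.id for r in config.estimation_registries]
    records = [
        r
        for rid in est_ids
        for sim in sims[rid]
        for r in sim.observed
    ]
    life_table = sims[est_ids[0]][0].life_table
    cure = fit_cure_by_band(records, life_table, max_time=config.durations_max)
    if not cure:
        raise PipelineError("fit-survival: no stratum converged")

    tables = []
    for reg in config.estimation_registries:
        for sim in sims[reg.id]:
            tables.append(
                tabulate_incidence(
                    sim.observed, sim.population,
                    year_range=(reg.registration_start, config.index_year - 1),
                ).df
            )
    pooled = (
        pd.concat(tables)
        .groupby(["sex", "site", "age_group", "period_start"], as_index=False)
        .sum()
    )
    table = IncidenceTable(pooled)
    inc_fits = fit_logistic_age_cohort(table, config.age_form)
    inc = {(f.sex, f.site): f for f in inc_fits}
    expected = set(
        pooled.groupby(["sex", "site"]).groups
    )
    missing = expected - set(inc)
    if missing and config.age_form != "exponential":
        # degree-6 fits can separate on sparse data; retry log-linear age
        fallback = fit_logistic_age_cohort(table, "exponential")
        for f in fallback:
            if (f.sex, f.site) in missing:
                logger.warning(
                    "incidence fit for (%s, %s) fell back to the "
                    "exponential age form", f.sex, f.site,
                )
                inc[(f.sex, f.site)] = f
        missing = expected - set(inc)
    if missing:
        raise PipelineError(f"fit-incidence: no converged model for {sorted(missing)}")
    return cure, inc


def build_indexes(
    config: RunConfig,
    sims: Mapping[str, list[SimulatedRegistry]],
    prevalence: Mapping[str, PrevalenceTable],
    cure: Mapping[tuple, CureModelParams],
    inc: Mapping[tuple, IncidenceModelParams],
) -> dict[str, CompletenessIndex]:
    index_date = date(config.index_year, 1, 1)
    indexes: dict[str, CompletenessIndex] = {}

    if "model" in config.methods:
        est0 = config.estimation_registries[0].id
        life_table = sims[est0][0].life_table
        population = sims[est0][0].population
        frames = []
        for (sex, site), params in sorted(inc.items()):
            bands = {
                band: p for (s, si, band), p in
                ((k, v) for k, v in cure.items()) if s == sex and si == site
            }
            if not bands:
                raise PipelineError(
                    f"build-index model: no converged survival fit for "
                    f"({sex}, {site})"
                )
            scenario = next(
                sim.scenario
                for sim in sims[est0]
                if sim.scenario.site == site
            )
            idx = model_based_R(
                params, bands, life_table, index_date, sex, site,
                durations=range(1, config.durations_max + 1),
                a_min=scenario.min_age_dx,
                population=population,
            )
            frames.append(idx.values)
        indexes["model"] = CompletenessIndex(
            "model", index_date, pd.concat(frames, ignore_index=True)
        )

    if "empirical" in config.methods:
        est_tables = [prevalence[r.id] for r in config.estimation_registries]
        longest = max(t.max_duration for t in est_tables)
        pool = [t for t in est_tables if t.max_duration == longest]
        counts = (
            pd.concat([t.counts for t in pool])
            .groupby(["sex", "site", "age_group", "duration"], as_index=False)["count"]
            .sum()
        )
        pooled = PrevalenceTable(
            index_date=index_date, counts=counts, max_duration=longest,
            registry_id="POOL", grouping=pool[0].grouping,
        )
        indexes["empirical"] = empirical_R(pooled)

    if "external" in config.methods:
        if not config.external_index:
            raise PipelineError("build-index external: no index file configured")
        indexes["external"] = load_external_index(
            config.external_index, index_date
        )
    return indexes


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every stage and write artifacts; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "artifacts": {},
        "valid": False,
    }

    def record(name: str, rows: int):
        manifest["artifacts"][name] = {"rows": rows}

    try:
        stage = "simulate"
        sims = simulate_all(config)

        stage = "count-prevalence"
        prevalence = count_all(config, sims)
        for rid, table in sorted(prevalence.items()):
            path = out / f"prevalence_{rid}.csv"
            write_prevalence(table, path)
            record(path.name, len(table.counts))

        stage = "fit-models"
        cure, inc = fit_models(config, sims)
        cure_json = {f"{k[0]}|{k[1]}|{k[2]}": v.to_dict() for k, v in sorted(cure.items())}
        (out / "cure_params.json").write_text(json.dumps(cure_json, indent=1, sort_keys=True))
        inc_json = {f"{k[0]}|{k[1]}": v.to_dict() for k, v in sorted(inc.items())}
        (out / "incidence_params.json").write_text(json.dumps(inc_json, indent=1, sort_keys=True))
        record("cure_params.json", len(cure_json))
        record("incidence_params.json", len(inc_json))

        stage = "build-index"
        indexes = build_indexes(config, sims, prevalence, cure, inc)
        for method, idx in sorted(indexes.items()):
            path = out / f"index_{method}.csv"
            write_index(idx, path)
            record(path.name, len(idx.values))

        stage = "estimate-complete"
        frames = []
        for rid, table in sorted(prevalence.items()):
            for method, idx in sorted(indexes.items()):
                comp = complete_prevalence(table, idx, strict=False)
                comp.insert(0, "registry", rid)
                comp.insert(1, "method", method)
                frames.append(comp)
        complete = pd.concat(frames, ignore_index=True)
        complete.to_csv(out / "complete_prevalence.csv", index=False,
                        float_format="%.10g")
        record("complete_prevalence.csv", len(complete))

        stage = "validate"
        val_ids = [r.id for r in config.validation_registries]
        if val_ids and "model" in indexes:
            result = truncation_validation(
                {rid: prevalence[rid] for rid in val_ids},
                indexes["model"],
                truncations=config.truncations,
                target=config.validation_target,
            )
            result.aprd_table.to_csv(out / "validation_aprd.csv", index=False,
                                     float_format="%.10g")
            record("validation_aprd.csv", len(result.aprd_table))

        stage = "compare"
        cmp_ids = [
            r.id for r in config.validation_registries + config.comparison_registries
        ]
        if cmp_ids and len(indexes) > 1 and "model" in indexes:
            lengths = {
                r.id: config.index_year - r.registration_start
                for r in config.all_registries()
            }
            pops = {
                r.id: (r.population_per_age or config.population_per_age)
                for r in config.all_registries()
            }
            comparison = compare_methods(
                {rid: prevalence[rid] for rid in cmp_ids},
                indexes, lengths, pops, standard="model",
            )
            comparison.prd_table.to_csv(out / "comparison_prd.csv", index=False,
                                        float_format="%.10g")
            record("comparison_prd.csv", len(comparison.prd_table))
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest["valid"] = True
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
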