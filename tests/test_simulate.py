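from datetime import date

import numpy as np
import pytest

from previndex.registry import MODEL_SCHEME, PatientRecord
from previndex.simulate import (
    AgeProfile,
    SCENARIO_LIBRARY,
    SimulationConfig,
    SiteScenario,
    breast_like,
    get_scenario,
    make_life_table,
    simulate_registry,
    true_prevalence,
    truncate_to_registration,
)
from tests.conftest import make_record


def flat_scenario(rate_logit=-7.0, c=0.4, shape=1.0, scale=0.5, **kw):
    return SiteScenario(
        site="syn",
        age_profile=AgeProfile("loglinear", (rate_logit, 0.0)),
        cure_fraction={b: c for b in ("0-59", "60-74", "75+")},
        weibull_shape=shape,
        weibull_scale=scale,
        **kw,
    )


class TestSimulateRegistry:
    def test_zero_incidence_zero_records(self):
        sc = flat_scenario(rate_logit=-np.inf)
        cfg = SimulationConfig(registration_start_year=1990, population_per_age=100)
        sim = simulate_registry(sc, cfg, np.random.default_rng(0))
        assert sim.records == [] and sim.truth_records == []

    def test_reproducibility(self):
        sc = get_scenario("pancreas_like")
        cfg = SimulationConfig(registration_start_year=1990, population_per_age=50)
        a = simulate_registry(sc, cfg, np.random.default_rng(42))
        b = simulate_registry(sc, cfg, np.random.default_rng(42))
        assert a.records == b.records
        assert a.truth_records == b.truth_records

    def test_expected_incident_count(self):
        # simulated diagnoses agree with the analytic binomial expectation
        sc = flat_scenario(rate_logit=-7.0)
        cfg = SimulationConfig(
            registration_start_year=1960, sim_start_year=1960,
            population_per_age=400,
        )
        sim = simulate_registry(sc, cfg, np.random.default_rng(7))
        rate = 1.0 / (1.0 + np.exp(7.0))
        n_years = 2013 - 1960
        n_trials = n_years * 100 * 400 * 2  # years x ages x pop x sexes
        expected = n_trials * rate
        sd = np.sqrt(n_trials * rate * (1 - rate))
        assert abs(len(sim.records) - expected) < 3 * sd

    def test_cause_specific_survival_curve(self):
        # Kaplan-Meier style check against c + (1-c) exp(-(lambda t)^gamma)
        c, shape, scale = 0.4, 1.0, 0.5
        sc = flat_scenario(rate_logit=-6.1, c=c, shape=shape, scale=scale)
        cfg = SimulationConfig(
            registration_start_year=1953, population_per_age=600, loss_rate=0.0,
            life_table=make_life_table(1953, 2013, makeham=0.0, gompertz_a=1e-12),
        )
        sim = simulate_registry(sc, cfg, np.random.default_rng(5))
        # with no background mortality, death = cause-specific death
        recs = [r for r in sim.truth_records if r.date_dx.year <= 2007]
        n = len(recs)
        assert n > 10_000
        t = 5.0
        surviving = sum(
            1 for r in recs
            if r.vital_status == "alive"
            or (r.date_end - r.date_dx).days / 365.2425 > t
        )
        observed = surviving / n
        expected = c + (1 - c) * np.exp(-((scale * t) ** shape))
        assert abs(observed - expected) < 3 * np.sqrt(expected * (1 - expected) / n) + 0.01

    def test_loss_proportion_below_two_percent(self):
        sc = get_scenario("breast_like")
        cfg = SimulationConfig(registration_start_year=1978, population_per_age=1000)
        sim = simulate_registry(sc, cfg, np.random.default_rng(3))
        lost = sum(1 for r in sim.observed if r.vital_status == "lost")
        assert lost / len(sim.observed) < 0.02

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            SimulationConfig(registration_start_year=2014)
        with pytest.raises(ValueError):
            SimulationConfig(registration_start_year=1950, sim_start_year=1960)


class TestTruePrevalence:
    def test_everyone_dead_all_zero(self, index_date):
        records = [
            make_record(person_id=f"p{i}", vital_status="dead",
                        date_dx=date(1990, 1, 1), date_end=date(1995, 1, 1))
            for i in range(5)
        ]
        table = true_prevalence(records, index_date)
        assert table.total() == 0

    def test_hand_enumeration(self, index_date):
        # 2 alive at index (durations 3 and 12), 3 not prevalent
        records = [
            make_record(person_id="a", date_dx=date(2009, 6, 1), age_dx=50),
            make_record(person_id="b", date_dx=date(2000, 6, 1), age_dx=50),
            make_record(person_id="c", vital_status="dead",
                        date_dx=date(2000, 6, 1), date_end=date(2001, 1, 1)),
            make_record(person_id="d", date_dx=date(2013, 1, 1),
                        date_end=date(2013, 6, 1)),  # diagnosed on index date
            make_record(person_id="e", vital_status="dead",
                        date_dx=date(1990, 1, 1), date_end=date(2012, 12, 31)),
        ]
        table = true_prevalence(records, index_date)
        assert table.total(5) == 1
        assert table.total(15) == 2
        durations = dict(zip(table.counts["duration"], table.counts["count"]))
        assert durations == {3: 1.0, 12: 1.0}

    def test_rejects_lost_records(self, index_date):
        lost = make_record(vital_status="lost", date_end=date(2010, 1, 1))
        with pytest.raises(ValueError):
            true_prevalence([lost], index_date)

    def test_duration_horizon_equals_simulation_span(self):
        sc = flat_scenario(rate_logit=-6.5)
        cfg = SimulationConfig(registration_start_year=1953, population_per_age=60)
        sim = simulate_registry(sc, cfg, np.random.default_rng(9))
        unlimited = true_prevalence(sim.truth_records, cfg.index_date)
        span = cfg.index_date.year - cfg.sim_start_year
        capped = true_prevalence(sim.truth_records, cfg.index_date, max_duration=span)
        assert unlimited.total() == capped.total(span)


class TestTruncation:
    def _records(self):
        return [
            make_record(person_id="a", date_dx=date(1980, 5, 1)),
            make_record(person_id="b", date_dx=date(1989, 12, 31)),
            make_record(person_id="c", date_dx=date(1990, 1, 1)),
            make_record(person_id="d", date_dx=date(2000, 7, 1)),
        ]

    def test_identity_when_start_precedes_all(self):
        records = self._records()
        assert truncate_to_registration(records, 1970) == records

    def test_empty_when_start_after_all(self):
        assert truncate_to_registration(self._records(), 2005) == []

    def test_mixed(self):
        kept = truncate_to_registration(self._records(), 1990)
        assert [r.person_id for r in kept] == ["c", "d"]


class TestScenarioLibrary:
    def test_four_contrast_classes(self):
        assert set(SCENARIO_LIBRARY) == {
            "pancreas_like", "breast_like", "testis_like", "bimodal_like"
        }

    def test_testis_profile_early_onset(self):
        sc = get_scenario("testis_like")
        r30 = sc.incidence_rate(30, 1970)
        r70 = sc.incidence_rate(70, 1940)
        assert r30 > 5 * r70

    def test_breast_profile_late_onset(self):
        sc = breast_like()
        assert sc.incidence_rate(65, 1950) > 2 * sc.incidence_rate(35, 1975)

    def test_unknown_scenario(self):
        with pytest.raises(KeyError):
            get_scenario("nope")
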