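from datetime import date

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from previndex.incidence import (
    IncidenceModelParams,
    IncidenceTable,
    compare_aic,
    fit_logistic_age_cohort,
    predict_incidence,
    tabulate_incidence,
)
from previndex.registry import PopulationTable
from previndex.simulate import SimulationConfig, get_scenario, simulate_registry
from tests.conftest import make_record


def cells_from_rates(rate_fn, denominator=1_000_000, rng=None,
                     periods=range(1980, 2015, 5), sex="male", site="s"):
    """Build an IncidenceTable directly from a rate surface (optionally noisy)."""
    rows = []
    for p in periods:
        for lo in range(0, 85, 5):
            age_mid = lo + 2.5
            rate = rate_fn(age_mid, p + 2.5 - age_mid)
            count = (
                rng.binomial(denominator, rate) if rng is not None
                else rate * denominator
            )
            rows.append((sex, site, f"{lo}-{lo + 4}", p, count, denominator))
        rate = rate_fn(87.5, p + 2.5 - 87.5)
        count = rng.binomial(denominator, rate) if rng is not None else rate * denominator
        rows.append((sex, site, "85+", p, count, denominator))
    return IncidenceTable(pd.DataFrame(
        rows, columns=["sex", "site", "age_group", "period_start", "count",
                       "person_years"]))


class TestTabulate:
    def test_empty_records_zero_counts(self, small_population):
        table = tabulate_incidence([], small_population, (1980, 2012))
        assert len(table.df) == 0 or (table.df["count"] == 0).all()

    def test_hand_tally(self, small_population):
        records = (
            [make_record(person_id=f"a{i}", age_dx=62, date_dx=date(1992, 5, 1))
             for i in range(2)]
            + [make_record(person_id=f"b{i}", age_dx=47, date_dx=date(2003, 5, 1))
               for i in range(4)]
        )
        table = tabulate_incidence(records, small_population, (1990, 2012))
        counted = table.df[table.df["count"] > 0].set_index(["age_group", "period_start"])
        assert counted.loc[("60-64", 1990), "count"] == 2
        assert counted.loc[("45-49", 2000), "count"] == 4

    def test_person_years_arithmetic(self, small_population):
        records = [make_record(age_dx=62, date_dx=date(1992, 5, 1))]
        table = tabulate_incidence(records, small_population, (1990, 2012))
        cell = table.df[(table.df["age_group"] == "60-64")
                        & (table.df["period_start"] == 1990)]
        # 100,000 persons spread over ages 0-99 -> 1,000 per single age;
        # 5 ages x 5 years
        assert cell["person_years"].iloc[0] == pytest.approx(1000 * 5 * 5)

    def test_window_exclusion(self, small_population):
        records = [make_record(age_dx=62, date_dx=date(1975, 5, 1))]
        table = tabulate_incidence(records, small_population, (1980, 2012))
        # the only record falls before the window -> nothing tabulated for it
        assert (table.df["count"] == 0).all()


class TestFit:
    def test_flat_rate_null_model(self):
        p = 1e-4
        table = cells_from_rates(lambda a, c: p)
        fit = fit_logistic_age_cohort(table, "exponential")[0]
        assert fit.age_coefs[0] == pytest.approx(logit(p), abs=1e-6)
        assert fit.age_coefs[1] == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(fit.cohort_coefs, 0.0, atol=1e-6)

    def test_recovery_within_2se(self):
        b0, b1 = -9.0, 2.0
        effects = {1900: 0.0, 1910: 0.05, 1920: 0.1, 1930: 0.15}

        def rate(age_mid, cohort):
            # age midpoints span 2.5..87.5 -> the fit centres at 45, scale 42.5
            dec = min(max(int(cohort) // 10 * 10, 1900), 1930)
            return expit(b0 + b1 * (age_mid - 45.0) / 42.5 + effects[dec])

        table = cells_from_rates(rate, denominator=2_000_000,
                                 rng=np.random.default_rng(123),
                                 periods=range(1980, 2015, 5))
        fit = fit_logistic_age_cohort(table, "exponential")[0]
        # center/scale match the fitted scaling, so coefficients compare 1:1
        assert abs(fit.age_coefs[0] - b0) < 2 * fit.bse[0]
        assert abs(fit.age_coefs[1] - b1) < 2 * fit.bse[1]

    def test_bimodal_poly6_beats_exponential(self):
        sc = get_scenario("bimodal_like")
        rate = lambda a, c: float(sc.incidence_rate(min(a, 99), 1950))
        table = cells_from_rates(rate, denominator=500_000,
                                 rng=np.random.default_rng(5))
        fe = fit_logistic_age_cohort(table, "exponential")[0]
        fp = fit_logistic_age_cohort(table, "poly6")[0]
        assert fp.deviance < fe.deviance
        assert fp.aic < fe.aic


class TestPredict:
    def test_zero_coefficients_give_half(self):
        p = IncidenceModelParams(
            sex="male", site="s", age_form="exponential",
            age_coefs=np.zeros(2), age_center=40.0, age_scale=40.0,
            cohort_decades=np.array([1950]), cohort_coefs=np.zeros(1),
            llf=0.0, aic=0.0, deviance=0.0, n_params=2,
        )
        assert predict_incidence(p, 50, 1955) == pytest.approx(0.5)

    def test_hand_linear_predictor(self):
        p = IncidenceModelParams(
            sex="male", site="s", age_form="exponential",
            age_coefs=np.array([-8.0, 1.5]), age_center=40.0, age_scale=40.0,
            cohort_decades=np.array([1950, 1960]),
            cohort_coefs=np.array([0.0, 0.3]),
            llf=0.0, aic=0.0, deviance=0.0, n_params=3,
        )
        eta = -8.0 + 1.5 * (60 - 40) / 40 + 0.3
        assert predict_incidence(p, 60, 1965) == pytest.approx(expit(eta))

    def test_constant_cohort_extrapolation(self):
        p = IncidenceModelParams(
            sex="male", site="s", age_form="exponential",
            age_coefs=np.array([-8.0, 1.0]), age_center=40.0, age_scale=40.0,
            cohort_decades=np.array([1950, 1960]),
            cohort_coefs=np.array([0.0, 0.4]),
            llf=0.0, aic=0.0, deviance=0.0, n_params=3,
        )
        assert predict_incidence(p, 50, 1890) == predict_incidence(p, 50, 1950)
        assert predict_incidence(p, 50, 2010) == predict_incidence(p, 50, 1965)

    def test_rates_bounded(self):
        p = IncidenceModelParams(
            sex="male", site="s", age_form="poly6",
            age_coefs=np.array([-6.0, 2.0, -1.0, 0.5, 0.2, -0.3, 0.1]),
            age_center=42.5, age_scale=42.5,
            cohort_decades=np.array([1900, 1950]),
            cohort_coefs=np.array([0.0, 0.5]),
            llf=0.0, aic=0.0, deviance=0.0, n_params=8,
        )
        ages = np.arange(0, 100)
        for cohort in (1880, 1920, 1980, 2010):
            r = predict_incidence(p, ages, cohort)
            assert np.all((r > 0) & (r < 1))


class TestCompareAic:
    def _fit(self, aic, k, form="exponential"):
        return IncidenceModelParams(
            sex="male", site="s", age_form=form,
            age_coefs=np.zeros(2), age_center=40.0, age_scale=40.0,
            cohort_decades=np.array([1950]), cohort_coefs=np.zeros(1),
            llf=-aic / 2 + k, aic=aic, deviance=0.0, n_params=k,
        )

    def test_tie_prefers_fewer_parameters(self):
        small = self._fit(100.0, 3)
        big = self._fit(100.0, 8, form="poly6")
        best, _ = compare_aic([big, small])
        assert best is small

    def test_single_candidate(self):
        only = self._fit(50.0, 3)
        best, table = compare_aic([only])
        assert best is only and len(table) == 1

    def test_lowest_aic_selected(self):
        a, b = self._fit(120.0, 3), self._fit(90.0, 8, form="poly6")
        best, _ = compare_aic([a, b])
        assert best is b
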