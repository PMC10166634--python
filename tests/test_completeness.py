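from datetime import date

import numpy as np
import pandas as pd
import pytest

from previndex.completeness import (
    CompletenessIndex,
    CompletenessIndexError,
    complete_prevalence,
    empirical_R,
    extend_prevalence,
    extend_prevalence_table,
    load_external_index,
    model_based_R,
    write_index,
)
from previndex.registry import EMPIRICAL_SCHEME, MODEL_SCHEME, PrevalenceTable

IDX = date(2013, 1, 1)


def prevalence_table(cells, max_duration=35, grouping=EMPIRICAL_SCHEME):
    df = pd.DataFrame(cells, columns=["sex", "site", "age_group", "duration", "count"])
    return PrevalenceTable(IDX, df, max_duration=max_duration, grouping=grouping)


def index_from(rows, method="model", grouping=EMPIRICAL_SCHEME):
    df = pd.DataFrame(rows, columns=["sex", "site", "age_group", "duration", "R"])
    return CompletenessIndex(method, IDX, df, grouping=grouping)


class TestEmpiricalR:
    def _table(self):
        cells = []
        # 80 cases within 5 years, 20 more spread to 35 years
        for d in range(5):
            cells.append(("male", "colon", "60-64", d, 16.0))
        for d in (10, 20, 30, 34):
            cells.append(("male", "colon", "60-64", d, 5.0))
        return prevalence_table(cells)

    def test_direct_ratio(self):
        idx = empirical_R(self._table(), 35)
        assert idx.lookup("male", "colon", "60-64", 5) == pytest.approx(0.80)

    def test_r_is_one_at_max_duration(self):
        idx = empirical_R(self._table(), 35)
        assert idx.lookup("male", "colon", "60-64", 35) == pytest.approx(1.0)

    def test_monotone_in_duration(self):
        idx = empirical_R(self._table(), 35)
        r = [idx.lookup("male", "colon", "60-64", d) for d in range(1, 36)]
        assert all(a <= b + 1e-12 for a, b in zip(r, r[1:]))

    def test_zero_denominator_cell_missing(self):
        table = prevalence_table(
            [("male", "colon", "60-64", 2, 4.0), ("male", "colon", "70-74", 3, 0.0)],
            max_duration=35,
        )
        idx = empirical_R(table, 35)
        assert idx.lookup("male", "colon", "70-74", 5) is None

    def test_max_duration_beyond_table_rejected(self):
        with pytest.raises(CompletenessIndexError):
            empirical_R(self._table(), 40)

    def test_model_grouping_collapsed(self):
        cells = [("male", "colon", "25-29", 2, 4.0), ("male", "colon", "85+", 3, 6.0)]
        table = prevalence_table(cells, max_duration=10, grouping=MODEL_SCHEME)
        idx = empirical_R(table, 10)
        assert idx.lookup("male", "colon", "0-29", 10) == pytest.approx(1.0)
        assert idx.lookup("male", "colon", "80+", 10) == pytest.approx(1.0)


class TestModelBasedR:
    def test_closed_form_no_mortality(self, flat_life_table):
        # stationary incidence, RS = 1, expected survival = 1 -> R = d/a
        idx = model_based_R(
            lambda age, cohort: 1e-4,
            lambda t, age_dx: 1.0,
            flat_life_table, IDX, "male", "s",
            durations=[5, 15, 35], a_min=0, group=False,
        )
        for a in (40, 60, 80):
            for d in (5, 15, 35):
                assert idx.lookup("male", "s", str(a), d) == pytest.approx(
                    d / a, abs=1e-6
                )

    def test_exhausted_survivorship_r_one(self, flat_life_table):
        # no patient survives beyond ~2 years -> R = 1 for d >= 3
        idx = model_based_R(
            lambda age, cohort: 1e-4,
            lambda t, age_dx: max(0.0, 1.0 - t / 2.0),
            flat_life_table, IDX, "male", "s",
            durations=[3, 10, 35], a_min=0, group=False,
        )
        for a in (40, 70):
            assert idx.lookup("male", "s", str(a), 3) == pytest.approx(1.0)
            assert idx.lookup("male", "s", str(a), 10) == pytest.approx(1.0)

    def test_grouped_output_in_bounds_and_monotone(self, simple_life_table):
        idx = model_based_R(
            lambda age, cohort: 1e-4 * (1 + age / 50.0),
            lambda t, age_dx: 0.3 + 0.7 * np.exp(-0.4 * t),
            simple_life_table, IDX, "male", "s",
            durations=range(1, 36), a_min=0,
        )
        for g, sub in idx.values.groupby("age_group"):
            r = sub.sort_values("duration")["R"].to_numpy()
            assert np.all((r > 0) & (r <= 1.0))
            assert np.all(np.diff(r) >= -1e-12)


class TestCompleteAndExtend:
    def test_arithmetic(self):
        table = prevalence_table([("male", "colon", "60-64", d, 100.0) for d in range(5)],
                                 max_duration=5)
        idx = index_from([("male", "colon", "60-64", 5, 0.8)])
        out = complete_prevalence(table, idx)
        assert out["complete"].iloc[0] == pytest.approx(500 / 0.8)

    def test_r_one_unchanged(self):
        table = prevalence_table([("male", "colon", "60-64", 0, 7.0)], max_duration=1)
        idx = index_from([("male", "colon", "60-64", 1, 1.0)])
        out = complete_prevalence(table, idx)
        assert out["complete"].iloc[0] == pytest.approx(7.0)

    def test_never_below_observed(self):
        table = prevalence_table([("male", "colon", "60-64", 0, 7.0)], max_duration=1)
        idx = index_from([("male", "colon", "60-64", 1, 0.37)])
        out = complete_prevalence(table, idx)
        assert (out["complete"] >= out["observed"] - 1e-12).all()

    def test_missing_r_with_nonzero_count_raises(self):
        table = prevalence_table([("male", "colon", "60-64", 0, 7.0)], max_duration=1)
        idx = index_from([("male", "colon", "70-74", 1, 0.9)])
        with pytest.raises(CompletenessIndexError):
            complete_prevalence(table, idx)

    def test_zero_count_with_missing_r_is_zero(self):
        table = prevalence_table([("male", "colon", "60-64", 0, 0.0)], max_duration=1)
        idx = index_from([("male", "colon", "70-74", 1, 0.9)])
        out = complete_prevalence(table, idx)
        assert out["complete"].iloc[0] == 0.0

    def test_extend_scalar(self):
        # N15=90, R15=0.9, R20=0.95 -> 95
        assert extend_prevalence(90.0, 0.9, 0.95) == pytest.approx(95.0)

    def test_extend_identity_same_duration(self):
        table = prevalence_table([("male", "colon", "60-64", d, 10.0) for d in range(15)],
                                 max_duration=20)
        idx = index_from([("male", "colon", "60-64", d, min(0.04 * d + 0.2, 1.0))
                          for d in range(1, 21)])
        out = extend_prevalence_table(table, idx, 15, 15)
        assert out["estimated"].iloc[0] == pytest.approx(out["observed"].iloc[0])

    def test_extend_to_max_matches_complete(self):
        cells = [("male", "colon", "60-64", d, 10.0) for d in range(20)]
        table = prevalence_table(cells, max_duration=20)
        idx = index_from([("male", "colon", "60-64", d, min(0.04 * d + 0.2, 1.0))
                          for d in range(1, 21)])
        ext = extend_prevalence_table(table, idx, 20, 20)
        comp = complete_prevalence(table, idx)
        # with R(20) as the complete-prevalence index, N20/R20 vs extension
        assert comp["complete"].iloc[0] == pytest.approx(
            ext["estimated"].iloc[0] / idx.lookup("male", "colon", "60-64", 20)
        )


class TestIndexValidation:
    def test_r_above_one_rejected(self):
        with pytest.raises(CompletenessIndexError):
            index_from([("male", "colon", "60-64", 5, 1.2)])

    def test_r_zero_rejected(self):
        with pytest.raises(CompletenessIndexError):
            index_from([("male", "colon", "60-64", 5, 0.0)])

    def test_tiny_overshoot_clipped(self):
        idx = index_from([("male", "colon", "60-64", 5, 1.0 + 1e-10)])
        assert idx.lookup("male", "colon", "60-64", 5) == 1.0


class TestExternalIndex:
    def test_round_trip(self, tmp_path):
        idx = index_from([("male", "colon", "60-64", d, min(0.1 * d, 1.0))
                          for d in range(1, 11)])
        path = tmp_path / "index.csv"
        write_index(idx, path)
        loaded = load_external_index(path)
        assert loaded.method == "external"
        for d in range(1, 11):
            assert loaded.lookup("male", "colon", "60-64", d) == pytest.approx(
                idx.lookup("male", "colon", "60-64", d)
            )

    def test_invalid_r_rejected(self, tmp_path):
        path = tmp_path / "index.csv"
        pd.DataFrame(
            {"sex": ["male"], "site": ["colon"], "age_group": ["60-64"],
             "duration": [5], "R": [1.2]}
        ).to_csv(path, index=False)
        with pytest.raises(CompletenessIndexError):
            load_external_index(path)

    def test_monotonicity_violation_warns(self, tmp_path, caplog):
        path = tmp_path / "index.csv"
        pd.DataFrame(
            {"sex": ["male"] * 2, "site": ["colon"] * 2, "age_group": ["60-64"] * 2,
             "duration": [5, 10], "R": [0.9, 0.5]}
        ).to_csv(path, index=False)
        import logging

        with caplog.at_level(logging.WARNING, logger="previndex.completeness"):
            load_external_index(path)
        assert any("non-decreasing" in m for m in caplog.messages)
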