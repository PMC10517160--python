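"""Feature vector assembly: chr, MET, response, anthropometrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import vo2quant as vq
from vo2quant import features, preprocessing
from conftest import minutes_frame


class TestChrFeature:
    def test_single_activity_minute(self):
        out = features.chr_feature([100.0], [100.0])
        assert out.tolist() == [1.0, 1.0, 1.0]

    def test_three_point_quartiles(self):
        # ratios 0.8, 1.0, 1.2 -> linear-interpolated quartiles
        hr = np.array([100.0, 100.0, 100.0])
        c = np.array([80.0, 100.0, 120.0])
        assert features.chr_feature(hr, c) == pytest.approx([0.9, 1.0, 1.1])

    def test_no_activity_minutes_is_missing(self):
        out = features.chr_feature([100.0, 90.0], [60.0, 10.0])
        assert np.isnan(out).all()

    @given(st.lists(st.floats(61, 220), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_quartiles_monotone(self, cadences):
        hr = np.full(len(cadences), 120.0)
        q25, q50, q75 = features.chr_feature(hr, np.array(cadences))
        assert 0 < q25 <= q50 <= q75


class TestMetMinute:
    def test_resting_gives_one(self):
        assert features.met_minute(60.0, 60.0) == 1.0

    def test_reference_point(self):
        assert features.met_minute(75.0, 60.0) == 2.5

    def test_floor_below_resting(self):
        # raw value is 0; clipped to the physiological floor of 1
        assert features.met_minute(50.0, 60.0) == 1.0

    def test_nonpositive_resting_rejected(self):
        with pytest.raises(ValueError):
            features.met_minute(70.0, 0.0)

    @given(st.floats(30, 220), st.floats(35, 100))
    @settings(max_examples=100, deadline=None)
    def test_at_least_one_and_monotone(self, hr, hr_rest):
        v = features.met_minute(hr, hr_rest)
        assert v >= 1.0
        assert features.met_minute(hr + 5.0, hr_rest) >= v


class TestDailyMet:
    def test_full_resting_day(self):
        assert features.daily_met(np.full(1440, 60.0), 60.0) == pytest.approx(1.0)

    def test_uncovered_minutes_count_as_one(self):
        # 60 covered minutes at MET 3 -> (180 + 1380) / 1440
        hr_at_met3 = 60.0 * (3.0 + 5.0) / 6.0  # inverse of the MET formula
        v = features.daily_met(np.full(60, hr_at_met3), 60.0)
        assert v == pytest.approx((180 + 1380) / 1440)

    def test_empty_day_rejected(self):
        with pytest.raises(Exception):
            features.daily_met(np.array([]), 60.0)

    def test_fully_uncovered_limit_is_one(self):
        # a single covered resting minute: value -> 1 as coverage -> 0
        assert features.daily_met(np.array([60.0]), 60.0) == pytest.approx(
            (1 + 1439) / 1440
        )


class TestMetFeature:
    def test_single_day(self):
        assert features.met_feature([1.1]).tolist() == [1.1, 1.1, 1.1]

    def test_five_day_quartiles(self):
        out = features.met_feature([1.0, 1.1, 1.2, 1.3, 1.4])
        assert out == pytest.approx([1.1, 1.2, 1.3])

    def test_no_days_is_missing(self):
        assert np.isnan(features.met_feature([])).all()


class TestDailyMetSeries:
    def test_matches_pandas_resting_hr_path(self, tiny_cohort):
        # the vectorised day loop must agree with the reference per-day
        # resting-heart-rate computation
        uid = tiny_cohort.users["user_id"].iloc[0]
        mins = tiny_cohort.minutes[tiny_cohort.minutes["user_id"] == uid]
        rest = preprocessing.daily_resting_hr(mins)
        hr = mins["hr"].to_numpy(dtype=float)
        dates = pd.to_datetime(mins["minute"]).dt.date
        expected = [
            features.daily_met(hr[np.asarray(dates == d)], rest.loc[d])
            for d in rest.index
        ]
        got = features.daily_met_series(mins["minute"].to_numpy(), hr)
        assert got == pytest.approx(expected)


class TestResponseFeature:
    def test_noiseless_user_repeats_coefficients(self):
        rng = np.random.default_rng(0)
        c = rng.uniform(61, 180, 400)
        hr = 95 + 0.25 * np.minimum(c, 100) + 0.45 * np.maximum(c - 100, 0)
        coefs, low = features.response_feature(hr, c)
        assert len(coefs) == 15
        assert not low
        assert coefs.reshape(5, 3) == pytest.approx(
            np.tile([95, 0.25, 0.45], (5, 1)), abs=1e-6
        )

    def test_no_qualifying_minutes_is_missing(self):
        coefs, low = features.response_feature([70.0, 74.0], [100.0, 120.0])
        assert np.isnan(coefs).all() and low

    def test_low_data_flag(self):
        hr = np.full(10, 120.0) + np.arange(10)
        c = np.linspace(61, 170, 10)
        coefs, low = features.response_feature(hr, c)
        assert len(coefs) == 15 and low


class TestAssemble:
    def ant(self):
        return features.AnthroFeature(age=35.0, gender=1.0, bmi=24.0)

    def test_length_and_order(self):
        x = features.assemble(
            self.ant(), [0.9, 1.0, 1.1], [1.0, 1.1, 1.2], np.arange(15.0)
        )
        assert len(x) == 24
        assert x[:3].tolist() == [35.0, 1.0, 24.0]
        assert x[9:].tolist() == list(np.arange(15.0))

    def test_bmi_formula(self):
        assert features.bmi(67.9, 1.709) == pytest.approx(23.24, abs=0.01)

    def test_all_missing_streams(self):
        x = features.user_features(
            pd.DataFrame(columns=["minute", "hr", "cadence"]), self.ant()
        )
        assert len(x) == 24
        assert np.isfinite(x[:3]).all()
        assert np.isnan(x[3:]).all()

    def test_deterministic_bit_for_bit(self):
        mins = minutes_frame(
            "2021-01-01 12:00", np.linspace(80, 150, 120), np.linspace(0, 180, 120)
        )
        x1 = features.user_features(mins, self.ant())
        x2 = features.user_features(mins.copy(), self.ant())
        assert (x1 == x2).all()


class TestExtractFeatures:
    def test_table_shape_and_names(self, small_features):
        assert list(small_features.columns) == (
            ["user_id"] + features.FEATURE_NAMES + ["active_minutes"]
        )
        assert len(features.FEATURE_NAMES) == 24

    def test_quartile_columns_monotone(self, small_features):
        for base in ("chr", "met"):
            sub = small_features[[f"{base}25", f"{base}50", f"{base}75"]].dropna()
            assert (sub[f"{base}25"] <= sub[f"{base}50"]).all()
            assert (sub[f"{base}50"] <= sub[f"{base}75"]).all()

    def test_met_floor(self, small_features):
        sub = small_features[["met25", "met50", "met75"]].dropna()
        assert (sub >= 1.0).all().all()

    def test_lookback_window_reduces_active_minutes(self, small_cohort, small_features):
        short = vq.extract_features(
            small_cohort.minutes, small_cohort.users, lookback_days=1
        )
        assert (
            short["active_minutes"] <= small_features["active_minutes"]
        ).all()

    def test_string_gender_codes(self, tiny_cohort, tmp_path):
        tiny_cohort.write_csv(tmp_path)
        users = pd.read_csv(tmp_path / "users.csv")
        assert set(users["gender"]) <= {"f", "m"}
        feats = vq.extract_features(tiny_cohort.minutes, users)
        assert set(feats["gender"]) <= {0.0, 1.0}
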