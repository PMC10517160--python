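"""Minute resampling, step proration, resting heart rate."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vo2quant import preprocessing as pp


def hr_frame(pairs):
    return pd.DataFrame(
        {"timestamp": pd.to_datetime([t for t, _ in pairs]), "bpm": [b for _, b in pairs]}
    )


def steps_frame(rows):
    return pd.DataFrame(
        {
            "start": pd.to_datetime([r[0] for r in rows]),
            "end": pd.to_datetime([r[1] for r in rows]),
            "steps": [r[2] for r in rows],
        }
    )


class TestResampleHr:
    @pytest.mark.parametrize(
        "pairs, expected",
        [
            ([("2021-01-01 12:00:30", 70.0)], [("2021-01-01 12:00", 70.0)]),
            (
                [("2021-01-01 12:00:10", 60.0), ("2021-01-01 12:00:50", 80.0)],
                [("2021-01-01 12:00", 70.0)],
            ),
        ],
    )
    def test_minute_means(self, pairs, expected):
        out = pp.resample_hr(hr_frame(pairs))
        assert list(out["minute"]) == [pd.Timestamp(t) for t, _ in expected]
        assert out["hr"].tolist() == [v for _, v in expected]

    def test_one_hertz_block_means(self):
        # 90 samples at 1 Hz: 60 at bpm 60 then 30 at bpm 90
        ts = pd.date_range("2021-01-01 12:00:00", periods=90, freq="s")
        bpm = np.where(np.arange(90) < 60, 60.0, 90.0)
        out = pp.resample_hr(pd.DataFrame({"timestamp": ts, "bpm": bpm}))
        # oracle: brute-force grouping by floor-to-minute
        floor = ts.floor("min")
        oracle = pd.Series(bpm).groupby(floor).mean()
        assert out["hr"].tolist() == oracle.tolist()
        assert out["hr"].tolist() == [60.0, 90.0]

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(pp.EmptySeriesError):
            pp.resample_hr(hr_frame([]))
        with pytest.raises(ValueError):
            pp.resample_hr(hr_frame([("2021-01-01 12:00", np.nan)]))
        with pytest.raises(ValueError):
            pp.resample_hr(hr_frame([("2021-01-01 12:00", 300.0)]))

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=20, deadline=None)
    def test_order_invariance(self, rnd):
        ts = pd.date_range("2021-01-01 10:00:00", periods=40, freq="37s")
        bpm = np.linspace(60, 120, 40)
        df = pd.DataFrame({"timestamp": ts, "bpm": bpm})
        shuffled = df.sample(frac=1.0, random_state=rnd.randrange(2**31))
        pd.testing.assert_frame_equal(pp.resample_hr(df), pp.resample_hr(shuffled))


class TestCadence:
    def test_exact_containment(self):
        c = pp.compute_cadence(
            steps_frame([("2021-01-01 12:00", "2021-01-01 12:01", 100)]),
            pd.to_datetime(["2021-01-01 12:01"]),
        )
        assert c.tolist() == [100.0]

    def test_two_minute_interval_prorated_uniformly(self):
        c = pp.compute_cadence(
            steps_frame([("2021-01-01 12:00", "2021-01-01 12:02", 120)]),
            pd.to_datetime(["2021-01-01 12:01", "2021-01-01 12:02"]),
        )
        assert c.tolist() == [60.0, 60.0]

    def test_no_intervals_gives_zero(self):
        c = pp.compute_cadence(
            steps_frame([]), pd.to_datetime(["2021-01-01 12:01"])
        )
        assert c.tolist() == [0.0]

    def test_partial_minute_overlap(self):
        # interval 12:00:30-12:01:30, 60 steps -> 30 to each adjacent window
        c = pp.compute_cadence(
            steps_frame([("2021-01-01 12:00:30", "2021-01-01 12:01:30", 60)]),
            pd.to_datetime(["2021-01-01 12:01", "2021-01-01 12:02"]),
        )
        assert c.tolist() == pytest.approx([30.0, 30.0])

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            pp.prorate_steps(
                steps_frame(
                    [
                        ("2021-01-01 12:00", "2021-01-01 12:02", 100),
                        ("2021-01-01 12:01", "2021-01-01 12:03", 100),
                    ]
                )
            )

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            pp.prorate_steps(
                steps_frame([("2021-01-01 12:01", "2021-01-01 12:00", 10)])
            )

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 5000),  # start offset, seconds
                st.integers(1, 600),  # duration, seconds
                st.integers(0, 500),  # steps
            ),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_step_conservation(self, raw):
        # lay intervals end-to-end so they never overlap
        t = pd.Timestamp("2021-01-01 09:00:00")
        rows = []
        for gap, dur, steps in raw:
            start = t + pd.Timedelta(seconds=gap)
            end = start + pd.Timedelta(seconds=dur)
            rows.append((start, end, steps))
            t = end
        prorated = pp.prorate_steps(steps_frame(rows))
        assert prorated.sum() == pytest.approx(sum(r[2] for r in rows))


class TestRestingHr:
    def day(self, start, hrs):
        n = len(hrs)
        return pd.DataFrame(
            {
                "minute": pd.date_range(start, periods=n, freq="min"),
                "hr": np.asarray(hrs, dtype=float),
            }
        )

    def test_constant_window(self):
        assert pp.resting_hr(self.day("2021-01-01 13:00", [60.0] * 30)) == 60.0

    def test_linear_interpolated_percentile(self):
        values = [50, 60, 70, 80, 90, 100, 110, 120, 130, 140, 150]
        assert pp.resting_hr(self.day("2021-01-01 12:00", values)) == pytest.approx(60.0)

    def test_fallback_to_whole_day(self):
        assert pp.resting_hr(self.day("2021-01-01 06:00", [55.0] * 20)) == 55.0

    def test_duplicates_outside_window_ignored(self):
        base = self.day("2021-01-01 13:00", [60, 65, 70, 75, 80])
        extra = self.day("2021-01-01 05:00", [40.0] * 10)
        assert pp.resting_hr(pd.concat([base, extra])) == pp.resting_hr(base)

    def test_empty_day_rejected(self):
        with pytest.raises(pp.EmptySeriesError):
            pp.resting_hr(self.day("2021-01-01", []))


class TestMerge:
    def test_mismatched_lengths_rejected(self):
        hr = pp.resample_hr(hr_frame([("2021-01-01 12:00:30", 70.0)]))
        with pytest.raises(ValueError):
            pp.merge_streams(hr, [1.0, 2.0])

    def test_zip(self):
        hr = pp.resample_hr(hr_frame([("2021-01-01 12:00:30", 70.0)]))
        out = pp.merge_streams(hr, [80.0])
        assert out.loc[0, "cadence"] == 80.0
        assert out.loc[0, "hr"] == 70.0

    def test_one_sample_per_minute_roundtrip_identity(self):
        ts = pd.date_range("2021-01-01 08:00:00", periods=120, freq="min")
        bpm = np.linspace(55, 110, 120)
        merged = pp.preprocess_user(
            pd.DataFrame({"timestamp": ts, "bpm": bpm}), steps_frame([])
        )
        assert (merged["minute"] == ts).all()
        assert merged["hr"].to_numpy() == pytest.approx(bpm)


class TestCsvReaders:
    def test_strict_headers(self, tmp_path):
        p = tmp_path / "hr.csv"
        p.write_text("user,when,bpm\nu1,2021-01-01T12:00:00,70\n")
        with pytest.raises(ValueError, match="expected columns"):
            pp.read_hr_csv(p)

    def test_rejects_unparseable_rows(self, tmp_path, caplog):
        p = tmp_path / "hr.csv"
        p.write_text(
            "user_id,timestamp,bpm\n"
            "u1,2021-01-01T12:00:00,70\n"
            "u1,2021-01-01T12:01:00,notanumber\n"
        )
        with caplog.at_level("WARNING", logger="vo2quant"):
            out = pp.read_hr_csv(p)
        assert len(out) == 1
        assert any("rejected 1" in r.message for r in caplog.records)

    def test_offset_timestamps_keep_wall_clock(self, tmp_path):
        p = tmp_path / "hr.csv"
        p.write_text(
            "user_id,timestamp,bpm\nu1,2021-01-01T12:00:30+03:00,70\n"
        )
        out = pp.read_hr_csv(p)
        assert out.loc[0, "timestamp"] == pd.Timestamp("2021-01-01 12:00:30")
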