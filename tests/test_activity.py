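"""Bouts, legal hours, daily records, subsampling and diel profiles."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from bearacc import activity as act
from bearacc import synthetic as syn
from bearacc.solar import sunrise_sunset
from oracles import brute_bouts


def label_frame(labels, bear_id="b1", start="2019-08-05 10:00:00", step_s=3.0):
    ts = pd.Timestamp(start) + pd.to_timedelta(np.arange(len(labels)) * step_s, unit="s")
    return pd.DataFrame({"bear_id": bear_id, "window_start": ts, "label": list(labels)})


class TestMergeFeedwalk:
    def test_walking_and_feeding_both_map_to_feedwalking(self):
        s = pd.Series(["walking", "feeding", "resting", "running"])
        assert list(act.merge_feedwalk(s)) == ["feedwalking", "feedwalking", "resting", "running"]

    def test_all_resting_unchanged(self):
        s = pd.Series(["resting"] * 5)
        assert list(act.merge_feedwalk(s)) == ["resting"] * 5

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        s = pd.Series(rng.choice(["walking", "feeding", "resting", "running"], size=500))
        merged = act.merge_feedwalk(s)
        assert (merged == "feedwalking").sum() == (s.isin(["walking", "feeding"])).sum()
        assert len(merged) == len(s)


class TestDetectBouts:
    def test_run_length_encoding_example(self):
        df = label_frame(["running", "running", "walking", "running"])
        bouts = act.detect_bouts(df, "running")
        assert len(bouts) == 2
        assert bouts["duration_s"].tolist() == [6.0, 3.0]
        assert bouts["n_windows"].tolist() == [2, 1]

    def test_no_target_labels_gives_empty(self):
        assert act.detect_bouts(label_frame(["resting"] * 10), "running").empty

    def test_recording_gap_splits_a_bout(self):
        df = label_frame(["running"] * 6)
        df = pd.concat([df.iloc[:3], df.iloc[3:].assign(
            window_start=df["window_start"].iloc[3:] + pd.Timedelta(seconds=30)
        )]).reset_index(drop=True)
        bouts = act.detect_bouts(df, "running")
        assert len(bouts) == 2

    def test_matches_rle_oracle_on_random_sequences(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            labels = rng.choice(["resting", "feedwalking", "running"], size=rng.integers(1, 60))
            df = label_frame(labels)
            bouts = act.detect_bouts(df, "running")
            expected = brute_bouts(list(labels), "running")
            assert len(bouts) == len(expected)
            assert bouts["n_windows"].tolist() == [n for _, n in expected]

    def test_bout_windows_conserve_label_count(self):
        rng = np.random.default_rng(2)
        labels = rng.choice(["resting", "running"], size=400)
        bouts = act.detect_bouts(label_frame(labels), "running")
        assert bouts["n_windows"].sum() == (labels == "running").sum()


class TestLegalHours:
    def test_interval_nonempty_for_every_august_date(self):
        for day in range(1, 32):
            lo, hi = act.legal_hours(dt.date(2019, 8, day))
            assert lo < hi

    def test_longitude_shift_moves_bounds_by_minus_one_hour(self):
        cal_e = act.StudyCalendar(site_lon=30.0)
        lo0, hi0 = act.legal_hours(dt.date(2019, 8, 10), act.StudyCalendar())
        lo1, hi1 = act.legal_hours(dt.date(2019, 8, 10), cal_e)
        assert abs((lo1 - lo0).total_seconds() + 3600) < 1.0
        assert abs((hi1 - hi0).total_seconds() + 3600) < 1.0

    def test_bounds_are_sunrise_minus_1h_and_sunset_minus_2h(self):
        date = dt.date(2019, 8, 21)
        sunrise, sunset = sunrise_sunset(date, 61.0, 15.0, 2.0)
        lo, hi = act.legal_hours(date)
        assert lo == sunrise - dt.timedelta(hours=1)
        assert hi == sunset - dt.timedelta(hours=2)

    def test_august_solar_times_in_plausible_local_range(self):
        sunrise, sunset = sunrise_sunset(dt.date(2019, 8, 21), 61.0, 15.0, 2.0)
        assert dt.time(4, 0) < sunrise.time() < dt.time(7, 0)
        assert dt.time(19, 0) < sunset.time() < dt.time(22, 30)

    def test_polar_night_reported(self):
        with pytest.raises(ValueError, match="polar"):
            sunrise_sunset(dt.date(2019, 12, 21), 80.0, 15.0, 2.0)


class TestDailyMetrics:
    def make_bouts(self, starts, bear_id="b1"):
        return pd.DataFrame(
            {
                "bear_id": bear_id,
                "behavior": "running",
                "start": pd.to_datetime(starts),
                "end": pd.to_datetime(starts) + pd.Timedelta(seconds=6),
                "duration_s": 6.0,
                "n_windows": 2,
            }
        )

    def test_three_of_four_bouts_in_legal_hours(self):
        date = dt.date(2019, 8, 10)
        lo, hi = act.legal_hours(date)
        bouts = self.make_bouts(
            [
                lo + dt.timedelta(hours=1),
                lo + dt.timedelta(hours=2),
                hi - dt.timedelta(hours=1),
                hi + dt.timedelta(hours=1),  # after legal close
            ]
        )
        labels = label_frame(["resting"] * 10, start="2019-08-10 12:00:00")
        rec = act.daily_metrics(bouts, labels)
        assert rec["n_running_bouts"].iloc[0] == 4
        assert rec["prop_legal"].iloc[0] == pytest.approx(0.75)

    def test_half_open_boundary_convention(self):
        date = dt.date(2019, 8, 10)
        lo, hi = act.legal_hours(date)
        bouts = self.make_bouts([lo, hi])  # exactly at the two bounds
        labels = label_frame(["resting"] * 10, start="2019-08-10 12:00:00")
        rec = act.daily_metrics(bouts, labels)
        assert rec["n_bouts_legal_hours"].iloc[0] == 1  # start in, end out

    def test_day_without_bouts_has_undefined_proportion(self):
        labels = label_frame(["resting"] * 10, start="2019-08-10 12:00:00")
        rec = act.daily_metrics(self.make_bouts([]), labels)
        assert rec["n_running_bouts"].iloc[0] == 0
        assert np.isnan(rec["prop_legal"].iloc[0])

    def test_bouts_forced_into_legal_hours_give_proportion_one(self):
        frames, bouts = [], []
        for day in range(5, 10):
            date = dt.date(2019, 8, day)
            lo, _ = act.legal_hours(date)
            bouts.append(self.make_bouts([lo + dt.timedelta(hours=h) for h in (1, 2, 3)]))
            frames.append(label_frame(["resting"] * 10, start=f"2019-08-{day:02d} 12:00:00"))
        rec = act.daily_metrics(pd.concat(bouts, ignore_index=True), pd.concat(frames, ignore_index=True))
        assert (rec["prop_legal"] == 1.0).all()

    def test_period_assignment_at_hunting_onset(self):
        labels = pd.concat(
            [
                label_frame(["resting"] * 4, start="2019-08-20 10:00:00"),
                label_frame(["resting"] * 4, start="2019-08-21 10:00:00"),
            ],
            ignore_index=True,
        )
        rec = act.daily_metrics(self.make_bouts([]), labels).set_index("date")
        assert rec.loc[dt.date(2019, 8, 20), "period"] == "pre_hunting"
        assert rec.loc[dt.date(2019, 8, 21), "period"] == "hunting"

    def test_bear_without_demographics_excluded(self, caplog):
        labels = pd.concat(
            [
                label_frame(["resting"] * 4, bear_id="b1"),
                label_frame(["resting"] * 4, bear_id="ghost"),
            ],
            ignore_index=True,
        )
        demo = pd.DataFrame({"bear_id": ["b1"], "demographic_group": ["adult_male"]})
        with caplog.at_level("WARNING"):
            rec = act.daily_metrics(self.make_bouts([]), labels, demographics=demo)
        assert set(rec["bear_id"]) == {"b1"}
        assert "ghost" in caplog.text

    def test_every_august_date_maps_to_exactly_one_period(self):
        cal = act.StudyCalendar()
        for day in range(1, 32):
            assert cal.period_of(dt.date(2021, 8, day)) in {"pre_hunting", "hunting"}
        assert cal.period_of(dt.date(2021, 7, 31)) is None
        assert cal.period_of(dt.date(2021, 9, 1)) is None


class TestDailyDistance:
    def test_stationary_track_travels_zero(self):
        ts = pd.date_range("2019-08-01", periods=24, freq="h")
        gps = pd.DataFrame({"timestamp": ts, "x_m": 0.0, "y_m": 0.0})
        assert act.daily_distance(gps)["daily_distance_m"].iloc[0] == 0.0

    def test_three_four_five_segment(self):
        gps = pd.DataFrame(
            {
                "timestamp": pd.to_datetime(["2019-08-01 10:00", "2019-08-01 11:00"]),
                "x_m": [0.0, 300.0],
                "y_m": [0.0, 400.0],
            }
        )
        assert act.daily_distance(gps)["daily_distance_m"].iloc[0] == pytest.approx(500.0)

    def test_matches_segment_sum_oracle_on_random_track(self):
        rng = np.random.default_rng(3)
        ts = pd.date_range("2019-08-01", periods=25, freq="h")
        xy = rng.normal(0, 300, size=(25, 2))
        gps = pd.DataFrame({"timestamp": ts, "x_m": xy[:, 0], "y_m": xy[:, 1]})
        out = act.daily_distance(gps).set_index("date")
        dates = ts.date
        expected = {}
        for d in set(dates):
            # a day with fewer than two fixes has no defined distance
            expected[d] = 0.0 if (dates == d).sum() >= 2 else np.nan
        for i in range(24):
            if dates[i] == dates[i + 1]:
                expected[dates[i]] += float(np.hypot(*(xy[i + 1] - xy[i])))
        for d, v in expected.items():
            if np.isnan(v):
                assert np.isnan(out.loc[d, "daily_distance_m"])
            else:
                assert out.loc[d, "daily_distance_m"] == pytest.approx(v)

    def test_single_fix_day_is_undefined(self):
        gps = pd.DataFrame(
            {"timestamp": [pd.Timestamp("2019-08-01 12:00")], "x_m": [5.0], "y_m": [0.0]}
        )
        assert np.isnan(act.daily_distance(gps)["daily_distance_m"].iloc[0])

    def test_great_circle_distance_for_geographic_tracks(self):
        gps = pd.DataFrame(
            {
                "timestamp": pd.to_datetime(["2019-08-01 10:00", "2019-08-01 11:00"]),
                "lat": [0.0, 0.0],
                "lon": [0.0, 1.0],
            }
        )
        d = act.daily_distance(gps)["daily_distance_m"].iloc[0]
        assert d == pytest.approx(111195, rel=1e-3)  # one degree at the equator


class TestSubsample:
    def test_crowded_hour_thinned_to_ten(self):
        df = label_frame(["resting"] * 1200, start="2019-08-05 10:00:00")
        out = act.subsample_hourly(df, n_per_hour=10, seed=0)
        assert len(out) == 10

    def test_sparse_hour_fully_retained(self):
        df = label_frame(["resting"] * 4, start="2019-08-05 10:00:00")
        assert len(act.subsample_hourly(df, n_per_hour=10, seed=0)) == 4

    def test_seed_controls_subset_but_not_counts(self):
        df = label_frame(["resting"] * 2400, start="2019-08-05 10:00:00")
        a = act.subsample_hourly(df, seed=1)
        b = act.subsample_hourly(df, seed=1)
        c = act.subsample_hourly(df, seed=2)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == len(c) == 20  # two hours touched
        assert not a["window_start"].equals(c["window_start"])


class TestExportModelTable:
    def test_window_row_schema(self):
        df = label_frame(["feeding"], start="2019-08-22 13:30:00")
        table, _ = act.export_model_table(df, pd.DataFrame())
        row = table.iloc[0]
        assert row["time_of_day_s"] == 48600
        assert row["is_feedwalking"] == 1
        assert row["is_resting"] == 0
        assert row["period"] == "hunting"
        assert row["year"] == 2019

    def test_row_count_equals_subsample_size(self):
        df = label_frame(["resting"] * 50, start="2019-08-05 10:00:00")
        sub = act.subsample_hourly(df, n_per_hour=10, seed=0)
        table, _ = act.export_model_table(sub, pd.DataFrame())
        assert len(table) == len(sub)


class TestDielProfile:
    def test_all_feedwalking_gives_probability_one_everywhere_observed(self):
        df = label_frame(["feeding"] * 1200, start="2019-08-05 00:00:00")
        out = act.diel_profile(df, n_boot=20, seed=0)
        observed = out[out["n_windows"] > 0]
        assert (observed["prop_feedwalking"] == 1.0).all()
        assert (observed["ci_hi"] - observed["ci_lo"] == 0.0).all()

    def test_single_bootstrap_collapses_to_point_estimate(self):
        rng = np.random.default_rng(4)
        df = label_frame(rng.choice(["feeding", "resting"], 480), start="2019-08-05 06:00:00")
        out = act.diel_profile(df, n_boot=1, seed=0)
        observed = out[out["n_windows"] > 0]
        assert np.allclose(observed["ci_lo"], observed["ci_hi"])

    def test_bimodal_simulation_recovered_in_profile(self):
        frames = []
        for day in range(1, 13):
            sch = syn.simulate_schedule(duration=86400.0, seed=400 + day)
            frames.append(
                syn.schedule_to_window_labels(sch, start_time=f"2019-08-{day:02d} 00:00:00")
            )
        labels = pd.concat(frames, ignore_index=True)
        out = act.diel_profile(labels, n_boot=10, seed=0)
        prop = out["prop_feedwalking"].to_numpy()
        morning = int(np.argmax(prop[:12]))
        evening = 12 + int(np.argmax(prop[12:]))
        assert morning in {3, 4, 5}
        assert evening in {19, 20, 21}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            act.diel_profile(label_frame([]))


def test_hunting_period_concentrates_running_in_legal_hours():
    """End-to-end direction recovery: a population whose running is pushed
    into legal hours during the hunting period shows a higher mean legal-hour
    proportion in hunting than pre-hunting records."""
    labels, demo = syn.simulate_hunting_response_population(
        n_bears=2, days_per_period=3, seed=123
    )
    bouts = act.detect_bouts(labels, "running")
    rec = act.daily_metrics(bouts, labels, demographics=demo)
    by_period = rec.groupby("period")["prop_legal"].mean()
    assert by_period["hunting"] > by_period["pre_hunting"]
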