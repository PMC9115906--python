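"""Observation cleaning, unit conversion, feed rules and daily aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thermoloop import preprocess as prep
from thermoloop.exceptions import ValidationError


def _obs_frame(rows):
    df = pd.DataFrame(rows, columns=["animal_id", "timestamp", "measure", "value"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["treatment"] = "TC"
    df["cohort"] = 1
    df["pair_id"] = "P01"
    return df[list(prep.OBS_COLUMNS)]


class TestRespirationRate:
    @pytest.mark.parametrize(
        "seconds,expected",
        [(6.0, 100.0), (60.0, 10.0), (5.2, 600.0 / 5.2)],
    )
    def test_conversion(self, seconds, expected):
        assert prep.rr_from_breath_timing(seconds) == pytest.approx(expected)

    @pytest.mark.parametrize("seconds", [0.0, -3.0, float("nan")])
    def test_rejects_nonpositive_duration(self, seconds):
        with pytest.raises(ValidationError):
            prep.rr_from_breath_timing(seconds)


class TestSanitizeRT:
    def test_floor_rule(self):
        obs = _obs_frame(
            [
                ("A", "2014-07-27T06:00", "RT", 39.5),
                ("A", "2014-07-27T06:10", "RT", 34.9),
                ("A", "2014-07-27T06:20", "RT", 40.1),
            ]
        )
        kept, log = prep.sanitize_rt(obs)
        assert list(kept["value"]) == [39.5, 40.1]
        assert len(log) == 1 and "35.0" in log[0]["reason"]

    def test_empty_and_noop(self):
        empty = _obs_frame([]).astype({"value": float})
        kept, log = prep.sanitize_rt(empty)
        assert kept.empty and log == []
        clean = _obs_frame([("A", "2014-07-27T06:00", "RT", 39.0)])
        kept, log = prep.sanitize_rt(clean)
        assert len(kept) == 1 and log == []

    def test_wc_event_masking_optional(self):
        rows = [
            ("A", "2014-07-27T06:00", "WC_meter", 100.0),
            ("A", "2014-07-27T08:00", "WC_meter", 110.0),  # 10 L event at 0800
            ("A", "2014-07-27T08:30", "RT", 38.2),  # within 60 min of event
            ("A", "2014-07-27T10:00", "RT", 39.4),  # outside window
        ]
        obs = _obs_frame(rows)
        kept_default, _ = prep.sanitize_rt(obs)
        assert (kept_default["measure"] == "RT").sum() == 2  # masking off by default
        kept, log = prep.sanitize_rt(obs, wc_mask=True)
        assert (kept["measure"] == "RT").sum() == 1
        assert "drinking" in log[0]["reason"]


class TestDedupe:
    def _records(self, rows):
        df = pd.DataFrame(rows, columns=["animal_id", "timestamp", "value", "transmission"])
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        return df

    def test_overlapping_retransmission(self):
        # two transmissions sharing 11 identical points: 24 raw -> 12 unique
        t0 = pd.Timestamp("2014-07-27T00:00")
        first = [("A", t0 + pd.Timedelta(minutes=10 * k), 39.0 + 0.01 * k, 1) for k in range(12)]
        second = [("A", t0 + pd.Timedelta(minutes=10 * k), 39.0 + 0.01 * k, 2) for k in range(1, 13)]
        out, conflicts = prep.dedupe_bolus_transmissions(self._records(first + second))
        assert len(out) == 13  # 12 from each with 11 shared
        assert conflicts == []

    def test_no_overlap_preserves_count(self):
        t0 = pd.Timestamp("2014-07-27T00:00")
        rows = [("A", t0 + pd.Timedelta(minutes=10 * k), 39.0, 1) for k in range(5)]
        out, conflicts = prep.dedupe_bolus_transmissions(self._records(rows))
        assert len(out) == 5 and conflicts == []

    def test_conflict_latest_transmission_wins(self):
        t0 = pd.Timestamp("2014-07-27T00:00")
        rows = [("A", t0, 39.0, 1), ("A", t0, 39.6, 2)]
        out, conflicts = prep.dedupe_bolus_transmissions(self._records(rows))
        assert len(out) == 1
        assert out["value"].iloc[0] == 39.6
        assert len(conflicts) == 1 and conflicts[0]["resolution"] == "latest transmission wins"

    def test_unique_per_measure_stream(self):
        # same timestamp, different measures must both survive
        obs = _obs_frame(
            [
                ("A", "2014-07-27T06:00", "RT", 39.5),
                ("A", "2014-07-27T06:00", "RR", 88.0),
            ]
        )
        out, _ = prep.dedupe_bolus_transmissions(obs, transmission_col=None)
        assert len(out) == 2


class TestFeedRules:
    @pytest.mark.parametrize(
        "intake,expected", [(5.0, 6.0), (0.0, 0.0), (10.85, 13.02)]
    )
    def test_pair_offer(self, intake, expected):
        assert prep.pair_offer(intake) == pytest.approx(expected)

    def test_pair_offer_rejects_negative(self):
        with pytest.raises(ValidationError):
            prep.pair_offer(-1.0)

    @given(a=st.floats(0, 20), b=st.floats(0, 20))
    def test_pair_offer_order_preserving(self, a, b):
        if a <= b:
            assert prep.pair_offer(a) <= prep.pair_offer(b)

    def test_step_down_converges_over_two_days(self):
        day1 = prep.step_down_offer(12.0, 6.0, 3.0)
        day2 = prep.step_down_offer(day1, 6.0, 3.0)
        assert (day1, day2) == (9.0, 6.0)

    @pytest.mark.parametrize(
        "prev,target,drop,expected",
        [(6.0, 6.0, 3.0, 6.0), (4.0, 6.0, 3.0, 6.0)],
    )
    def test_step_down_edge_cases(self, prev, target, drop, expected):
        assert prep.step_down_offer(prev, target, drop) == expected


class TestWaterConsumption:
    def _meter(self, rows):
        df = pd.DataFrame(rows, columns=["animal_id", "timestamp", "value"])
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        return df

    def test_daily_difference(self):
        rows = [("A", "2014-07-27T18:00", 95.0)] + [
            ("A", f"2014-07-28T{h:02d}:00", v)
            for h, v in [(6, 100.0), (12, 110.0), (18, 130.0)]
        ]
        out = prep.compute_wc(self._meter(rows))
        assert out.loc[out["date"].astype(str) == "2014-07-28", "wc_l"].iloc[0] == 35.0

    def test_constant_meter_is_zero(self):
        rows = [("A", f"2014-07-27T{h:02d}:00", 50.0) for h in (6, 12, 18)]
        out = prep.compute_wc(self._meter(rows))
        assert (out["wc_l"] == 0).all()

    def test_telescoping_conservation(self, rng):
        increments = rng.uniform(0, 5, size=30)
        readings = 100.0 + np.cumsum(increments)
        times = pd.date_range("2014-07-27T06:00", periods=30, freq="5h")
        out = prep.compute_wc(self._meter([("A", t, v) for t, v in zip(times, readings)]))
        assert out["wc_l"].sum() == pytest.approx(readings[-1] - readings[0])

    def test_decreasing_meter_rejected(self):
        rows = [("A", "2014-07-27T06:00", 100.0), ("A", "2014-07-27T08:00", 99.0)]
        with pytest.raises(ValidationError, match="A"):
            prep.compute_wc(self._meter(rows))


class TestDMI:
    def test_formula_with_chaff(self):
        feed = pd.DataFrame(
            {
                "animal_id": ["A"],
                "day": [3],
                "offered_asfed_kg": [12.0],
                "refusals_asfed_kg": [2.0],
                "dm_fraction": [0.904],
            }
        )
        out = prep.compute_dmi(feed)
        assert out["dmi_kg"].iloc[0] == pytest.approx(10.0 * 0.904 + 1.08)
        prorated = prep.compute_dmi(feed, chaff_policy="prorate_refusals")
        assert prorated["dmi_kg"].iloc[0] == pytest.approx(10.0 * 0.904 + 1.08 * (10.0 / 12.0))

    def test_refusals_beyond_offer_rejected(self):
        feed = pd.DataFrame(
            {
                "animal_id": ["A"],
                "day": [1],
                "offered_asfed_kg": [5.0],
                "refusals_asfed_kg": [6.0],
                "dm_fraction": [0.9],
            }
        )
        with pytest.raises(ValidationError):
            prep.compute_dmi(feed)


class TestPeriods:
    @pytest.mark.parametrize(
        "day,period,transition",
        [
            (1, "PreChallenge", False),
            (4, "PreChallenge", True),
            (5, "Challenge", False),
            (11, "Challenge", False),
            (12, "Recovery", True),
            (18, "Recovery", False),
        ],
    )
    def test_assignment(self, day, period, transition):
        assert prep.assign_period(day) == (period, transition)


class TestAggregate:
    def _small_obs(self):
        return _obs_frame(
            [
                ("A", "2014-07-27T06:00", "RT", 39.0),
                ("A", "2014-07-27T08:00", "RT", 40.0),
                ("A", "2014-07-27T06:00", "RR", 80.0),
                ("A", "2014-07-28T06:00", "RT", 39.4),
            ]
        )

    def test_exact_means_and_counts(self):
        daily = prep.aggregate(self._small_obs())
        d1 = daily.loc[daily["day"] == 1].iloc[0]
        assert d1["mean_rt"] == pytest.approx(39.5)
        assert d1["n_rt"] == 2 and d1["n_rr"] == 1
        d2 = daily.loc[daily["day"] == 2].iloc[0]
        assert d2["mean_rt"] == pytest.approx(39.4)

    def test_missing_measure_is_nan_not_zero(self):
        daily = prep.aggregate(self._small_obs())
        d2 = daily.loc[daily["day"] == 2].iloc[0]
        assert np.isnan(d2["mean_rr"]) and d2["n_rr"] == 0
        assert np.isnan(d2["mean_ps"])

    def test_permutation_invariance(self, rng):
        obs = self._small_obs()
        shuffled = obs.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a = prep.aggregate(obs)
        b = prep.aggregate(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_single_record_mean_is_itself(self):
        obs = _obs_frame([("A", "2014-07-27T06:00", "PS", 1.5)])
        daily = prep.aggregate(obs)
        assert daily["mean_ps"].iloc[0] == 1.5

    def test_empty_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            prep.aggregate(_obs_frame([]).astype({"value": float}))

    def test_recovers_generator_truth(self, small_cohort, small_daily_via_records):
        """Record-level aggregation reproduces the generator's daily summaries."""
        fast = small_cohort.daily.sort_values(["animal_id", "day"]).reset_index(drop=True)
        slow = small_daily_via_records.sort_values(["animal_id", "day"]).reset_index(drop=True)
        for col in ["mean_rt", "mean_rr", "mean_ps", "mean_st_head", "wc_l", "dmi_kg", "lw_kg"]:
            np.testing.assert_allclose(
                fast[col].to_numpy(), slow[col].to_numpy(), atol=1e-9, err_msg=col
            )

    def test_hourly_variant_keys(self, small_cohort):
        obs = small_cohort.observations
        sub = obs.loc[obs["animal_id"] == obs["animal_id"].iloc[0]]
        hourly = prep.aggregate_hourly(sub)
        assert {"animal_id", "day", "hour", "mean_rt"} <= set(hourly.columns)
        # bolus transmits 6 times per hour
        assert (hourly["n_rt"] == 6).all()
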