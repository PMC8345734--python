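import math
from datetime import datetime, timedelta

import numpy as np
import pytest

from radonrisk.dose_model import ValidationError, default_config
from radonrisk.exposure_timeseries import (
    NoDataError,
    NoOccupancyError,
    OccupancySchedule,
    RadonReading,
    RadonSeries,
    WindowSpec,
    annualize,
    assess,
    occupancy_mask,
    read_series,
    standard_windows,
    summary_stats,
    window_amrc,
    window_ied,
)

from conftest import brute_force_masked_mean, make_series, office_schedule


class TestReadSeries:
    def test_well_formed(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text(
            "timestamp,concentration\n"
            "2021-01-04T00:00:00,100\n"
            "2021-01-04T01:00:00,200\n"
            "2021-01-04T02:00:00,300\n"
        )
        s = read_series(p)
        assert len(s) == 3
        assert s.readings[1].concentration == 200

    def test_sort_invariance(self, tmp_path):
        rows = [
            "2021-01-04T02:00:00,300",
            "2021-01-04T00:00:00,100",
            "2021-01-04T01:00:00,200",
        ]
        a = tmp_path / "shuffled.csv"
        a.write_text("timestamp,concentration\n" + "\n".join(rows) + "\n")
        b = tmp_path / "sorted.csv"
        b.write_text("timestamp,concentration\n" + "\n".join(sorted(rows)) + "\n")
        assert read_series(a).readings == read_series(b).readings

    def test_negative_concentration_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "timestamp,concentration\n2021-01-04T00:00:00,100\n2021-01-04T01:00:00,-5\n"
        )
        with pytest.raises(ValidationError, match="row 3"):
            read_series(p)

    def test_unparseable_timestamp_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("timestamp,concentration\nnot-a-time,100\n")
        with pytest.raises(ValidationError, match="row 2"):
            read_series(p)

    def test_duplicate_timestamps_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(
            "timestamp,concentration\n2021-01-04T00:00:00,1\n2021-01-04T00:00:00,2\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_series(p)

    def test_csv_round_trip(self, tmp_path, monday):
        s = make_series([100, 200, 300], monday)
        p = tmp_path / "rt.csv"
        s.to_csv(p)
        assert read_series(p, "test").readings == s.readings


class TestOccupancyMask:
    def test_single_workday(self, monday):
        sched = office_schedule()
        mask = occupancy_mask(sched, monday, monday + timedelta(days=1))
        assert mask == [
            (monday + timedelta(hours=9), monday + timedelta(hours=17))
        ]

    def test_empty_schedule(self, monday):
        sched = OccupancySchedule.from_dict({"weekly": []})
        assert occupancy_mask(sched, monday, monday + timedelta(days=7)) == []

    def test_midnight_crossing_matches_brute_force(self, monday):
        # 22:00–02:00: split across the day boundary, 4 h total
        sched = OccupancySchedule.from_dict(
            {"weekly": [{"day": "Mon", "start": "22:00", "end": "02:00"}]}
        )
        t0, t1 = monday, monday + timedelta(days=2)
        mask = occupancy_mask(sched, t0, t1)
        total_h = sum((e - s).total_seconds() for s, e in mask) / 3600
        # brute-force minute membership
        brute = 0
        t = t0
        while t < t1:
            if (t.weekday() == 0 and t.hour >= 22) or (
                t.weekday() == 1 and t.hour < 2
            ):
                brute += 1
            t += timedelta(minutes=1)
        assert total_h == pytest.approx(brute / 60) == pytest.approx(4.0)
        # contiguous across midnight: returned as one merged block
        assert mask == [
            (monday + timedelta(hours=22), monday + timedelta(hours=26))
        ]

    def test_mask_disjoint_sorted(self, monday):
        sched = office_schedule()
        mask = occupancy_mask(sched, monday, monday + timedelta(days=14))
        for (s1, e1), (s2, e2) in zip(mask, mask[1:]):
            assert e1 <= s2
            assert s1 < e1

    def test_holiday_exception_removes_day(self, monday):
        sched = OccupancySchedule.from_dict(
            {
                "weekly": [{"day": "Mon", "start": "09:00", "end": "17:00"}],
                "exceptions": [{"date": "2021-01-04", "occupied": False}],
            }
        )
        assert occupancy_mask(sched, monday, monday + timedelta(days=1)) == []
        # the following Monday is unaffected
        nxt = monday + timedelta(days=7)
        assert len(occupancy_mask(sched, nxt, nxt + timedelta(days=1))) == 1

    def test_special_event_adds_occupancy(self, monday):
        saturday = monday + timedelta(days=5)
        sched = OccupancySchedule.from_dict(
            {
                "weekly": [],
                "exceptions": [
                    {
                        "date": saturday.date().isoformat(),
                        "occupied": True,
                        "start": "10:00",
                        "end": "14:00",
                    }
                ],
            }
        )
        mask = occupancy_mask(sched, monday, monday + timedelta(days=7))
        assert mask == [
            (saturday + timedelta(hours=10), saturday + timedelta(hours=14))
        ]

    def test_t0_after_t1_rejected(self, monday):
        with pytest.raises(ValidationError):
            occupancy_mask(office_schedule(), monday, monday)

    def test_json_round_trip(self, tmp_path):
        sched = office_schedule()
        p = tmp_path / "s.json"
        sched.to_json(p)
        assert OccupancySchedule.from_json(p) == sched


class TestWindowAmrc:
    def test_constant_series_any_mask(self, monday):
        series = make_series([300.0] * 48, monday)
        w = WindowSpec("VST", timedelta(hours=24), True)
        amrc, cov = window_amrc(series, w, office_schedule(), monday + timedelta(hours=36))
        assert amrc == pytest.approx(300.0)

    def test_two_half_windows_unmasked(self, monday):
        series = make_series([500.0] * 12 + [1000.0] * 12, monday)
        w = WindowSpec("RT", timedelta(hours=24), False)
        amrc, cov = window_amrc(series, w, None, monday + timedelta(hours=24))
        assert amrc == pytest.approx(750.0)
        assert cov == pytest.approx(1.0)

    def test_masked_mean_hand_example(self, monday):
        # hourly readings 100,200,300,400 starting at 00:00; occupied 02:00-04:00
        series = make_series([100.0, 200.0, 300.0, 400.0], monday)
        sched = OccupancySchedule.from_dict(
            {
                "weekly": [
                    {"day": d, "start": "02:00", "end": "04:00"}
                    for d in ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
                ]
            }
        )
        w = WindowSpec("VST", timedelta(hours=24), True)
        amrc, cov = window_amrc(series, w, sched, monday + timedelta(hours=4))
        assert amrc == pytest.approx((300 + 400) / 2)
        assert cov == pytest.approx(1.0)

    def test_no_occupancy_distinct_from_no_data(self, monday):
        series = make_series([100.0] * 24, monday)
        w = WindowSpec("VST", timedelta(hours=24), True)
        empty = OccupancySchedule.from_dict({"weekly": []})
        with pytest.raises(NoOccupancyError):
            window_amrc(series, w, empty, monday + timedelta(hours=24))
        # occupancy exists but the series is elsewhere entirely
        far = monday + timedelta(days=400)
        with pytest.raises(NoDataError):
            window_amrc(series, w, office_schedule(), far)

    def test_brute_force_oracle_agreement(self, monday):
        # irregular values, office mask, partial data coverage
        rng = np.random.default_rng(42)
        values = rng.lognormal(math.log(200), 0.5, size=72).tolist()
        series = make_series(values, monday)
        sched = office_schedule()
        w = WindowSpec("ST", timedelta(days=7), True)
        asof = monday + timedelta(days=4)
        amrc, cov = window_amrc(series, w, sched, asof)
        mask = occupancy_mask(sched, asof - w.span, asof)
        oracle_mean, oracle_cov = brute_force_masked_mean(
            series, mask, asof - w.span, asof
        )
        assert amrc == pytest.approx(oracle_mean, rel=0.005)
        assert cov == pytest.approx(oracle_cov, rel=0.005)

    def test_causality(self, monday):
        # readings at/after asof never affect the result
        base = make_series([100.0] * 24, monday)
        asof = monday + timedelta(hours=24)
        extended = RadonSeries(
            base.readings + (RadonReading(asof, 9999.0), RadonReading(asof + timedelta(hours=1), 9999.0)),
            "test",
        )
        w = WindowSpec("RT", timedelta(hours=24), False)
        a1, _ = window_amrc(base, w, None, asof)
        a2, _ = window_amrc(extended, w, None, asof)
        assert a1 == a2 == pytest.approx(100.0)

    def test_translation_invariance_whole_weeks(self, monday):
        rng = np.random.default_rng(7)
        values = rng.lognormal(5, 0.4, size=100).tolist()
        series = make_series(values, monday)
        sched = office_schedule()
        w = WindowSpec("VST", timedelta(hours=24), True)
        asof = monday + timedelta(days=3)
        ref = window_amrc(series, w, sched, asof)
        for weeks in (1, 10):
            shift = timedelta(days=7 * weeks)
            got = window_amrc(series.shift(shift), w, sched, asof + shift)
            assert got[0] == pytest.approx(ref[0])
            assert got[1] == pytest.approx(ref[1])

    def test_coverage_one_when_fully_observed(self, monday):
        series = make_series([150.0] * (24 * 8), monday)
        w = WindowSpec("ST", timedelta(days=7), True)
        _, cov = window_amrc(series, w, office_schedule(), monday + timedelta(days=8))
        assert cov == pytest.approx(1.0)

    def test_missing_flag_reduces_coverage(self, monday):
        flags = ["ok"] * 24
        flags[10] = "missing"
        series = make_series([100.0] * 24, monday, flags=flags)
        w = WindowSpec("RT", timedelta(hours=24), False)
        _, cov = window_amrc(series, w, None, monday + timedelta(hours=24))
        assert cov == pytest.approx(23 / 24)


class TestSummaryStats:
    def test_constant_series(self, monday):
        series = make_series([250.0] * 24, monday)
        w = WindowSpec("VST", timedelta(hours=24), False)
        stats = summary_stats(series, w, None, monday + timedelta(hours=24))
        assert stats["AM"] == pytest.approx(250)
        assert stats["GM"] == pytest.approx(250)
        assert stats["SD"] == pytest.approx(0)
        assert stats["GSD"] == pytest.approx(1)

    def test_gm_hand_example(self, monday):
        series = make_series([100.0, 400.0], monday)
        w = WindowSpec("VST", timedelta(hours=24), False)
        stats = summary_stats(series, w, None, monday + timedelta(hours=2))
        assert stats["GM"] == pytest.approx(200.0)  # exp(mean(ln 100, ln 400))

    def test_gm_le_am(self, monday):
        rng = np.random.default_rng(3)
        series = make_series(rng.lognormal(4, 1, 50).tolist(), monday)
        w = WindowSpec("ST", timedelta(days=7), False)
        stats = summary_stats(series, w, None, monday + timedelta(days=3))
        assert stats["GM"] <= stats["AM"]

    def test_zero_concentration_undefines_gm(self, monday):
        series = make_series([0.0, 100.0, 200.0], monday)
        w = WindowSpec("VST", timedelta(hours=24), False)
        stats = summary_stats(series, w, None, monday + timedelta(hours=3))
        assert math.isnan(stats["GM"]) and math.isnan(stats["GSD"])
        assert stats["AM"] == pytest.approx(100.0)


class TestDoseSteps:
    def test_window_ied_hand_value(self, config):
        # 300 Bq·m⁻³ × 40 h × 0.4 × 9e-9 Sv = 4.32e-5 Sv = 4.32e-2 mSv
        assert window_ied(300, 40, config) == pytest.approx(4.32e-2)

    def test_zero_hours(self, config):
        assert window_ied(300, 0, config) == 0.0

    def test_linearity_in_hours(self, config):
        assert window_ied(300, 80, config) == pytest.approx(
            2 * window_ied(300, 40, config)
        )

    def test_annualize_worked_example(self, config):
        iaed = annualize(300, 8, config)
        assert iaed == pytest.approx(3.1536)

    def test_annualize_full_day(self, config):
        from radonrisk.dose_model import iaed_from_aao

        assert annualize(77, 24, config) == pytest.approx(
            iaed_from_aao(77, 8760, config)
        )


class TestAssess:
    def test_constant_series_all_windows_yellow(self, monday, config):
        series = make_series([300.0] * (24 * 95), monday)
        sched = OccupancySchedule.from_dict(
            {
                "weekly": [
                    {"day": d, "start": "09:00", "end": "17:00"}
                    for d in ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
                ]
            }
        )
        res = assess(series, sched, config, monday + timedelta(days=95))
        for name in ("VST", "ST", "LT"):
            assert res[name].irrei.level == 2
            assert res[name].dao == pytest.approx(8.0)
            assert res[name].iaed_mSv == pytest.approx(3.1536)
        assert res["RT"].irrei is None
        assert res["RT"].amrc == pytest.approx(300.0)

    def test_low_concentration_always_green(self, monday, config):
        series = make_series([10.0] * (24 * 95), monday)
        sched = OccupancySchedule.from_dict(
            {
                "weekly": [
                    {"day": d, "start": "00:00", "end": "24:00"}
                    for d in ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
                ]
            }
        )
        res = assess(series, sched, config, monday + timedelta(days=95))
        for name in ("VST", "ST", "LT"):
            assert res[name].irrei.level == 1

    def test_empty_schedule_reports_no_occupancy(self, monday, config):
        series = make_series([100.0] * 48, monday)
        empty = OccupancySchedule.from_dict({"weekly": []})
        res = assess(series, empty, config, monday + timedelta(hours=48))
        assert res["RT"].status == "ok"
        assert res["RT"].amrc == pytest.approx(100.0)
        for name in ("VST", "ST", "LT"):
            assert res[name].status == "no_occupancy"

    def test_stale_series_lt_unavailable(self, monday, config):
        series = make_series([100.0] * 24, monday)
        sched = office_schedule()
        asof = monday + timedelta(days=200)
        res = assess(series, sched, config, asof)
        assert res["LT"].status == "unavailable"

    def test_low_coverage_flagged(self, monday, config):
        # data only covers the last day of a 7-day window -> ST coverage ~1/7
        series = make_series([100.0] * 24, monday + timedelta(days=6))
        sched = OccupancySchedule.from_dict(
            {
                "weekly": [
                    {"day": d, "start": "00:00", "end": "24:00"}
                    for d in ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
                ]
            }
        )
        res = assess(series, sched, config, monday + timedelta(days=7))
        assert res["ST"].status == "ok"
        assert res["ST"].coverage_fraction == pytest.approx(1 / 7, rel=1e-6)
        assert res["ST"].low_confidence

    def test_empty_series_rejected(self, config):
        with pytest.raises(ValidationError):
            assess(RadonSeries((), "x"), office_schedule(), config, datetime(2021, 1, 4))


class TestSeriesValidation:
    def test_non_increasing_rejected(self, monday):
        with pytest.raises(ValidationError):
            RadonSeries(
                (RadonReading(monday, 1.0), RadonReading(monday, 2.0)), "x"
            )

    def test_negative_concentration_rejected(self, monday):
        with pytest.raises(ValidationError):
            RadonReading(monday, -1.0)

    def test_all_missing_rejected(self, monday):
        with pytest.raises(ValidationError):
            RadonSeries(
                (RadonReading(monday, float("nan"), "missing"),), "x"
            )

    def test_bad_flag_rejected(self, monday):
        with pytest.raises(ValidationError):
            RadonReading(monday, 1.0, "dubious")
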