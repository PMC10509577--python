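from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tidegam.errors import ArgumentError, CoverageError, EmptyInputError, FormatError
from tidegam.tide_clock import (
    TideEvent,
    TideTable,
    hours_to_nearest_low,
    read_tide_table,
    synth_tide_schedule,
)

T0 = datetime(2023, 3, 1)


class TestReadTideTable:
    def test_two_row_file(self, tmp_path):
        p = tmp_path / "tides.csv"
        p.write_text(
            "timestamp,kind\n2023-03-01T01:00,low\n2023-03-01T07:15,high\n"
        )
        table = read_tide_table(p)
        assert [e.kind for e in table.events] == ["low", "high"]
        assert table.events[0].timestamp == datetime(2023, 3, 1, 1, 0)

    def test_unknown_kind_names_row(self, tmp_path):
        p = tmp_path / "tides.csv"
        p.write_text("timestamp,kind\n2023-03-01T01:00,ebb\n")
        with pytest.raises(FormatError, match="row 0.*ebb"):
            read_tide_table(p)

    def test_rows_out_of_order_same_as_sorted(self, tmp_path):
        rows = [
            "2023-03-01T13:30,low", "2023-03-01T01:00,low",
            "2023-03-01T07:15,high",
        ]
        a = tmp_path / "a.csv"
        a.write_text("timestamp,kind\n" + "\n".join(rows) + "\n")
        b = tmp_path / "b.csv"
        b.write_text("timestamp,kind\n" + "\n".join(sorted(rows)) + "\n")
        ta, tb = read_tide_table(a), read_tide_table(b)
        assert [e.timestamp for e in ta.events] == [e.timestamp for e in tb.events]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "tides.csv"
        p.write_text("timestamp,kind\n")
        with pytest.raises(EmptyInputError):
            read_tide_table(p)

    def test_extra_columns_tolerated(self, tmp_path):
        p = tmp_path / "tides.csv"
        p.write_text(
            "timestamp,kind,height_m,source\n"
            "2023-03-01T01:00,low,0.4,chart\n2023-03-01T13:30,low,0.6,chart\n"
        )
        table = read_tide_table(p)
        assert table.events[0].height_m == pytest.approx(0.4)


class TestSynthSchedule:
    def test_low_positions_one_day(self):
        t = synth_tide_schedule(T0, 1)
        lows = t.low_times.astype("datetime64[s]").tolist()
        assert lows == [T0, T0 + timedelta(hours=12.5)]

    def test_low_gaps_all_equal_12_5(self):
        t = synth_tide_schedule(T0, 10)
        gaps = np.diff(t.low_times).astype("timedelta64[s]").astype(float) / 3600
        assert np.allclose(gaps, 12.5)

    def test_first_low_advances_one_hour_per_day(self):
        # 2 x 12.5 h - 24 h = 1 h daily shift of the tidal clock
        t = synth_tide_schedule(T0, 6)
        lows = t.low_times.astype("datetime64[s]").tolist()
        first_by_day = {}
        for low in lows:
            first_by_day.setdefault(low.date(), low)
        hours = [
            lo.hour + lo.minute / 60 for lo in sorted(first_by_day.values())
        ]
        assert np.allclose(np.diff(hours), 1.0)

    def test_highs_at_midpoints(self):
        t = synth_tide_schedule(T0, 2)
        lows = [e.timestamp for e in t.events if e.kind == "low"]
        highs = [e.timestamp for e in t.events if e.kind == "high"]
        for h, (l0, l1) in zip(highs, zip(lows, lows[1:])):
            assert h == l0 + (l1 - l0) / 2

    def test_invalid_args(self):
        with pytest.raises(ArgumentError):
            synth_tide_schedule(T0, 0)
        with pytest.raises(ArgumentError):
            synth_tide_schedule(T0, 3, low_interval_h=10.0)


class TestHoursToNearestLow:
    def test_exactly_at_low(self, tiny_tides):
        assert hours_to_nearest_low(T0, tiny_tides) == 0.0

    def test_nearest_event_arithmetic(self):
        table = TideTable(
            [TideEvent(datetime(2023, 3, 1, 0, 0), "low"),
             TideEvent(datetime(2023, 3, 1, 12, 30), "low")]
        )
        assert hours_to_nearest_low(datetime(2023, 3, 1, 3, 0), table) == 3.0
        assert hours_to_nearest_low(datetime(2023, 3, 1, 10, 0), table) == -2.5

    def test_midpoint_tie_assigned_to_earlier_low(self, tiny_tides):
        ts = T0 + timedelta(hours=6.25)
        assert hours_to_nearest_low(ts, tiny_tides) == 6.25

    def test_outside_padded_span(self, tiny_tides):
        with pytest.raises(CoverageError):
            hours_to_nearest_low(T0 - timedelta(days=2), tiny_tides)

    @settings(deadline=None, max_examples=100)
    @given(st.floats(min_value=-10.0, max_value=46.0))
    def test_brute_force_oracle(self, offset_h):
        table = synth_tide_schedule(T0, 2, low_interval_h=12.1,
                                    first_low_offset_h=1.7)
        ts = T0 + timedelta(hours=offset_h)
        got = hours_to_nearest_low(ts, table)
        lows = [e.timestamp for e in table.events if e.kind == "low"]
        diffs = [(ts - lo).total_seconds() / 3600 for lo in lows]
        best = min(np.abs(diffs))
        assert abs(got) == pytest.approx(best, abs=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(
        st.floats(min_value=0.0, max_value=30.0),
        st.integers(min_value=-1000, max_value=1000),
    )
    def test_translation_invariance(self, offset_h, shift_minutes):
        shift = timedelta(minutes=shift_minutes)
        base = synth_tide_schedule(T0, 2)
        shifted = TideTable(
            [TideEvent(e.timestamp + shift, e.kind) for e in base.events]
        )
        ts = T0 + timedelta(hours=offset_h)
        assert hours_to_nearest_low(ts, base) == pytest.approx(
            hours_to_nearest_low(ts + shift, shifted), abs=1e-9
        )

    def test_piecewise_linear_unit_slope(self):
        table = synth_tide_schedule(T0, 4)
        ts = [T0 + timedelta(hours=h) for h in np.arange(0.5, 40, 0.25)]
        lags = hours_to_nearest_low(ts, table)
        # covers (-interval/2, +interval/2]
        assert lags.min() >= -6.25 and lags.max() <= 6.25
        d = np.diff(lags)
        # unit slope except at the wrap discontinuities
        assert np.all((np.abs(d - 0.25) < 1e-9) | (d < -12))

    def test_high_tides_do_not_enter(self):
        lows_only = TideTable(
            [TideEvent(datetime(2023, 3, 1, 0, 0), "low"),
             TideEvent(datetime(2023, 3, 1, 12, 30), "low")]
        )
        with_high = TideTable(
            [TideEvent(datetime(2023, 3, 1, 0, 0), "low"),
             TideEvent(datetime(2023, 3, 1, 6, 15), "high"),
             TideEvent(datetime(2023, 3, 1, 12, 30), "low")]
        )
        ts = datetime(2023, 3, 1, 5, 0)
        assert hours_to_nearest_low(ts, lows_only) == hours_to_nearest_low(
            ts, with_high
        )


class TestTideTableInvariants:
    def test_gap_over_24h_is_error(self):
        with pytest.raises(FormatError, match="gap"):
            TideTable(
                [TideEvent(datetime(2023, 3, 1), "low"),
                 TideEvent(datetime(2023, 3, 3), "low")]
            )

    def test_gap_outside_band_warns(self):
        with pytest.warns(UserWarning, match="gap"):
            TideTable(
                [TideEvent(datetime(2023, 3, 1, 0, 0), "low"),
                 TideEvent(datetime(2023, 3, 1, 18, 0), "low")]
            )

    def test_non_increasing_rejected(self):
        with pytest.raises(FormatError, match="increasing"):
            TideTable(
                [TideEvent(datetime(2023, 3, 1, 1, 0), "low"),
                 TideEvent(datetime(2023, 3, 1, 1, 0), "high")]
            )
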