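"""CSV reading, validation contract, gap repair, and report round-trips."""

import json

import numpy as np
import pytest

from h2sindex import (
    GasTimeSeries,
    IrregularIntervalError,
    NegativeReadingError,
    ParseError,
    analyze_shift,
    fill_short_gaps,
    read_report,
    read_series,
    write_report,
    write_series,
)


def _write_csv(path, rows, header="timestamp,h2s_ppm", sep=","):
    lines = [header] + [sep.join(str(c) for c in row) for row in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


class TestReadSeries:
    def test_minimal_well_formed(self, tmp_path):
        p = tmp_path / "shift.csv"
        _write_csv(
            p,
            [
                ("2021-06-01T06:00:00", "0.0"),
                ("2021-06-01T06:00:10", "0.5"),
                ("2021-06-01T06:00:20", "0.0"),
            ],
        )
        s = read_series(p)
        assert len(s) == 3
        assert s.logging_interval == 10.0
        np.testing.assert_array_equal(s.readings, [0.0, 0.5, 0.0])

    def test_gap_beyond_tolerance_rejected_with_position(self, tmp_path):
        p = tmp_path / "gap.csv"
        times = ["06:00:00", "06:00:10", "06:00:20", "06:01:20", "06:01:30"]
        _write_csv(p, [(f"2021-06-01T{t}", "0.1") for t in times])
        with pytest.raises(IrregularIntervalError) as exc:
            read_series(p)
        assert exc.value.gaps == [(3, 60.0)]
        assert "row 3" in str(exc.value)

    def test_header_autodetection_and_interval_inference(self, tmp_path):
        p = tmp_path / "auto.csv"
        # 100 rows at 2-s spacing, reading column labelled like an instrument export
        start = np.datetime64("2021-06-01T06:00:00")
        rows = [
            (str(start + np.timedelta64(2 * i, "s")), f"{0.1 * (i % 4):.1f}")
            for i in range(100)
        ]
        _write_csv(p, rows, header="Date/Time,H2S (ppm)")
        s = read_series(p)
        assert len(s) == 100
        assert s.logging_interval == 2.0
        assert s.meta["reading_column"] == "H2S (ppm)"

    def test_semicolon_separator(self, tmp_path):
        p = tmp_path / "euro.csv"
        _write_csv(
            p,
            [("2021-06-01T06:00:00", "0.0"), ("2021-06-01T06:01:00", "1.2")],
            header="timestamp;h2s_ppm",
            sep=";",
        )
        s = read_series(p)
        assert s.readings[1] == 1.2

    def test_malformed_timestamp_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        _write_csv(
            p,
            [
                ("2021-06-01T06:00:00", "0.0"),
                ("not-a-time", "0.1"),
                ("2021-06-01T06:00:20", "0.0"),
            ],
        )
        with pytest.raises(ParseError, match="row 1"):
            read_series(p)

    def test_negative_reading_is_an_error_not_clipped(self, tmp_path):
        p = tmp_path / "neg.csv"
        _write_csv(
            p,
            [
                ("2021-06-01T06:00:00", "0.0"),
                ("2021-06-01T06:00:10", "-0.2"),
                ("2021-06-01T06:00:20", "0.0"),
            ],
        )
        with pytest.raises(NegativeReadingError):
            read_series(p)

    def test_explicit_column_map(self, tmp_path):
        p = tmp_path / "map.csv"
        _write_csv(
            p,
            [("2021-06-01T06:00:00", "0.0", "x"), ("2021-06-01T06:00:10", "0.7", "y")],
            header="when,level,note",
        )
        s = read_series(p, column_map={"timestamp": "when", "reading": "level"})
        assert s.readings[1] == 0.7


class TestRoundTrip:
    def test_write_then_read_identity(self, tmp_path, make_series):
        rng = np.random.default_rng(42)
        r = np.round(rng.lognormal(0.5, 1.0, size=50), 4)
        r[::3] = 0.0
        s = make_series(r, dt=10.0)
        p = tmp_path / "rt.csv"
        write_series(s, p)
        back = read_series(p)
        np.testing.assert_array_equal(back.readings, s.readings)
        np.testing.assert_array_equal(back.timestamps, s.timestamps)
        assert back.logging_interval == s.logging_interval


class TestFillShortGaps:
    def test_no_gaps_identity(self, make_series):
        s = make_series([0.0, 1.0, 0.0])
        out = fill_short_gaps(s, max_gap=30.0)
        np.testing.assert_array_equal(out.readings, s.readings)
        np.testing.assert_array_equal(out.timestamps, s.timestamps)

    def test_single_missing_sample_linear_interpolation(self, make_series):
        s = make_series([0.0, 1.0, 2.0, 3.0])
        # drop the sample between 1.0 and 3.0 -> 20-s hole
        ts = np.delete(s.timestamps, 2)
        rd = np.delete(s.readings, 2)
        gappy = GasTimeSeries(ts, rd, 10.0)
        out = fill_short_gaps(gappy, max_gap=30.0)
        assert len(out) == 4
        assert out.readings[2] == pytest.approx(2.0)
        assert out.meta["filled_gaps"]
        out.validate()

    def test_long_gap_left_untouched(self, make_series):
        base = make_series(np.concatenate([[1.0], np.full(10, 2.0), [3.0]]))
        ts = np.concatenate([base.timestamps[:1], base.timestamps[11:]])
        rd = np.concatenate([base.readings[:1], base.readings[11:]])
        gappy = GasTimeSeries(ts, rd, 10.0)
        out = fill_short_gaps(gappy, max_gap=30.0)
        assert len(out) == len(gappy)
        with pytest.raises(IrregularIntervalError):
            out.validate()


class TestReportIO:
    def test_json_round_trip_bit_exact(self, tmp_path, single_spike_series):
        rep = analyze_shift(single_spike_series)
        p = tmp_path / "report.json"
        write_report(rep, p, format="json")
        back = read_report(p)
        assert back.elements == rep.elements
        assert back.index == rep.index
        assert back.twa_8h == rep.twa_8h
        assert back.task_durations_min == rep.task_durations_min

    def test_zero_report_round_trip(self, tmp_path, make_series):
        rep = analyze_shift(make_series(np.zeros(100)))
        p = tmp_path / "zero.json"
        write_report(rep, p, format="json")
        back = read_report(p)
        assert back.index == 0.0
        assert back == rep

    def test_csv_rows_accumulate(self, tmp_path, make_series, single_spike_series):
        p = tmp_path / "batch.csv"
        for series in (make_series(np.zeros(100)), single_spike_series, single_spike_series):
            write_report(analyze_shift(series), p, format="csv-row")
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 4  # header + 3 rows
        assert lines[0].startswith("file,index,twa_8h")
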