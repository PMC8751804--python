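"""Shift-level gas concentration time series: container, CSV reading, validation.

The whole pipeline operates on one work shift's log from a direct-reading
sensor: a regular grid of timestamps with one concentration (ppm) per sample.
Everything downstream (moving averages, task segmentation, durations) assumes
that grid, so the contract is enforced here and nowhere else.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IrregularIntervalError, NegativeReadingError, ParseError

#: default tolerance on "regular" spacing, as a fraction of the median interval
DEFAULT_TOLERANCE = 0.05

#: decimals used when serialising readings to CSV
CSV_DECIMALS = 4

_TIMESTAMP_KEYWORDS = ("time", "date", "stamp")
_READING_KEYWORDS = ("ppm", "h2s", "conc")


@dataclass
class GasTimeSeries:
    """One shift's concentration log on a regular time grid.

    Attributes
    ----------
    timestamps
        Strictly increasing instants, ``datetime64[ns]``.
    readings
        Concentration in ppm at each instant, non-negative and finite.
    logging_interval
        Nominal seconds between consecutive samples.
    meta
        Free-form provenance: source path, instrument label, gap-fill flags.
    """

    timestamps: np.ndarray
    readings: np.ndarray
    logging_interval: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[ns]")
        self.readings = np.asarray(self.readings, dtype=float)

    def __len__(self) -> int:
        return len(self.readings)

    @property
    def duration_seconds(self) -> float:
        """Measurement duration: number of samples times the logging interval."""
        return len(self) * self.logging_interval

    def interval_seconds(self) -> np.ndarray:
        """Differences between consecutive timestamps, in seconds."""
        return np.diff(self.timestamps).astype("timedelta64[ns]").astype(float) / 1e9

    def validate(self, tolerance: float = DEFAULT_TOLERANCE) -> "GasTimeSeries":
        """Check the regular-grid contract; return self so calls can be chained.

        Raises
        ------
        ValueError
            Fewer than two samples, or non-finite readings.
        IrregularIntervalError
            Any consecutive gap deviating from ``logging_interval`` by more
            than ``tolerance`` (fraction of the interval).
        NegativeReadingError
            Any reading below zero.
        """
        if len(self) < 2:
            raise ValueError("a series needs at least 2 samples")
        if len(self.timestamps) != len(self.readings):
            raise ValueError("timestamps and readings differ in length")
        if not np.all(np.isfinite(self.readings)):
            bad = int(np.flatnonzero(~np.isfinite(self.readings))[0])
            raise ValueError(f"non-finite reading at row {bad}")
        if np.any(self.readings < 0):
            bad = int(np.flatnonzero(self.readings < 0)[0])
            raise NegativeReadingError(
                f"negative reading {self.readings[bad]:g} ppm at row {bad}; "
                "correct sensor drift before analysis"
            )
        diffs = self.interval_seconds()
        if np.any(diffs <= 0):
            bad = int(np.flatnonzero(diffs <= 0)[0])
            raise IrregularIntervalError(
                f"timestamps not strictly increasing at row {bad + 1}",
                gaps=[(bad + 1, float(diffs[bad]))],
            )
        if self.logging_interval <= 0:
            raise ValueError("logging_interval must be positive")
        lo = self.logging_interval * (1 - tolerance)
        hi = self.logging_interval * (1 + tolerance)
        off = np.flatnonzero((diffs < lo) | (diffs > hi))
        if off.size:
            gaps = [(int(i) + 1, float(diffs[i])) for i in off]
            shown = ", ".join(f"row {r}: {g:g} s" for r, g in gaps[:5])
            more = "" if len(gaps) <= 5 else f" (+{len(gaps) - 5} more)"
            raise IrregularIntervalError(
                f"irregular logging intervals (expected {self.logging_interval:g} s "
                f"±{tolerance:.0%}): {shown}{more}",
                gaps=gaps,
            )
        return self


def _sniff_separator(sample: str) -> str:
    # European instrument exports use ';' (and often ',' as decimal mark)
    header = sample.splitlines()[0] if sample else ""
    if header.count(";") > header.count(","):
        return ";"
    return ","


def _pick_columns(
    columns: Sequence[str], column_map: Mapping[str, str] | None
) -> tuple[str, str]:
    if column_map:
        ts = column_map.get("timestamp")
        rd = column_map.get("reading")
        if ts is None or rd is None:
            raise ValueError("column_map must provide 'timestamp' and 'reading'")
        for name in (ts, rd):
            if name not in columns:
                raise ParseError(f"column {name!r} not found (have {list(columns)})")
        return ts, rd
    lowered = {c: c.lower() for c in columns}
    ts = next(
        (c for c in columns if any(k in lowered[c] for k in _TIMESTAMP_KEYWORDS)),
        columns[0],
    )
    rd = next(
        (
            c
            for c in columns
            if c != ts and any(k in lowered[c] for k in _READING_KEYWORDS)
        ),
        None,
    )
    if rd is None:
        remaining = [c for c in columns if c != ts]
        if not remaining:
            raise ParseError("no concentration column found")
        rd = remaining[0]
    return ts, rd


def read_series(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
    timestamp_format: str | None = None,
    validate: bool = True,
) -> GasTimeSeries:
    """Read one shift's CSV log into a validated :class:`GasTimeSeries`.

    The file must have a header row with at least a timestamp column and a
    concentration column. Columns are chosen by ``column_map`` (keys
    ``timestamp`` and ``reading``) when given, otherwise by header keyword
    (a concentration header containing ``ppm``/``h2s``/``conc``), otherwise
    the second column. Separator is auto-detected among comma/semicolon.

    The logging interval is inferred as the median of consecutive timestamp
    differences. Set ``validate=False`` to defer the regular-grid check, e.g.
    before :func:`fill_short_gaps`.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8-sig")
    sep = _sniff_separator(text)
    try:
        frame = pd.read_csv(_io.StringIO(text), sep=sep)
    except Exception as exc:  # malformed CSV structure
        raise ParseError(f"{path.name}: {exc}") from exc
    if frame.shape[1] < 2:
        raise ParseError(f"{path.name}: need at least 2 columns, got {frame.shape[1]}")
    ts_col, rd_col = _pick_columns(list(frame.columns), column_map)

    ts = pd.to_datetime(
        frame[ts_col], format=timestamp_format or "ISO8601", errors="coerce"
    )
    if ts.isna().any():
        row = int(ts.isna().idxmax())
        raise ParseError(
            f"{path.name}: cannot parse timestamp {frame[ts_col].iloc[row]!r} "
            f"at data row {row}"
        )
    readings = pd.to_numeric(frame[rd_col], errors="coerce")
    if readings.isna().any():
        row = int(readings.isna().idxmax())
        raise ParseError(
            f"{path.name}: cannot parse reading {frame[rd_col].iloc[row]!r} "
            f"at data row {row}"
        )

    stamps = ts.to_numpy(dtype="datetime64[ns]")
    if len(stamps) < 2:
        raise ValueError(f"{path.name}: a series needs at least 2 samples")
    diffs = np.diff(stamps).astype("timedelta64[ns]").astype(float) / 1e9
    interval = float(np.median(diffs))
    series = GasTimeSeries(
        timestamps=stamps,
        readings=readings.to_numpy(dtype=float),
        logging_interval=interval,
        meta={"source": str(path), "timestamp_column": ts_col, "reading_column": rd_col},
    )
    if validate:
        series.validate(tolerance)
    return series


def write_series(series: GasTimeSeries, path: str | Path, decimals: int = CSV_DECIMALS) -> None:
    """Write a series as ``timestamp,h2s_ppm`` CSV (ISO-8601, fixed decimals)."""
    path = Path(path)
    frame = pd.DataFrame(
        {
            "timestamp": pd.DatetimeIndex(series.timestamps).strftime(
                "%Y-%m-%dT%H:%M:%S.%f"
            ),
            "h2s_ppm": np.round(series.readings, decimals),
        }
    )
    frame.to_csv(path, index=False, float_format=f"%.{decimals}f")


def fill_short_gaps(
    series: GasTimeSeries,
    max_gap: float,
    tolerance: float = DEFAULT_TOLERANCE,
) -> GasTimeSeries:
    """Repair dropped samples by linear interpolation on the regular grid.

    A gap is a consecutive timestamp difference exceeding the logging interval
    by more than ``tolerance``. Gaps of at most ``max_gap`` seconds are filled
    with samples on the nominal grid, readings linearly interpolated between
    the gap's endpoints; the inserted positions are recorded in
    ``meta['filled_gaps']``. Longer gaps are left untouched (and will still
    fail :meth:`GasTimeSeries.validate`). Pure transform: the input is not
    modified.
    """
    if max_gap < series.logging_interval:
        raise ValueError("max_gap must be at least the logging interval")
    dt = series.logging_interval
    diffs = series.interval_seconds()
    gap_rows = set(np.flatnonzero(diffs > dt * (1 + tolerance)).tolist())
    if not gap_rows:
        return GasTimeSeries(
            series.timestamps.copy(), series.readings.copy(), dt, dict(series.meta)
        )

    step = np.timedelta64(int(round(dt * 1e9)), "ns")
    ts_out: list[np.datetime64] = []
    rd_out: list[float] = []
    filled: list[str] = []
    for i in range(len(series)):
        ts_out.append(series.timestamps[i])
        rd_out.append(float(series.readings[i]))
        if i in gap_rows and diffs[i] <= max_gap:
            n_missing = int(round(diffs[i] / dt)) - 1
            t0, t1 = series.timestamps[i], series.timestamps[i + 1]
            r0, r1 = series.readings[i], series.readings[i + 1]
            for k in range(1, n_missing + 1):
                t = t0 + k * step
                frac = (t - t0).astype(float) / (t1 - t0).astype(float)
                ts_out.append(t)
                rd_out.append(float(r0 + frac * (r1 - r0)))
                filled.append(str(np.datetime_as_string(t, unit="s")))
    meta = dict(series.meta)
    if filled:
        meta["filled_gaps"] = meta.get("filled_gaps", []) + filled
    return GasTimeSeries(np.array(ts_out, dtype="datetime64[ns]"), np.array(rd_out), dt, meta)
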