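"""Serialisation of shift reports: JSON per shift, flat CSV rows for batches.

JSON round-trips every numeric field exactly (Python's float repr is
lossless for doubles). The batch CSV is the triage surface: one row per
shift, sorted by descending index so the shifts that most need attention
come first.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .index import IndexElements, ShiftReport

#: fixed column order of the batch summary CSV
SUMMARY_COLUMNS = [
    "file",
    "index",
    "twa_8h",
    "mean_ppm",
    "max_ppm",
    "n_tasks",
    "c01",
    "c1",
    "c5",
    "c10",
    "dur01_min",
    "dur5_min",
]


def write_report(report: ShiftReport, path: str | Path, format: str = "json") -> None:
    """Write one report as JSON, or append it as a CSV summary row.

    ``format='csv-row'`` creates the file with a header if absent and appends
    one summary row otherwise.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2) + "\n", encoding="utf-8")
    elif format == "csv-row":
        row = summary_row(report)
        header = not path.exists() or path.stat().st_size == 0
        pd.DataFrame([row], columns=SUMMARY_COLUMNS).to_csv(
            path, mode="a", header=header, index=False
        )
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> ShiftReport:
    """Read back a JSON report written by :func:`write_report`."""
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    return ShiftReport(
        elements=IndexElements(**d["elements"]),
        index=d["index"],
        twa_8h=d["twa_8h"],
        mean_measured=d["mean_measured"],
        measurement_duration_h=d["measurement_duration_h"],
        n_tasks=d["n_tasks"],
        task_durations_min=d["task_durations_min"],
        exposed_median=d["exposed_median"],
        exposed_gm=d["exposed_gm"],
        exposed_gsd=d["exposed_gsd"],
        n_exposed_samples=d["n_exposed_samples"],
        provenance=d["provenance"],
    )


def summary_row(report: ShiftReport) -> dict:
    e = report.elements
    return {
        "file": report.provenance.get("source", ""),
        "index": report.index,
        "twa_8h": report.twa_8h,
        "mean_ppm": report.mean_measured,
        "max_ppm": e.max_ppm,
        "n_tasks": report.n_tasks,
        "c01": e.c01,
        "c1": e.c1,
        "c5": e.c5,
        "c10": e.c10,
        "dur01_min": e.dur01,
        "dur5_min": e.dur5,
    }


def write_summary(reports: list[ShiftReport], path: str | Path) -> pd.DataFrame:
    """Write the batch summary CSV, rows sorted by descending index."""
    frame = pd.DataFrame([summary_row(r) for r in reports], columns=SUMMARY_COLUMNS)
    frame = frame.sort_values("index", ascending=False, kind="stable").reset_index(drop=True)
    frame.to_csv(path, index=False)
    return frame
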