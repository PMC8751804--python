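"""Literal sample-by-sample reference implementation of the index elements.

A deliberately naive restatement of the method, written as plain Python loops
directly from its definition: per-sample centred averages, run scanning,
the two peak criteria checked literally at every sample, duration counting.
It shares no code with the production modules (which vectorise with
convolutions) and exists solely as the independent arm of equivalence
testing — never call it from the production pipeline.
"""

from __future__ import annotations

import numpy as np

from .index import AlgorithmParams, IndexElements
from .timeseries import GasTimeSeries


def _cma_at(readings, i: int, h: int) -> float:
    lo = max(0, i - h)
    hi = min(len(readings) - 1, i + h)
    total = 0.0
    for j in range(lo, hi + 1):
        total += readings[j]
    return total / (hi - lo + 1)


def _odd_window(window_seconds: float, interval: float) -> int:
    w = int(round(window_seconds / interval))
    if w % 2 == 0:
        w += 1
    return max(w, 1)


def oracle_tasks(series: GasTimeSeries, params: AlgorithmParams) -> list[tuple[int, int]]:
    """Task index ranges (inclusive) by the literal definition."""
    r = [float(x) for x in series.readings]
    n = len(r)
    h = (_odd_window(params.cma_window, series.logging_interval) - 1) // 2
    positive = [_cma_at(r, i, h) > 0.0 for i in range(n)]

    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if positive[i]:
            j = i
            while j + 1 < n and positive[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    merged: list[list[int]] = []
    for s, e in runs:
        if merged and (s - merged[-1][1] - 1) * series.logging_interval < params.separation:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def oracle_peaks(
    series: GasTimeSeries, start: int, end: int, params: AlgorithmParams
) -> list[tuple[int, float]]:
    """(index, apex) of every peak of one task, literal two-criterion check."""
    r = [float(x) for x in series.readings]
    n = len(r)
    h1 = (_odd_window(params.peak_cma_window, series.logging_interval) - 1) // 2
    peaks: list[tuple[int, float]] = []
    for i in range(start, end + 1):
        if r[i] <= 0:
            continue
        if i > 0 and not r[i] > r[i - 1]:
            continue
        if i < n - 1 and not r[i] > r[i + 1]:
            continue
        if r[i] >= params.ratio * _cma_at(r, i, h1):
            peaks.append((i, r[i]))
    if not peaks:
        best_i, best_v = start, r[start]
        for i in range(start, end + 1):
            if r[i] > best_v:
                best_i, best_v = i, r[i]
        peaks.append((best_i, best_v))
    return peaks


def oracle_elements(series: GasTimeSeries, params: AlgorithmParams = AlgorithmParams()) -> IndexElements:
    """The seven index elements by the literal method, one sample at a time."""
    if params.quantize:
        # input conditioning, not part of the method: same rounding convention
        # as the production pipeline (0.1-ppm instrument resolution)
        series = GasTimeSeries(
            series.timestamps,
            np.round(series.readings, 1),
            series.logging_interval,
            dict(series.meta),
        )
    r = [float(x) for x in series.readings]
    c01 = c1 = c5 = c10 = 0
    for start, end in oracle_tasks(series, params):
        for _, apex in oracle_peaks(series, start, end, params):
            if apex <= 1.0:
                c01 += 1
            elif apex <= 5.0:
                c1 += 1
            elif apex <= 10.0:
                c5 += 1
            else:
                c10 += 1
    minutes = series.logging_interval / 60.0
    dur01 = sum(1 for x in r if 0 < x <= 5.0) * minutes
    dur5 = sum(1 for x in r if x > 5.0) * minutes
    max_ppm = max(r) if r else 0.0
    return IndexElements(c01, c1, c5, c10, dur01, dur5, max_ppm)


def oracle_index(series: GasTimeSeries, params: AlgorithmParams = AlgorithmParams()) -> float:
    """The index value, with the weighted sum restated literally."""
    e = oracle_elements(series, params)
    return e.c01 * 0.1 + e.dur01 * 0.1 + e.c1 + e.c5 * 5 + e.dur5 * 5 + e.c10 * 10 + e.max_ppm
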