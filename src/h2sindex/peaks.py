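"""Peak detection and interval classification within exposure tasks.

A sample counts as a distinct peak when two criteria hold together:

1. it is a strict local maximum of the raw readings — larger than both the
   previous and the next sample (at the shift boundary, only the neighbour
   that exists is compared);
2. it stands at least ``ratio`` (default 1.25, i.e. 25% higher) above the
   1-min centred moving average at the same sample.

Criterion 2 suppresses sawtooth noise riding on a broad excursion: a jagged
plateau has many strict local maxima, but none of them rises far above its
own local average. Because it is a ratio, peak detection is invariant under
positive rescaling of the readings.

A task with no qualifying sample still represents a real exposure incident,
so exactly one *forced* peak is emitted at the task's maximum reading
(earliest sample attaining it). Dips towards zero inside a task do not by
themselves create new peaks — only the two criteria do.

Peaks are classified into four concentration bands chosen for their
regulatory and biological relevance (1, 5 and 10 ppm set points):
up to 1.0 ppm, 1.1–5.0 ppm, 5.1–10.0 ppm, and 10.1 ppm and higher. On the
continuous scale the bands are the half-open intervals (0,1], (1,5], (5,10],
(10, inf).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .segmentation import Task
from .smoothing import centred_moving_average
from .timeseries import GasTimeSeries

DEFAULT_PEAK_CMA_WINDOW = 60.0  # seconds
DEFAULT_RATIO = 1.25


class Interval(str, enum.Enum):
    """Concentration band of a peak apex, ppm."""

    I01 = "I01"  # (0, 1]
    I1 = "I1"    # (1, 5]
    I5 = "I5"    # (5, 10]
    I10 = "I10"  # (10, inf)


def classify_interval(apex_ppm: float) -> Interval:
    """Band of a positive apex value under the (lo, hi] convention."""
    if apex_ppm <= 0:
        raise ValueError("a peak apex must be positive")
    if apex_ppm <= 1.0:
        return Interval.I01
    if apex_ppm <= 5.0:
        return Interval.I1
    if apex_ppm <= 10.0:
        return Interval.I5
    return Interval.I10


@dataclass
class Peak:
    """A detected exposure peak: apex sample, value, band, provenance."""

    index: int
    time: np.datetime64
    apex_value: float
    interval: Interval
    forced: bool = False


def detect_peaks(
    series: GasTimeSeries,
    task: Task,
    peak_cma_window: float = DEFAULT_PEAK_CMA_WINDOW,
    ratio: float = DEFAULT_RATIO,
) -> list[Peak]:
    """Find the distinct peaks of one task, ordered by sample index.

    The 1-min CMA used by criterion 2 is computed over the full series, so a
    task boundary does not distort the local average. If no sample satisfies
    both criteria, one forced peak at the task maximum is returned.
    """
    r = series.readings
    n = len(r)
    cma = centred_moving_average(series, peak_cma_window).values

    found: list[Peak] = []
    for i in range(task.start_index, task.end_index + 1):
        v = r[i]
        if v <= 0:
            continue
        higher_than_prev = i == 0 or v > r[i - 1]
        higher_than_next = i == n - 1 or v > r[i + 1]
        if not (higher_than_prev and higher_than_next):
            continue
        # cma[i] > 0 is guaranteed here: the centred window contains sample i
        # itself and v > 0
        assert cma[i] > 0
        if v >= ratio * cma[i]:
            found.append(
                Peak(
                    index=i,
                    time=series.timestamps[i],
                    apex_value=float(v),
                    interval=classify_interval(float(v)),
                )
            )
    if not found:
        seg = r[task.start_index : task.end_index + 1]
        apex_rel = int(np.argmax(seg))  # earliest sample attaining the maximum
        i = task.start_index + apex_rel
        found.append(
            Peak(
                index=i,
                time=series.timestamps[i],
                apex_value=float(r[i]),
                interval=classify_interval(float(r[i])),
                forced=True,
            )
        )
    return found


def count_peaks_by_interval(peaks: list[Peak]) -> tuple[int, int, int, int]:
    """Peak counts per band ``(c01, c1, c5, c10)``; the counts partition the list."""
    c = {Interval.I01: 0, Interval.I1: 0, Interval.I5: 0, Interval.I10: 0}
    for p in peaks:
        c[p.interval] += 1
    return c[Interval.I01], c[Interval.I1], c[Interval.I5], c[Interval.I10]
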