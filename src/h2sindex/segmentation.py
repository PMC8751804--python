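"""Segmentation of a shift into exposure incidents ("tasks").

A task is a maximal run of samples whose 3-min centred moving average is
strictly positive. Two runs separated by a stretch of zero CMA shorter than
the minimum separation time are merged into one task: brief unexposed moments
(walking between manholes, repositioning) do not end an incident. Both the
CMA window and the separation default to 3 min, a choice grounded in the
rhythm of wastewater field work, and both are adjustable for other work
patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .smoothing import centred_moving_average
from .timeseries import GasTimeSeries

DEFAULT_CMA_WINDOW = 180.0  # seconds
DEFAULT_SEPARATION = 180.0  # seconds


@dataclass
class Task:
    """One contiguous exposure incident.

    Indices are 0-based and inclusive on both ends; they address samples of
    the parent series. ``duration_min`` covers the CMA-positive support, so a
    task's boundary samples may themselves read zero.
    """

    start_index: int
    end_index: int
    start_time: np.datetime64
    end_time: np.datetime64
    duration_min: float
    max_reading: float
    peaks: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index + 1


def segment_tasks(
    series: GasTimeSeries,
    cma_window: float = DEFAULT_CMA_WINDOW,
    separation: float = DEFAULT_SEPARATION,
) -> list[Task]:
    """Identify exposure incidents as maximal runs of positive CMA.

    Runs of ``CMA(cma_window) > 0`` whose separating all-zero-CMA gap is
    shorter than ``separation`` seconds are merged into one task. Tasks are
    returned in time order; an all-zero series yields an empty list.
    """
    cma = centred_moving_average(series, cma_window).values
    mask = cma > 0.0
    if not mask.any():
        return []

    # maximal runs of True
    edges = np.diff(mask.astype(np.int8))
    starts = (np.flatnonzero(edges == 1) + 1).tolist()
    ends = np.flatnonzero(edges == -1).tolist()
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask) - 1)

    # merge runs whose zero-CMA gap is shorter than the separation time
    merged: list[list[int]] = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        gap_seconds = (s - merged[-1][1] - 1) * series.logging_interval
        if gap_seconds < separation:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    tasks = []
    for s, e in merged:
        tasks.append(
            Task(
                start_index=s,
                end_index=e,
                start_time=series.timestamps[s],
                end_time=series.timestamps[e],
                duration_min=(e - s + 1) * series.logging_interval / 60.0,
                max_reading=float(series.readings[s : e + 1].max()),
            )
        )
    return tasks


def exposed_samples(series: GasTimeSeries) -> np.ndarray:
    """Indices of samples with a strictly positive raw reading.

    Distinct from the CMA-positive support that defines tasks; used for
    exposed-duration accumulation and the exposed-period summary statistics.
    """
    return np.flatnonzero(series.readings > 0)
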