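"""The exposure index: element assembly, the weighted sum, TWA and summaries.

One shift is condensed into a single dimensionless hazard number built from
seven elements: peak counts in four concentration bands, exposed duration in
two bands, and the shift maximum,

    index = c01*0.1 + dur01*0.1 + c1*1 + c5*5 + dur5*5 + c10*10 + max_ppm

where ``c01..c10`` count peaks with apex in (0,1], (1,5], (5,10] and
(10, inf) ppm, ``dur01``/``dur5`` are the minutes spent at readings in
(0, 5] and above 5 ppm, and ``max_ppm`` is the maximum raw reading of the
whole measurement. Durations enter in minutes: with the 0.1/min and 5/min
weights this is the only unit that keeps duration terms commensurate with
peak counts for incidents lasting minutes. Samples reading exactly zero
contribute to no duration term, so a fully unexposed shift scores 0.

Alongside the index, the conventional averages are computed: the mean over
the measured time and the 8-h time-weighted average (TWA), assuming the
unmeasured remainder of the reference period is unexposed — measurements
covered the active work and stopped when it ended.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .peaks import DEFAULT_PEAK_CMA_WINDOW, DEFAULT_RATIO, count_peaks_by_interval, detect_peaks
from .segmentation import DEFAULT_CMA_WINDOW, DEFAULT_SEPARATION, segment_tasks
from .timeseries import GasTimeSeries

#: Eq. weights, exposed for sensitivity exploration; changing them changes
#: the meaning of the index and published comparability.
WEIGHTS = {
    "c01": 0.1,
    "dur01": 0.1,
    "c1": 1.0,
    "c5": 5.0,
    "dur5": 5.0,
    "c10": 10.0,
    "max_ppm": 1.0,
}


@dataclass(frozen=True)
class AlgorithmParams:
    """Tunable parameters of the pipeline; defaults are the reference choices.

    cma_window
        Wall-time window (s) of the segmentation CMA. Default 180 s.
    separation
        Minimum unexposed (zero-CMA) time (s) separating distinct tasks.
        Default 180 s.
    peak_cma_window
        Window (s) of the local average used by the peak prominence
        criterion. Default 60 s.
    ratio
        A peak apex must be at least this multiple of the local 1-min CMA
        (1.25 = "25% higher"). Dimensionless.
    reference_hours
        Reference period for the TWA. Default 8 h.
    quantize
        Round readings to 0.1 ppm (instrument resolution) before analysis.
        Default off: readings are analysed at the precision they were logged.
    """

    cma_window: float = DEFAULT_CMA_WINDOW
    separation: float = DEFAULT_SEPARATION
    peak_cma_window: float = DEFAULT_PEAK_CMA_WINDOW
    ratio: float = DEFAULT_RATIO
    reference_hours: float = 8.0
    quantize: bool = False


@dataclass
class IndexElements:
    """The seven index elements of one shift."""

    c01: int = 0
    c1: int = 0
    c5: int = 0
    c10: int = 0
    dur01: float = 0.0  # minutes at (0, 5] ppm
    dur5: float = 0.0   # minutes above 5 ppm
    max_ppm: float = 0.0

    def as_tuple(self) -> tuple:
        return (self.c01, self.c1, self.c5, self.c10, self.dur01, self.dur5, self.max_ppm)


@dataclass
class ShiftReport:
    """Everything the pipeline derives from one shift, plus provenance."""

    elements: IndexElements
    index: float
    twa_8h: float
    mean_measured: float
    measurement_duration_h: float
    n_tasks: int
    task_durations_min: list[float]
    exposed_median: float | None
    exposed_gm: float | None
    exposed_gsd: float | None
    n_exposed_samples: int
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def accumulate_durations(series: GasTimeSeries) -> tuple[float, float]:
    """Exposed minutes in the two duration bands ``(dur01, dur5)``.

    Each sample with raw reading ``r`` contributes one logging interval to
    ``dur01`` if ``0 < r <= 5`` and to ``dur5`` if ``r > 5``; zeros count to
    neither.
    """
    r = series.readings
    minutes = series.logging_interval / 60.0
    dur01 = int(np.count_nonzero((r > 0) & (r <= 5.0))) * minutes
    dur5 = int(np.count_nonzero(r > 5.0)) * minutes
    return dur01, dur5


def compute_index(elements: IndexElements) -> float:
    """Evaluate the weighted sum; pure function of the seven elements."""
    e = elements
    return (
        e.c01 * WEIGHTS["c01"]
        + e.dur01 * WEIGHTS["dur01"]
        + e.c1 * WEIGHTS["c1"]
        + e.c5 * WEIGHTS["c5"]
        + e.dur5 * WEIGHTS["dur5"]
        + e.c10 * WEIGHTS["c10"]
        + e.max_ppm * WEIGHTS["max_ppm"]
    )


def compute_twa(series: GasTimeSeries, reference_hours: float = 8.0) -> tuple[float, float]:
    """8-h TWA and measured-time mean, both in ppm.

    The dose is the reading-weighted time integral. ``twa_8h`` spreads it over
    the reference period (time outside the measurement assumed unexposed);
    ``mean_measured`` spreads it over the measured duration only.
    """
    if reference_hours <= 0:
        raise ValueError("reference_hours must be positive")
    dose_ppm_s = float(series.readings.sum()) * series.logging_interval
    duration_s = series.duration_seconds
    mean_measured = dose_ppm_s / duration_s
    twa = dose_ppm_s / (reference_hours * 3600.0)
    return twa, mean_measured


def exposed_summary(
    series: GasTimeSeries,
) -> tuple[float | None, float | None, float | None, int]:
    """Median, geometric mean and geometric SD of the positive readings.

    Returns ``(median, gm, gsd, n_positive)``. GM = exp(mean(ln r));
    GSD = exp(sd(ln r)) with the sample (n-1) standard deviation, undefined
    (None) for fewer than two positive readings; all three are None for a
    fully unexposed shift.
    """
    pos = series.readings[series.readings > 0]
    n = int(pos.size)
    if n == 0:
        return None, None, None, 0
    logs = np.log(pos)
    median = float(np.median(pos))
    gm = float(np.exp(logs.mean()))
    gsd = float(np.exp(logs.std(ddof=1))) if n > 1 else None
    return median, gm, gsd, n


def analyze_shift(
    series: GasTimeSeries, params: AlgorithmParams = AlgorithmParams()
) -> ShiftReport:
    """Run the full pipeline on one validated shift.

    Segmentation, per-task peak detection, duration accumulation, the index
    sum, TWA and exposed-period summaries; the report records every parameter
    used so a run can be reproduced from the report alone.
    """
    if params.quantize:
        series = GasTimeSeries(
            series.timestamps,
            np.round(series.readings, 1),
            series.logging_interval,
            dict(series.meta, quantized_to=0.1),
        )
    tasks = segment_tasks(series, params.cma_window, params.separation)
    all_peaks = []
    for task in tasks:
        task.peaks = detect_peaks(series, task, params.peak_cma_window, params.ratio)
        all_peaks.extend(task.peaks)
    c01, c1, c5, c10 = count_peaks_by_interval(all_peaks)
    dur01, dur5 = accumulate_durations(series)
    max_ppm = float(series.readings.max()) if len(series) else 0.0
    elements = IndexElements(c01, c1, c5, c10, dur01, dur5, max_ppm)
    index = compute_index(elements)
    twa, mean_measured = compute_twa(series, params.reference_hours)
    median, gm, gsd, n_pos = exposed_summary(series)
    return ShiftReport(
        elements=elements,
        index=index,
        twa_8h=twa,
        mean_measured=mean_measured,
        measurement_duration_h=series.duration_seconds / 3600.0,
        n_tasks=len(tasks),
        task_durations_min=[t.duration_min for t in tasks],
        exposed_median=median,
        exposed_gm=gm,
        exposed_gsd=gsd,
        n_exposed_samples=n_pos,
        provenance={
            "source": series.meta.get("source", "<in-memory>"),
            "params": asdict(params),
            "n_samples": len(series),
            "logging_interval_s": series.logging_interval,
        },
    )
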