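"""Seeded generator of realistic shift logs with ground truth attached.

Emulates the structure of field H2S logs from wastewater work: shifts of a
few hours that are mostly zero, with a handful of episodic exposure tasks.
Each task is a burst of one or more pulses with an instantaneous rise and an
exponential decay — outdoors or in ventilated spaces H2S peaks are very steep
and last minutes — and pulse amplitudes are lognormal, matching the
geometric-mean / geometric-SD character of observed positive readings
(defaults GM 1.8 ppm, GSD 9.3).

The generator returns, next to the series, a :class:`GroundTruth` whose
index elements come from the naive literal oracle, never from the production
pipeline, so the whole pipeline can be validated end to end without any
field download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InfeasibleScenario
from .index import AlgorithmParams, IndexElements
from .oracle import oracle_elements, oracle_index, oracle_tasks
from .timeseries import GasTimeSeries

#: pulses decayed below this value (ppm) are cut to zero; keeps exponential
#: tails from gluing the whole shift into one endless task
PULSE_CUTOFF = 0.05

_EPOCH = np.datetime64("2021-06-01T06:00:00", "ns")


@dataclass
class ScenarioSpec:
    """What one synthetic shift should look like.

    ``peaks_per_task`` is either an int or an inclusive ``(lo, hi)`` range
    sampled uniformly. ``task_start_times`` (seconds from shift start)
    overrides automatic placement; automatic placement spaces tasks so that
    segmentation is guaranteed to separate them (zero gap of at least
    separation + cma_window).
    """

    shift_hours: float = 3.75
    logging_interval: float = 10.0
    n_tasks: int = 3
    task_start_times: list[float] | None = None
    peak_amplitude_gm: float = 1.8
    peak_amplitude_gsd: float = 9.3
    peaks_per_task: int | tuple[int, int] = (1, 3)
    pulse_spacing: float = 45.0  # seconds between pulse apexes within a task
    decay_tau: float = 30.0  # seconds, exponential decay constant
    quantize_to: float | None = None  # 0.1 to mimic instrument resolution
    seed: int = 0


@dataclass
class GroundTruth:
    """Construction- and oracle-derived truth for one generated shift."""

    task_windows: list[tuple[int, int]]  # sample index ranges per the oracle
    peak_apexes: list[tuple[float, float]]  # (seconds from start, realized ppm)
    amplitudes: list[float]  # drawn pulse amplitudes, pre-quantization
    elements: IndexElements
    index: float
    n_tasks_constructed: int


def _draw_peaks_per_task(spec: ScenarioSpec, rng: np.random.Generator) -> int:
    if isinstance(spec.peaks_per_task, int):
        return spec.peaks_per_task
    lo, hi = spec.peaks_per_task
    return int(rng.integers(lo, hi + 1))


def generate_shift(
    spec: ScenarioSpec, params: AlgorithmParams = AlgorithmParams()
) -> tuple[GasTimeSeries, GroundTruth]:
    """Synthesize one shift and its ground truth. Deterministic per seed.

    Raises :class:`InfeasibleScenario` when the requested tasks (plus the
    separation margin that keeps them distinct under segmentation) do not fit
    in the shift, or when explicit start times violate that margin.
    """
    rng = np.random.default_rng(spec.seed)
    dt = spec.logging_interval
    n = int(round(spec.shift_hours * 3600.0 / dt))
    if n < 2:
        raise InfeasibleScenario("shift too short for the logging interval")
    readings = np.zeros(n)
    timestamps = _EPOCH + (np.arange(n) * np.timedelta64(int(round(dt * 1e9)), "ns"))

    mu, sigma = math.log(spec.peak_amplitude_gm), math.log(spec.peak_amplitude_gsd)
    # gap that guarantees a zero-CMA stretch of at least `separation` between
    # consecutive tasks: the CMA support extends ~half a window past each end
    margin_s = params.separation + params.cma_window + 2 * dt

    apex_records: list[tuple[float, float]] = []  # (seconds, sample index) later value
    apex_indices: list[int] = []
    amplitudes: list[float] = []
    explicit = spec.task_start_times is not None
    starts = list(spec.task_start_times) if explicit else []
    cursor_s = 600.0 if not explicit else 0.0  # auto mode: first task after 10 min
    support_end_s = -math.inf

    for t in range(spec.n_tasks):
        k = _draw_peaks_per_task(spec, rng)
        amps = np.exp(rng.normal(mu, sigma, size=k))
        if explicit:
            if t >= len(starts):
                raise InfeasibleScenario("fewer task_start_times than n_tasks")
            start_s = float(starts[t])
            if start_s < support_end_s + margin_s:
                raise InfeasibleScenario(
                    f"task {t} starts {start_s:.0f} s from shift start, inside the "
                    f"separation margin of the previous task"
                )
        else:
            jitter = float(rng.uniform(0, 60.0))
            start_s = cursor_s + jitter
        task_end_s = start_s
        for p in range(k):
            amp = float(amps[p])
            amplitudes.append(amp)
            apex_s = start_s + p * spec.pulse_spacing
            i0 = int(round(apex_s / dt))
            if i0 >= n:
                raise InfeasibleScenario(
                    f"task {t} does not fit: pulse at {apex_s:.0f} s beyond shift end"
                )
            # instantaneous rise at i0, exponential decay until below cutoff
            n_decay = (
                int(math.ceil(spec.decay_tau * math.log(amp / PULSE_CUTOFF) / dt))
                if amp > PULSE_CUTOFF
                else 0
            )
            j_hi = min(n - 1, i0 + n_decay)
            idx = np.arange(i0, j_hi + 1)
            pulse = amp * np.exp(-(idx - i0) * dt / spec.decay_tau)
            pulse[pulse < PULSE_CUTOFF] = 0.0
            readings[idx] += pulse
            apex_indices.append(i0)
            apex_records.append((apex_s, 0.0))  # realized value filled below
            task_end_s = max(task_end_s, (j_hi + 1) * dt)
        support_end_s = task_end_s
        if not explicit:
            cursor_s = support_end_s + margin_s
            if cursor_s > n * dt and t + 1 < spec.n_tasks:
                raise InfeasibleScenario(
                    f"only {t + 1} of {spec.n_tasks} tasks fit in a "
                    f"{spec.shift_hours:g}-h shift"
                )

    if spec.quantize_to:
        readings = np.round(readings / spec.quantize_to) * spec.quantize_to

    series = GasTimeSeries(
        timestamps=timestamps,
        readings=readings,
        logging_interval=dt,
        meta={"source": f"synthetic(seed={spec.seed})", "scenario_seed": spec.seed},
    )
    apex_records = [
        (s, float(readings[i])) for (s, _), i in zip(apex_records, apex_indices)
    ]
    elements = oracle_elements(series, params)
    truth = GroundTruth(
        task_windows=oracle_tasks(series, params),
        peak_apexes=apex_records,
        amplitudes=amplitudes,
        elements=elements,
        index=oracle_index(series, params),
        n_tasks_constructed=spec.n_tasks,
    )
    return series, truth
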