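# Methods

## Problem and model

Personal H₂S sensors log a concentration every few seconds across a work
shift. Exposure in wastewater work is episodic: most samples are zero, and
the hazardous part of the day is a handful of incidents in which
concentrations rise within one or two logging intervals and decay within
minutes. An 8-h time-weighted average (TWA) dilutes those incidents to near
zero, so compliance with an average-based limit says little about acute risk.
The pipeline instead summarises a shift as

```
index = c01·0.1 + dur01·0.1 + c1·1 + c5·5 + dur5·5 + c10·10 + max_ppm
```

where `c01..c10` count detected peaks with apex in (0,1], (1,5], (5,10] and
(10,∞) ppm, `dur01`/`dur5` are exposed minutes at (0,5] and >5 ppm, and
`max_ppm` is the maximum raw reading of the measurement. The band edges match
the regulatory anchor points for H₂S (1 ppm threshold limit, 5 ppm 8-h OEL,
10 ppm ceiling value); the weights grow with the acute significance of each
band. The index is dimensionless and reported per shift next to the 8-h TWA.

## Pipeline definitions

**Regular grid.** All windows are defined in wall time, so the input contract
is a strictly increasing timestamp grid whose consecutive differences equal
the logging interval within ±5 % (logger clocks jitter; larger deviations are
validation errors, not silent repairs). `fill_short_gaps` optionally
reconstructs isolated drop-outs by linear interpolation up to a caller-chosen
bound; it is a conservative repair for real logger files, not part of the
method.

**Centred moving average.** A window of `w = round(window/Δt)` samples,
forced odd so the average is centred (`h = (w−1)/2`). At the series edges the
window shrinks to the available samples and the divisor is the actual count —
zero-padding would fabricate unexposed time at shift boundaries and could
suppress tasks there. Windows are accumulated by direct convolution rather
than cumulative sums: segmentation tests `CMA > 0` *strictly*, and a running
cumulative sum would leak rounding error into unexposed stretches, turning
exact zeros into ±1e-16 and corrupting task boundaries.

**Segmentation.** Tasks are maximal runs of positive 3-min CMA; runs whose
separating zero-CMA gap is shorter than the 3-min separation time are merged.
With both parameters at 3 min the CMA already bridges raw zero gaps shorter
than the window, and the merge step additionally joins runs whose zero-CMA
gap (raw gap minus roughly one window) is under 3 min. Task duration is the
CMA-positive support, which is why even a single positive sample yields a
task of about one window's length.

**Peaks.** A sample qualifies when it is a strict local maximum of the raw
readings (boundary samples compare only against the neighbour that exists)
and at least `ratio` (default 1.25) times the 1-min CMA centred on it,
including the sample itself. The ratio reading of the prominence criterion is
the only dimensionless one, making detection invariant under rescaling of the
readings. Plateaus of equal values contain no strict local maximum and fall
through to the forced-peak rule: a task with no qualifying sample emits
exactly one peak at its maximum reading, earliest sample on ties. The local
CMA of a positive candidate is always positive (its own reading is in the
window), so the ratio test never divides by zero.

**Durations, TWA, summaries.** Each sample with reading `r` contributes one
logging interval to `dur01` if `0 < r ≤ 5` and to `dur5` if `r > 5`; zeros
count to neither, so a fully unexposed 8-h shift scores index 0 rather than
48. Durations enter the index in minutes — with incidents lasting minutes,
hours would make the duration terms negligible against the counts and
seconds would dominate everything. The TWA assumes the unmeasured remainder
of the 8-h reference period is unexposed (measurements cover the active
work); the measured-time mean is reported alongside. Exposed-period
statistics (median, geometric mean, geometric SD with the n−1 estimator) are
computed over strictly positive raw readings; the GSD is undefined for fewer
than two of them.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| `cma_window` | 180 | s | segmentation CMA window |
| `separation` | 180 | s | minimum zero-CMA time between tasks |
| `peak_cma_window` | 60 | s | local average for the prominence criterion |
| `ratio` | 1.25 | — | apex-to-local-CMA multiple defining a peak |
| `reference_hours` | 8 | h | TWA reference period |
| `quantize` | off | — | round readings to 0.1 ppm before analysis |

Defaults are the reference configuration for wastewater work; shorter
separations suit work with rapid task turnover. The seven index weights are
module constants; changing them redefines the index and breaks comparability
with previously scored shifts.

## Synthetic generator

`generate_shift` emulates the structure of field logs: a mostly-zero shift
(default 3.75 h at 10-s logging) containing `n_tasks` incidents, each a burst
of 1–3 pulses spaced 45 s apart. A pulse rises instantaneously and decays
exponentially (τ = 30 s default) — steep episodic peaks lasting minutes —
with lognormal apex amplitude (GM 1.8 ppm, GSD 9.3 by default, the character
of observed positive readings in wastewater measurements). Pulse tails are
cut at 0.05 ppm so that decays terminate and tasks stay separated; automatic
placement leaves at least `separation + cma_window` of silence between the
end of one task's support and the next start, which guarantees segmentation
keeps them distinct. Optional 0.1-ppm quantization mimics instrument
resolution.

Each generated shift carries a `GroundTruth` whose index elements are
computed by `h2sindex.oracle` — a deliberately naive, loop-by-loop literal
restatement of the method that shares no algorithmic code with the
production pipeline. Pipeline-vs-oracle equality on hundreds of seeded
shifts is the package's core correctness argument.

What the generator does **not** emulate: sensor drift and negative-baseline
artefacts, cross-sensitivity, alarm-triggered behaviour changes, nonzero
ambient backgrounds, autocorrelated within-task noise, and heavy pulse
overlap. Passing tests therefore demonstrate the algorithm's correctness on
clean episodic signals, not robustness to instrument pathology; real files
with such artefacts will fail validation (by design) rather than be silently
reinterpreted.

A note on amplitudes: with GM 1.8/GSD 9.3, about 5 % of drawn pulses fall
below the 0.05-ppm visibility cutoff and produce no signal, so "number of
constructed tasks" and "number of visible tasks" can differ at those
settings. Structural recovery tests (task count equals the constructed
count) therefore use a controlled amplitude setting (GM 2, GSD 2) where
sub-cutoff draws are virtually impossible; distributional tests use the
study-like defaults.

## Numerical choices

- Band and duration boundaries are half-open `(lo, hi]` on the continuous
  scale, consistent with 0.1-ppm-resolution labels (a "1.1–5.0 ppm" band is
  `(1.0, 5.0]`).
- Forced-peak ties resolve to the earliest sample (determinism).
- Quantization, when enabled, is `np.round(r, 1)` applied once before
  analysis, in both the pipeline and the oracle: it is input conditioning,
  not part of the method.
- JSON reports serialise floats with full `repr` precision, so reading a
  report back reproduces every numeric field exactly.
- CSV series output uses 4 decimals; round-trip identity holds at that
  precision.

## Known limitations

- **The index is not monotone in individual readings.** Raising the dip
  sample between two pulses above a neighbouring apex removes that apex's
  strict-local-maximum status; the lost peak's count weight generally
  exceeds the duration gained, so the index can *decrease* when a single
  reading increases (e.g. readings `[0, 2, 1, 8, 0]` at 10-s logging: raising
  the dip from 1 to 5 ppm drops the index by ~1). This is intrinsic to
  counting strict local maxima, not an implementation artefact; a regression
  test documents the counterexample.
- Task duration is defined on CMA support, so it is bounded below by roughly
  one CMA window and exceeds the raw-positive time of short incidents.
- With very long logging intervals (≥ the CMA window) the window degenerates
  to a single sample and every positive reading becomes its own candidate
  peak; the method is intended for intervals of a few seconds to a minute.
- The TWA headline assumes no exposure outside the measurement; for
  measurements longer than the reference period the measured-time mean is
  the more meaningful figure.
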