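"""Centred moving averages over wall-time windows.

The CMA is the single smoothing primitive of the pipeline: a 3-min CMA drives
task segmentation, a 1-min CMA drives peak validation. The window is specified
in seconds of wall time and converted to an odd number of samples so that the
average is truly centred on each sample; at the series edges the window
shrinks to the samples that exist and the divisor is the actual count (zero
padding would fabricate unexposed time at shift boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import GasTimeSeries


def window_samples(window_seconds: float, logging_interval: float) -> int:
    """Convert a wall-time window to an odd sample count.

    ``w = round(window / interval)``, incremented by one if even so the window
    is symmetric around the centre sample.
    """
    if window_seconds < logging_interval:
        raise ValueError(
            f"window ({window_seconds:g} s) shorter than the logging interval "
            f"({logging_interval:g} s)"
        )
    w = int(round(window_seconds / logging_interval))
    if w % 2 == 0:
        w += 1
    return max(w, 1)


@dataclass
class SmoothedSeries:
    """CMA values aligned sample-for-sample with the parent series."""

    parent: GasTimeSeries
    window: float  # seconds, as requested
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def centred_moving_average(series: GasTimeSeries, window: float) -> SmoothedSeries:
    """Centred moving average of the raw readings over a wall-time window.

    At sample ``i`` the value is the arithmetic mean of readings with index in
    ``[i-h, i+h]`` intersected with the series, where the window spans
    ``w`` samples (odd, ``h = (w-1)//2``).

    Sums are accumulated by direct convolution so that windows containing only
    zero readings come out exactly zero — segmentation tests ``CMA > 0``
    strictly, and cumulative-sum tricks would leak rounding error into
    unexposed stretches.
    """
    w = window_samples(window, series.logging_interval)
    h = (w - 1) // 2
    r = series.readings
    n = len(r)
    kernel = np.ones(w)
    # full convolution sliced to centre alignment: works also when w > n
    sums = np.convolve(r, kernel, mode="full")[h : h + n]
    counts = np.convolve(np.ones(n), kernel, mode="full")[h : h + n]
    return SmoothedSeries(parent=series, window=window, values=sums / counts)
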