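"""Build the observation series the hidden Markov model consumes.

The model's observation at point *t* is the temperature change from the
previous measurement, computed on either the raw egg temperature or the
air-adjusted egg temperature (egg minus air), optionally after a centered
rolling-mean smooth that damps sensor jitter and small posture shifts.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .errors import CapabilityError, ParameterError
from .trace_io import ThermalTrace


class Source(str, Enum):
    """Which temperature series drives the observations."""

    RAW_EGG = "raw_egg"
    ADJUSTED_EGG = "adjusted_egg"


@dataclass
class ObservationSeries:
    """Per-sample temperature changes aligned to trace points.

    ``deltas[0]`` (point 1, which has no previous measurement) is 0 by
    convention; ``deltas[t]`` is the change from point ``t`` to ``t+1``
    of the (optionally smoothed) source series.
    """

    deltas: np.ndarray
    source: Source = Source.RAW_EGG
    smoothing_window: int = 1

    def __post_init__(self) -> None:
        self.deltas = np.asarray(self.deltas, dtype=float)
        if not np.all(np.isfinite(self.deltas)):
            raise ParameterError("non-finite observation delta")
        self.source = Source(self.source)

    def __len__(self) -> int:
        return len(self.deltas)


def rolling_mean(series, window: int) -> np.ndarray:
    """Centered moving average whose window is clipped at the edges.

    The window is centered on each point and shrinks to the points that
    exist near the boundaries, so output length equals input length and
    bout boundaries are not shifted in time.

    >>> rolling_mean([1, 2, 3, 4, 5], 3)
    array([1.5, 2. , 3. , 4. , 4.5])
    """
    x = np.asarray(series, dtype=float)
    if window < 1:
        raise ParameterError(f"smoothing window must be >= 1, got {window}")
    if window > len(x):
        raise ParameterError(
            f"smoothing window {window} exceeds series length {len(x)}"
        )
    if window == 1:
        return x.copy()
    out = (
        pd.Series(x)
        .rolling(window=window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return out


def adjusted_series(trace: ThermalTrace) -> np.ndarray:
    """Egg temperature minus simultaneously logged air temperature.

    Isolates parental heating from environmental drift; requires the trace
    to carry an air column.
    """
    if not trace.has_air:
        raise CapabilityError(
            "adjusted egg temperature needs an air column; trace has none"
        )
    return trace.egg_temp - trace.air_temp


def make_observations(
    trace: ThermalTrace,
    source: Source | str = Source.RAW_EGG,
    window: int = 1,
) -> ObservationSeries:
    """Select the source series, smooth it and difference it.

    Point 1 carries delta 0 (it has no previous measurement); the returned
    series has the same length as the trace.
    """
    source = Source(source)
    if len(trace) < 2:
        raise ParameterError("at least 2 points needed to form observations")
    base = trace.egg_temp if source is Source.RAW_EGG else adjusted_series(trace)
    smoothed = rolling_mean(base, window)
    deltas = np.concatenate([[0.0], np.diff(smoothed)])
    return ObservationSeries(deltas, source=source, smoothing_window=window)
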