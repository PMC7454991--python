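"""Turn per-point state sequences into bouts and filter spurious off-bouts.

A bout is a maximal run of one state. Consecutive bouts alternate kind and
tile the trace without gaps or overlap; a bout's duration includes one
trailing sampling interval, so a single-point bout lasts one interval and
the bout durations of a trace sum to its span plus one interval.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime

import numpy as np

from .errors import AlignmentError, ParameterError
from .trace_io import OFF, ON, ThermalTrace, _STATE_NAMES


@dataclass(frozen=True)
class Bout:
    """A maximal run of one incubation state."""

    kind: int  # ON or OFF
    start_index: int  # 1-based, inclusive
    end_index: int  # 1-based, inclusive
    start_time: datetime
    end_time: datetime
    duration: float  # seconds, includes one trailing sampling interval

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise ParameterError("bout start after end")

    @property
    def kind_name(self) -> str:
        return _STATE_NAMES[self.kind]

    @property
    def n_points(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass(frozen=True)
class BoutFilter:
    """Criteria a decoded off-bout must meet to count as a real one.

    ``min_temp_drop`` is the least egg-temperature drop (degC, starting
    temperature minus the bout's minimum) and ``min_duration`` the least
    duration (seconds). A zero disables that criterion. Off-bouts failing
    either are reclassified as on and absorbed into their neighbors.
    """

    min_temp_drop: float = 0.0
    min_duration: float = 0.0

    def __post_init__(self) -> None:
        if self.min_temp_drop < 0 or self.min_duration < 0:
            raise ParameterError("filter thresholds must be >= 0")


def segment(states, trace: ThermalTrace) -> list[Bout]:
    """Run-length encode a state sequence into bouts tiling the trace."""
    states = np.asarray(states, dtype=int)
    if len(states) != len(trace):
        raise AlignmentError(
            f"state sequence ({len(states)}) and trace ({len(trace)}) lengths differ"
        )
    bouts: list[Bout] = []
    boundaries = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries - 1, [len(states) - 1]])
    for a, b in zip(starts, ends):
        t0 = trace.timestamps[a].to_pydatetime()
        t1 = trace.timestamps[b].to_pydatetime()
        bouts.append(
            Bout(
                kind=int(states[a]),
                start_index=int(a) + 1,
                end_index=int(b) + 1,
                start_time=t0,
                end_time=t1,
                duration=(t1 - t0).total_seconds() + trace.interval,
            )
        )
    return bouts


def states_of(bouts, n_points: int) -> np.ndarray:
    """Inverse of :func:`segment`: expand bouts back to per-point states."""
    states = np.empty(n_points, dtype=int)
    for b in bouts:
        states[b.start_index - 1 : b.end_index] = b.kind
    return states


def _merge_runs(bouts: list[Bout], trace: ThermalTrace) -> list[Bout]:
    return segment(states_of(bouts, len(trace)), trace)


def filter_bouts(
    bouts: list[Bout], trace: ThermalTrace, flt: BoutFilter
) -> tuple[list[Bout], int]:
    """Reclassify off-bouts failing the filter as on-bouts.

    The temperature drop is measured as the starting egg temperature minus
    the minimum egg temperature within the bout (a parent may return before
    the logger catches the rebound, so the net start-to-end change would
    understate real drops). Neighbors of a reclassified bout are merged,
    so the result still tiles the trace. Returns the filtered bouts and
    the number of off-bouts discarded. Applying the same filter twice is a
    no-op the second time.
    """
    if not bouts:
        return [], 0
    kept: list[Bout] = []
    discarded = 0
    for b in bouts:
        if b.kind == OFF:
            egg = trace.egg_temp[b.start_index - 1 : b.end_index]
            drop = float(egg[0] - egg.min())
            if drop < flt.min_temp_drop or b.duration < flt.min_duration:
                discarded += 1
                b = replace(b, kind=ON)
        kept.append(b)
    if discarded:
        kept = _merge_runs(kept, trace)
    return kept, discarded
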