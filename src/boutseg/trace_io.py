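"""Reading and writing logger CSV files, label files and bout tables.

The input dialect is the one thermal data loggers (e.g. HOBO exports)
produce after conversion to CSV: one row per sample with a running data
point number, a date/time, the egg (nest-cup) temperature in degrees
Celsius and, optionally, a simultaneously logged ambient air temperature.
A header row is auto-detected and skipped.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ContiguityError,
    OrderingError,
    ParameterError,
    ParseError,
    ReferenceError_,
    SchemaError,
)

log = logging.getLogger(__name__)

#: state codes used across the package
ON, OFF = 0, 1

_STATE_NAMES = {ON: "on", OFF: "off"}
_STATE_CODES = {"on": ON, "off": OFF}

#: plausible logger range; values outside are rejected at parse time
_TEMP_MIN, _TEMP_MAX = -40.0, 80.0

#: accepted datetime layouts (HOBO-style US dates and ISO-8601)
_DT_FORMATS = (
    "%m/%d/%Y %H:%M:%S",
    "%m/%d/%Y %H:%M",
    "%Y-%m-%dT%H:%M:%S",
    "%Y-%m-%d %H:%M:%S",
    "%Y-%m-%d %H:%M",
)


def parse_datetime(text: str) -> datetime:
    """Parse a timestamp in one of the accepted layouts.

    Accepts ``M/D/YYYY H:MM``, ``M/D/YYYY H:MM:SS`` and ISO-8601 variants;
    anything else raises :class:`ParseError` rather than guessing.
    """
    text = text.strip()
    for fmt in _DT_FORMATS:
        try:
            return datetime.strptime(text, fmt)
        except ValueError:
            continue
    raise ParseError(f"unrecognized date/time {text!r}")


@dataclass(frozen=True)
class SamplePoint:
    """One logger reading: ordinal, timestamp and temperatures (degC)."""

    index: int
    timestamp: datetime
    egg_temp: float
    air_temp: float | None = None


@dataclass
class ThermalTrace:
    """A regularly sampled nest-temperature series.

    Parameters
    ----------
    timestamps
        Strictly increasing, timezone-naive sample times.
    egg_temp
        Egg (nest-cup) temperature per sample, degC.
    air_temp
        Ambient air temperature per sample, degC, or ``None`` when the
        logger recorded egg temperature only.
    interval
        Sampling period in seconds. Computed as the modal gap between
        consecutive timestamps when not given.
    source
        Optional provenance tag (usually the input file name).
    """

    timestamps: pd.DatetimeIndex
    egg_temp: np.ndarray
    air_temp: np.ndarray | None = None
    interval: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.egg_temp = np.asarray(self.egg_temp, dtype=float)
        if self.air_temp is not None:
            self.air_temp = np.asarray(self.air_temp, dtype=float)
            if len(self.air_temp) != len(self.egg_temp):
                raise AlignmentError("air and egg series differ in length")
            if not np.all(np.isfinite(self.air_temp)):
                raise ParseError("non-finite air temperature in trace")
        if len(self.timestamps) != len(self.egg_temp):
            raise AlignmentError("timestamps and egg series differ in length")
        if len(self.timestamps) == 0:
            raise ParseError("empty trace")
        if not np.all(np.isfinite(self.egg_temp)):
            raise ParseError("non-finite egg temperature in trace")
        diffs = np.diff(self.timestamps.asi8)
        if np.any(diffs <= 0):
            pos = int(np.argmax(diffs <= 0)) + 2
            raise OrderingError(
                f"timestamps not strictly increasing at data point {pos}"
            )
        if self.interval <= 0:
            self.interval = _modal_interval(self.timestamps)

    def __len__(self) -> int:
        return len(self.egg_temp)

    @property
    def has_air(self) -> bool:
        return self.air_temp is not None

    @property
    def indices(self) -> np.ndarray:
        """1-based data point ordinals."""
        return np.arange(1, len(self) + 1)

    @property
    def span_seconds(self) -> float:
        """Time from first to last sample (excludes the trailing interval)."""
        return (self.timestamps[-1] - self.timestamps[0]).total_seconds()

    def point(self, index: int) -> SamplePoint:
        """Return the 1-based ``index``-th sample as a :class:`SamplePoint`."""
        i = index - 1
        if not 0 <= i < len(self):
            raise ReferenceError_(f"data point {index} outside trace 1..{len(self)}")
        air = float(self.air_temp[i]) if self.has_air else None
        return SamplePoint(index, self.timestamps[i].to_pydatetime(),
                           float(self.egg_temp[i]), air)

    @property
    def points(self) -> list[SamplePoint]:
        return [self.point(i) for i in self.indices]

    def slice(self, start_index: int, end_index: int) -> "ThermalTrace":
        """Sub-trace over 1-based inclusive ordinals."""
        a, b = start_index - 1, end_index
        air = self.air_temp[a:b] if self.has_air else None
        return ThermalTrace(self.timestamps[a:b], self.egg_temp[a:b], air,
                            interval=self.interval, source=self.source)


@dataclass
class LabelSet:
    """Per-point on/off labels over a contiguous index range of a trace."""

    first_index: int
    states: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if self.states.size == 0:
            raise ContiguityError("label set is empty")
        if self.first_index < 1:
            raise ReferenceError_("labels must start at data point >= 1")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def last_index(self) -> int:
        return self.first_index + len(self.states) - 1

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.first_index, self.last_index + 1)

    def state_of(self, index: int) -> int:
        return int(self.states[index - self.first_index])


def _modal_interval(timestamps: pd.DatetimeIndex) -> float:
    diffs = np.diff(timestamps.asi8) / 1e9
    if diffs.size == 0:
        return 0.0
    values, counts = np.unique(diffs, return_counts=True)
    return float(values[np.argmax(counts)])


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def read_trace(path, *, gap_factor: float = 2.0) -> ThermalTrace:
    """Read a logger CSV into a :class:`ThermalTrace`.

    Columns are (data point number, date/time, egg temperature[, air
    temperature]). A header row — detected as a first row whose third
    field is non-numeric — is skipped. ``has_air`` is true iff a fourth
    column is present and non-empty on every row; a mixed layout raises
    :class:`SchemaError`.

    Gaps up to ``gap_factor`` times the modal sampling interval are
    tolerated with a warning; use :func:`split_on_gaps` to break a trace
    with larger gaps into independently analyzable segments.
    """
    rows: list[tuple[int, list[str]]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            rows.append((lineno, [c.strip() for c in row]))
    if not rows:
        raise ParseError(f"{path}: no data rows")
    # header auto-detection: first row whose 3rd field is non-numeric
    first = rows[0][1]
    if len(first) >= 3 and not _is_number(first[2]):
        rows = rows[1:]
    if not rows:
        raise ParseError(f"{path}: no data rows after header")

    times: list[datetime] = []
    egg: list[float] = []
    air: list[float] = []
    air_seen = air_missing = 0
    prev_ordinal: int | None = None
    for rowno, r in rows:
        if len(r) not in (3, 4):
            raise ParseError(f"{path}: row {rowno}: expected 3 or 4 columns, got {len(r)}")
        try:
            ordinal = int(float(r[0]))
        except ValueError as exc:
            raise ParseError(f"{path}: row {rowno}: bad data point number {r[0]!r}") from exc
        if prev_ordinal is not None and ordinal != prev_ordinal + 1:
            raise ParseError(
                f"{path}: row {rowno}: data point numbers not consecutive "
                f"({prev_ordinal} -> {ordinal})"
            )
        prev_ordinal = ordinal
        try:
            ts = parse_datetime(r[1])
        except ParseError as exc:
            raise ParseError(f"{path}: row {rowno}: {exc}") from exc
        try:
            t_egg = float(r[2])
        except ValueError as exc:
            raise ParseError(f"{path}: row {rowno}: bad egg temperature {r[2]!r}") from exc
        if not _TEMP_MIN <= t_egg <= _TEMP_MAX:
            raise ParseError(
                f"{path}: row {rowno}: egg temperature {t_egg} degC outside "
                f"plausible range [{_TEMP_MIN}, {_TEMP_MAX}]"
            )
        if len(r) == 4 and r[3] != "":
            try:
                t_air = float(r[3])
            except ValueError as exc:
                raise ParseError(f"{path}: row {rowno}: bad air temperature {r[3]!r}") from exc
            if not _TEMP_MIN <= t_air <= _TEMP_MAX:
                raise ParseError(
                    f"{path}: row {rowno}: air temperature {t_air} degC outside "
                    f"plausible range [{_TEMP_MIN}, {_TEMP_MAX}]"
                )
            air.append(t_air)
            air_seen += 1
        else:
            air_missing += 1
        times.append(ts)
        egg.append(t_egg)

    if air_seen and air_missing:
        raise SchemaError(
            f"{path}: air temperature present on {air_seen} rows but missing on "
            f"{air_missing}; the column must be all-present or all-absent"
        )
    trace = ThermalTrace(
        pd.DatetimeIndex(times),
        np.array(egg),
        np.array(air) if air_seen else None,
        source=str(path),
    )
    diffs = np.diff(trace.timestamps.asi8) / 1e9
    big = diffs > gap_factor * trace.interval
    if np.any(big):
        n = int(big.sum())
        warnings.warn(
            f"{path}: {n} sampling gap(s) exceed {gap_factor}x the modal interval "
            f"({trace.interval:.0f} s); consider split_on_gaps()",
            stacklevel=2,
        )
    return trace


def split_on_gaps(trace: ThermalTrace, gap_factor: float = 2.0) -> list[ThermalTrace]:
    """Split a trace at sampling gaps larger than ``gap_factor`` x interval.

    The model assumes regular observations, so segments separated by long
    logger outages are analyzed independently.
    """
    diffs = np.diff(trace.timestamps.asi8) / 1e9
    cuts = np.flatnonzero(diffs > gap_factor * trace.interval)
    if cuts.size == 0:
        return [trace]
    bounds = [0, *(cuts + 1), len(trace)]
    return [trace.slice(a + 1, b) for a, b in zip(bounds[:-1], bounds[1:])]


def read_labels(path, trace: ThermalTrace) -> LabelSet:
    """Read a labels CSV and return a contiguous per-point :class:`LabelSet`.

    Two forms are accepted, auto-detected from the second column:

    * per-point — ``index,state`` with state in {on, off};
    * vertex — ``index,event`` with event in {depart, return}. Points from
      a ``depart`` vertex up to (excluding) the next ``return`` vertex are
      labeled off; every other point of the trace is labeled on, and the
      labeled range is the whole trace.
    """
    entries: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ParseError(f"{path}: row {lineno}: expected index,label")
            idx_s, lab = row[0].strip(), row[1].strip().lower()
            if not _is_number(idx_s):
                continue  # header
            entries.append((int(float(idx_s)), lab))
    if not entries:
        raise ParseError(f"{path}: no label rows")

    kinds = {lab for _, lab in entries}
    if kinds <= {"on", "off"}:
        entries.sort(key=lambda e: e[0])
        idx = np.array([i for i, _ in entries])
        for i in idx:
            if not 1 <= i <= len(trace):
                raise ReferenceError_(f"{path}: labeled point {i} outside trace 1..{len(trace)}")
        if np.any(np.diff(idx) == 0):
            raise ParseError(f"{path}: duplicate labeled point")
        if np.any(np.diff(idx) != 1):
            raise ContiguityError(f"{path}: labeled index range has gaps")
        states = np.array([_STATE_CODES[lab] for _, lab in entries])
        return LabelSet(int(idx[0]), states)
    if kinds <= {"depart", "return"}:
        entries.sort(key=lambda e: e[0])
        for i, _ in entries:
            if not 1 <= i <= len(trace):
                raise ReferenceError_(f"{path}: vertex {i} outside trace 1..{len(trace)}")
        states = np.full(len(trace), ON, dtype=int)
        off_from: int | None = None
        for i, event in entries:
            if event == "depart":
                off_from = i
            elif off_from is not None:
                states[off_from - 1 : i - 1] = OFF
                off_from = None
        if off_from is not None:  # departure with no recorded return
            states[off_from - 1 :] = OFF
        return LabelSet(1, states)
    raise ParseError(
        f"{path}: labels must all be on/off or all depart/return, got {sorted(kinds)}"
    )


#: Individual-bout output columns, in table order
BOUT_COLUMNS = (
    "Date",
    "Bout type",
    "Start time",
    "End time",
    "Start data point",
    "End data point",
    "Duration (min)",
    "Egg temperature change (degC)",
    "Starting egg temperature (degC)",
    "Ending egg temperature (degC)",
    "Mean egg temperature (degC)",
    "Starting air temperature (degC)",
    "Ending air temperature (degC)",
    "Mean air temperature (degC)",
)


def write_bout_records(records, path) -> None:
    """Write one CSV row per bout with the individual-bout statistics.

    Air fields are written as empty strings for traces without air data.
    Durations are minutes with 2 decimals; temperatures degC with 2
    decimals.
    """
    records = list(records)
    if not records:
        raise ParameterError("no bout records to write")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(BOUT_COLUMNS)
        for r in records:
            w.writerow(r.as_row())
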