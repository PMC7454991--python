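"""Bout-level, daily, per-file and multi-file incubation statistics.

Three tiers are reported:

* individual bout — date, type, start/end, duration, egg temperature
  change and per-bout egg/air temperature summaries;
* individual day / file — bout counts and duration/change aggregates,
  total on/off time, cumulative time above/below critical egg
  temperatures, discarded-bout count, and egg/air temperature statistics
  split into daytime, nighttime and combined;
* multiple files — the same aggregates pooled over every input file, plus
  the number of full days of coverage.

Bouts are assigned to the calendar date (and to the day or night window)
containing their *start* time; temperature statistics are computed
point-wise, each sample counted in its own date and window, so nothing is
double counted when a bout straddles a boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as date_t
from datetime import datetime, time

import numpy as np

from .errors import AlignmentError, ParameterError
from .segmentation import Bout
from .trace_io import OFF, ON, ThermalTrace

_SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class SummaryConfig:
    """Reporting options.

    ``day_start``/``day_end`` bound the daytime window (default
    07:00-19:00); a sample is "day" iff its clock time lies in
    ``[day_start, day_end)``. ``critical_upper``/``critical_lower`` are
    egg-temperature thresholds (degC) for cumulative exposure time;
    leave ``None`` to omit those fields.
    """

    day_start: time = time(7, 0)
    day_end: time = time(19, 0)
    critical_upper: float | None = None
    critical_lower: float | None = None

    def __post_init__(self) -> None:
        if self.day_start >= self.day_end:
            raise ParameterError("day_start must be before day_end")

    def is_day(self, ts: datetime) -> bool:
        return self.day_start <= ts.time() < self.day_end


@dataclass(frozen=True)
class BoutRecord:
    """Individual-bout statistics (Table-style row)."""

    date: date_t
    bout_type: str
    start_time: datetime
    end_time: datetime
    start_index: int
    end_index: int
    duration_min: float
    egg_change: float
    egg_start: float
    egg_end: float
    egg_mean: float
    air_start: float | None = None
    air_end: float | None = None
    air_mean: float | None = None

    def as_row(self) -> list[str]:
        def t(v):
            return "" if v is None else f"{v:.2f}"

        return [
            self.start_time.strftime("%m/%d/%Y"),
            self.bout_type,
            self.start_time.strftime("%m/%d/%Y %H:%M:%S"),
            self.end_time.strftime("%m/%d/%Y %H:%M:%S"),
            str(self.start_index),
            str(self.end_index),
            f"{self.duration_min:.2f}",
            t(self.egg_change),
            t(self.egg_start),
            t(self.egg_end),
            t(self.egg_mean),
            t(self.air_start),
            t(self.air_end),
            t(self.air_mean),
        ]


@dataclass(frozen=True)
class TempStats:
    """Point-wise summary of one temperature series over one partition."""

    n: int
    mean: float
    stdev: float | None
    median: float
    min: float
    max: float

    @classmethod
    def of(cls, x: np.ndarray) -> "TempStats | None":
        if len(x) == 0:
            return None
        return cls(
            n=int(len(x)),
            mean=float(np.mean(x)),
            stdev=float(np.std(x, ddof=1)) if len(x) >= 2 else None,
            median=float(np.median(x)),
            min=float(np.min(x)),
            max=float(np.max(x)),
        )


@dataclass
class PeriodSummary:
    """Aggregates for one reporting period (a day, a file, or all files)."""

    label: str
    on_count: int
    off_count: int
    mean_on_dur: float | None  # minutes
    sd_on_dur: float | None
    mean_off_dur: float | None
    sd_off_dur: float | None
    mean_on_change: float | None  # degC
    sd_on_change: float | None
    mean_off_change: float | None
    sd_off_change: float | None
    on_time: float  # minutes
    off_time: float
    time_above: float | None  # minutes
    time_below: float | None
    discarded: int
    egg: dict[str, TempStats | None] = field(default_factory=dict)
    air: dict[str, TempStats | None] | None = None
    n_full_days: int | None = None


def bout_record(bout: Bout, trace: ThermalTrace) -> BoutRecord:
    """Individual-bout statistics straight from the trace.

    Egg temperature change is ending minus starting egg temperature; means
    are arithmetic over the bout's points. Air fields are ``None`` when
    the trace has no air column.
    """
    if bout.end_index > len(trace) or bout.start_index < 1:
        raise AlignmentError(
            f"bout {bout.start_index}-{bout.end_index} outside trace 1..{len(trace)}"
        )
    a, b = bout.start_index - 1, bout.end_index
    egg = trace.egg_temp[a:b]
    air = trace.air_temp[a:b] if trace.has_air else None
    return BoutRecord(
        date=bout.start_time.date(),
        bout_type=bout.kind_name,
        start_time=bout.start_time,
        end_time=bout.end_time,
        start_index=bout.start_index,
        end_index=bout.end_index,
        duration_min=bout.duration / 60.0,
        egg_change=float(egg[-1] - egg[0]),
        egg_start=float(egg[0]),
        egg_end=float(egg[-1]),
        egg_mean=float(egg.mean()),
        air_start=float(air[0]) if air is not None else None,
        air_end=float(air[-1]) if air is not None else None,
        air_mean=float(air.mean()) if air is not None else None,
    )


def _mean_sd(x: list[float]) -> tuple[float | None, float | None]:
    if not x:
        return None, None
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if len(x) >= 2 else None
    return mean, sd


def _summarize(
    label: str,
    bout_rows: list[tuple[int, float, float]],  # (kind, duration s, egg change)
    point_sets: list[tuple[ThermalTrace, np.ndarray]],  # (trace, selection mask)
    discarded: int,
    config: SummaryConfig,
    n_full_days: int | None = None,
) -> PeriodSummary:
    on_dur = [d / 60.0 for k, d, _ in bout_rows if k == ON]
    off_dur = [d / 60.0 for k, d, _ in bout_rows if k == OFF]
    on_chg = [c for k, _, c in bout_rows if k == ON]
    off_chg = [c for k, _, c in bout_rows if k == OFF]
    mean_on_dur, sd_on_dur = _mean_sd(on_dur)
    mean_off_dur, sd_off_dur = _mean_sd(off_dur)
    mean_on_change, sd_on_change = _mean_sd(on_chg)
    mean_off_change, sd_off_change = _mean_sd(off_chg)

    egg_parts: dict[str, list[np.ndarray]] = {"day": [], "night": [], "combined": []}
    air_parts: dict[str, list[np.ndarray]] = {"day": [], "night": [], "combined": []}
    any_air = False
    above = below = 0.0
    for trace, mask in point_sets:
        if not mask.any():
            continue
        is_day = np.array([config.is_day(ts) for ts in trace.timestamps[mask]])
        egg = trace.egg_temp[mask]
        egg_parts["day"].append(egg[is_day])
        egg_parts["night"].append(egg[~is_day])
        egg_parts["combined"].append(egg)
        if trace.has_air:
            any_air = True
            air = trace.air_temp[mask]
            air_parts["day"].append(air[is_day])
            air_parts["night"].append(air[~is_day])
            air_parts["combined"].append(air)
        if config.critical_upper is not None:
            above += float((egg > config.critical_upper).sum()) * trace.interval
        if config.critical_lower is not None:
            below += float((egg < config.critical_lower).sum()) * trace.interval

    def collect(parts):
        return {
            k: TempStats.of(np.concatenate(v) if v else np.empty(0))
            for k, v in parts.items()
        }

    return PeriodSummary(
        label=label,
        on_count=len(on_dur),
        off_count=len(off_dur),
        mean_on_dur=mean_on_dur,
        sd_on_dur=sd_on_dur,
        mean_off_dur=mean_off_dur,
        sd_off_dur=sd_off_dur,
        mean_on_change=mean_on_change,
        sd_on_change=sd_on_change,
        mean_off_change=mean_off_change,
        sd_off_change=sd_off_change,
        on_time=sum(on_dur),
        off_time=sum(off_dur),
        time_above=above / 60.0 if config.critical_upper is not None else None,
        time_below=below / 60.0 if config.critical_lower is not None else None,
        discarded=discarded,
        egg=collect(egg_parts),
        air=collect(air_parts) if any_air else None,
        n_full_days=n_full_days,
    )


def _bout_rows(bouts: list[Bout], trace: ThermalTrace):
    rows = []
    for b in bouts:
        egg = trace.egg_temp[b.start_index - 1 : b.end_index]
        rows.append((b.kind, b.duration, float(egg[-1] - egg[0])))
    return rows


def full_days(trace: ThermalTrace) -> int:
    """Calendar dates whose coverage spans at least 24 h minus one interval."""
    dates = trace.timestamps.normalize()
    n = 0
    for d in dates.unique():
        sel = dates == d
        ts = trace.timestamps[sel]
        span = (ts[-1] - ts[0]).total_seconds() + trace.interval
        if span >= _SECONDS_PER_DAY - 1e-6:
            n += 1
    return n


def daily_summaries(
    bouts: list[Bout],
    trace: ThermalTrace,
    discarded: int,
    config: SummaryConfig,
) -> list[PeriodSummary]:
    """One :class:`PeriodSummary` per calendar date of the trace.

    A bout counts toward the date containing its start time; temperature
    statistics cover the points whose timestamps fall on the date. The
    discarded-bout count is a whole-file quantity and is repeated on each
    day's summary unchanged.
    """
    dates = trace.timestamps.normalize()
    out = []
    for d in dates.unique():
        mask = (dates == d).to_numpy() if hasattr(dates == d, "to_numpy") else np.asarray(dates == d)
        day_bouts = [b for b in bouts if b.start_time.date() == d.date()]
        out.append(
            _summarize(
                d.strftime("%m/%d/%Y"),
                _bout_rows(day_bouts, trace),
                [(trace, mask)],
                discarded=discarded,
                config=config,
            )
        )
    return out


def file_summary(
    bouts: list[Bout],
    trace: ThermalTrace,
    discarded: int,
    config: SummaryConfig,
) -> PeriodSummary:
    """Whole-file aggregates."""
    mask = np.ones(len(trace), dtype=bool)
    return _summarize(
        trace.source or "file",
        _bout_rows(bouts, trace),
        [(trace, mask)],
        discarded,
        config,
        n_full_days=full_days(trace),
    )


def compile_summaries(per_file, config: SummaryConfig) -> PeriodSummary:
    """Pooled aggregates across input files.

    ``per_file`` is a sequence of ``(bouts, trace, discarded)`` triples.
    Bout-level aggregates pool all bouts and point-level aggregates pool
    all samples (each bout and each point gets equal weight, rather than
    averaging per-file means). Air statistics cover the air-bearing files
    only; a mixed set logs a warning.
    """
    per_file = list(per_file)
    if not per_file:
        raise ParameterError("no files to compile")
    rows: list[tuple[int, float, float]] = []
    point_sets = []
    discarded = 0
    days = 0
    has_air = [t.has_air for _, t, _ in per_file]
    if any(has_air) and not all(has_air):
        import logging

        logging.getLogger(__name__).warning(
            "air statistics pooled over %d of %d files (others lack air data)",
            sum(has_air), len(has_air),
        )
    for bouts, trace, disc in per_file:
        rows.extend(_bout_rows(bouts, trace))
        point_sets.append((trace, np.ones(len(trace), dtype=bool)))
        discarded += disc
        days += full_days(trace)
    return _summarize("all files", rows, point_sets, discarded, config,
                      n_full_days=days)


# --- rendering ------------------------------------------------------------

def _fmt(v, nd=2):
    if v is None:
        return ""
    return f"{v:.{nd}f}"


def render_summary(s: PeriodSummary, *, tier: str = "file") -> str:
    """Render a :class:`PeriodSummary` as ``field,value`` CSV lines.

    ``tier`` is ``"day"``, ``"file"`` or ``"compiled"`` and controls which
    fields appear (the compiled tier adds the number of full days).
    """
    lines = [f"Summary,{s.label}"]
    lines += [
        f"Bout number (on),{s.on_count}",
        f"Bout number (off),{s.off_count}",
        f"Mean bout duration (on) (min),{_fmt(s.mean_on_dur)}",
        f"Mean bout duration (on) stdev (min),{_fmt(s.sd_on_dur)}",
        f"Mean bout duration (off) (min),{_fmt(s.mean_off_dur)}",
        f"Mean bout duration (off) stdev (min),{_fmt(s.sd_off_dur)}",
        f"Mean egg temperature change (on) (degC),{_fmt(s.mean_on_change)}",
        f"Mean egg temperature change (on) stdev (degC),{_fmt(s.sd_on_change)}",
        f"Mean egg temperature change (off) (degC),{_fmt(s.mean_off_change)}",
        f"Mean egg temperature change (off) stdev (degC),{_fmt(s.sd_off_change)}",
    ]
    if tier != "compiled":
        lines += [
            f"Sum of bout type time (on) (min),{_fmt(s.on_time)}",
            f"Sum of bout type time (off) (min),{_fmt(s.off_time)}",
        ]
        if s.time_above is not None:
            lines.append(f"Time above critical egg temperature (min),{_fmt(s.time_above)}")
        if s.time_below is not None:
            lines.append(f"Time below critical egg temperature (min),{_fmt(s.time_below)}")
        lines.append(f"Bouts discarded,{s.discarded}")
    else:
        lines.append(f"Number of full days,{s.n_full_days}")

    def temp_block(name, stats: dict, fields):
        block = []
        for part in ("day", "night", "combined"):
            st = stats.get(part)
            suffix = "" if part == "combined" else f" ({part})"
            for label, attr in fields:
                v = getattr(st, attr) if st is not None else None
                block.append(f"{label} {name} temperature{suffix} (degC),{_fmt(v)}")
        return block

    if tier == "compiled":
        egg_fields = [("Mean", "mean"), ("Stdev", "stdev")]
    else:
        egg_fields = [
            ("Mean", "mean"),
            ("Stdev", "stdev"),
            ("Median", "median"),
            ("Minimum", "min"),
            ("Maximum", "max"),
        ]
    lines += temp_block("egg", s.egg, egg_fields)
    if tier == "compiled":
        comb = s.egg.get("combined")
        lines.append(f"Minimum egg temperature (degC),{_fmt(comb.min if comb else None)}")
        lines.append(f"Maximum egg temperature (degC),{_fmt(comb.max if comb else None)}")
    if s.air is not None:
        if tier == "compiled":
            comb = s.air.get("combined")
            lines.append(f"Mean air temperature (degC),{_fmt(comb.mean if comb else None)}")
        else:
            lines += temp_block("air", s.air, [("Mean", "mean")])
        comb = s.air.get("combined")
        lines.append(f"Minimum air temperature (degC),{_fmt(comb.min if comb else None)}")
        lines.append(f"Maximum air temperature (degC),{_fmt(comb.max if comb else None)}")
    return "\n".join(lines) + "\n"
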