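"""Synthetic nest-temperature traces with ground-truth bout labels.

The generator emulates what an egg-shaped thermal probe in an attended
nest records: during on-bouts the egg warms toward an incubation setpoint,
during off-bouts it cools toward ambient air by Newtonian relaxation; air
follows a diurnal sinusoid and the sensor adds Gaussian noise. Bout
durations are geometric (memoryless), matching the first-order Markov
assumption of the decoding model, so parameter-recovery tests have an
exactly correct target: the self-transition probability of each state is
``1 - interval / mean_duration``.

Presets cover an easy regime (``clear``: strong warming/cooling contrast,
low noise), a stressful one (``hard``: weak contrast, heavy noise), and
two logger configurations used with real species: 2-minute sampling as
for quail and wood ducks, and 30-second sampling as for swallows, tits
and canaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, time, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .hmm_core import HMMParams
from .trace_io import OFF, ON, _STATE_NAMES, ThermalTrace

_DAY_SECONDS = 86400.0


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    Attributes
    ----------
    seed
        Pseudo-random seed; one stream per run, so identical seeds give
        bit-identical output.
    interval
        Sampling period, seconds (30 s and 120 s match common logger
        programs).
    duration_hours
        Length of the trace.
    start
        Timestamp of the first sample.
    setpoint
        Incubation equilibrium egg temperature, degC.
    k_on, k_off
        Per-sample Newtonian relaxation rates in (0, 1]: each step moves
        the egg this fraction of the way toward its current target
        (setpoint when attended, air when not).
    air_mean, air_amplitude
        Diurnal air sinusoid, degC; ``air_min_time`` is the clock time at
        which air bottoms out (pre-dawn by default).
    noise_sd
        Gaussian sensor noise per sample, degC.
    mean_on_minutes, mean_off_minutes
        Mean bout durations of the generating two-state chain.
    night_suppression
        If true, off-bouts cannot start between ``day_end`` and
        ``day_start`` (many incubating birds sit tight overnight).
    """

    seed: int = 0
    interval: float = 30.0
    duration_hours: float = 24.0
    start: datetime = datetime(2021, 6, 1, 0, 0, 0)
    setpoint: float = 37.5
    k_on: float = 0.2
    k_off: float = 0.018
    air_mean: float = 18.0
    air_amplitude: float = 6.0
    air_min_time: time = time(5, 0)
    noise_sd: float = 0.02
    mean_on_minutes: float = 60.0
    mean_off_minutes: float = 8.0
    night_suppression: bool = False
    day_start: time = time(7, 0)
    day_end: time = time(19, 0)

    def __post_init__(self) -> None:
        if not (0 < self.k_on <= 1 and 0 < self.k_off <= 1):
            raise ParameterError("relaxation rates must be in (0, 1]")
        if self.interval <= 0 or self.duration_hours <= 0:
            raise ParameterError("interval and duration must be positive")
        if self.mean_on_minutes <= 0 or self.mean_off_minutes <= 0:
            raise ParameterError("mean bout durations must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    @property
    def stay_on(self) -> float:
        """Self-transition probability of the on state per sample."""
        return max(0.0, 1.0 - self.interval / (self.mean_on_minutes * 60.0))

    @property
    def stay_off(self) -> float:
        return max(0.0, 1.0 - self.interval / (self.mean_off_minutes * 60.0))


PRESETS: dict[str, SimConfig] = {
    # strong contrast, low noise: bouts are visually unambiguous
    "clear": SimConfig(),
    # weak contrast, heavy noise: exercises smoothing and the bout filter
    "hard": SimConfig(
        k_on=0.05,
        k_off=0.015,
        noise_sd=0.15,
        mean_on_minutes=25.0,
        mean_off_minutes=6.0,
        air_mean=24.0,
        air_amplitude=4.0,
    ),
    # 2-minute logger program (quail / wood duck style), longer bouts
    "quail-2min": SimConfig(
        interval=120.0,
        k_on=0.4,
        k_off=0.1,
        mean_on_minutes=60.0,
        mean_off_minutes=20.0,
        night_suppression=True,
    ),
    # 30-second logger program (swallow / tit style)
    "swallow-30s": SimConfig(
        interval=30.0,
        mean_on_minutes=20.0,
        mean_off_minutes=8.0,
        air_mean=14.0,
        air_amplitude=8.0,
    ),
}


def air_temperature(config: SimConfig, seconds_since_start: np.ndarray) -> np.ndarray:
    """Diurnal air sinusoid with its minimum at ``air_min_time``."""
    t0 = (
        _clock_seconds(config.start.time())
        - _clock_seconds(config.air_min_time)
    )
    phase = 2.0 * np.pi * (np.asarray(seconds_since_start) + t0) / _DAY_SECONDS
    return config.air_mean - config.air_amplitude * np.cos(phase)


def _clock_seconds(t: time) -> float:
    return t.hour * 3600.0 + t.minute * 60.0 + t.second


def true_hmm_params(config: SimConfig) -> HMMParams:
    """The generating chain's transition structure as decoder parameters.

    Transition probabilities are exact; observation moments are rough
    analytic stand-ins (warming/cooling deltas vary within a bout, so no
    single Gaussian is exact) — supervised fitting on simulated truth
    labels gives better moments.
    """
    drop = config.setpoint - config.air_mean
    mu_off = -config.k_off * drop * 0.6
    mu_on = config.k_on * drop * 0.1
    sigma_on = max(config.noise_sd * 1.5, abs(mu_on), 1e-3)
    sigma_off = max(config.noise_sd * 1.5, abs(mu_off) * 0.8, 1e-3)
    return HMMParams(
        pi_on=0.5,
        pi_off=0.5,
        a_on_on=config.stay_on,
        a_on_off=1.0 - config.stay_on,
        a_off_on=1.0 - config.stay_off,
        a_off_off=config.stay_off,
        mu_on=mu_on,
        mu_off=mu_off,
        sigma_on=sigma_on,
        sigma_off=sigma_off,
    )


def simulate_trace(config: SimConfig) -> tuple[ThermalTrace, np.ndarray]:
    """Generate a trace and its ground-truth state sequence.

    The state chain starts on-bout. Egg temperature follows
    ``egg[t] = egg[t-1] + k * (target - egg[t-1]) + noise`` with target
    and rate set by the state at ``t``.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_hours * 3600.0 / config.interval)) + 1
    if n < 2:
        raise ParameterError("duration too short for the sampling interval")
    seconds = np.arange(n) * config.interval
    air = air_temperature(config, seconds)
    timestamps = pd.DatetimeIndex(
        [config.start + timedelta(seconds=float(s)) for s in seconds]
    )

    states = np.empty(n, dtype=int)
    states[0] = ON
    u = rng.random(n)
    for t in range(1, n):
        prev = states[t - 1]
        stay = config.stay_on if prev == ON else config.stay_off
        ts = timestamps[t]
        night = not (config.day_start <= ts.time() < config.day_end)
        if config.night_suppression and night and prev == ON:
            states[t] = ON  # no departures overnight
            continue
        states[t] = prev if u[t] < stay else 1 - prev

    egg = np.empty(n)
    egg[0] = config.setpoint if states[0] == ON else air[0]
    noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)
    for t in range(1, n):
        if states[t] == ON:
            k, target = config.k_on, config.setpoint
        else:
            k, target = config.k_off, air[t]
        egg[t] = egg[t - 1] + k * (target - egg[t - 1]) + noise[t]

    trace = ThermalTrace(timestamps, egg, air.copy(), interval=config.interval,
                         source=f"simulated(seed={config.seed})")
    return trace, states


def sample_hmm_observations(
    params: HMMParams, n: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (observations, states) directly from a Gaussian two-state HMM.

    Useful as a clean target for Baum-Welch recovery tests, with none of
    the within-bout delta drift of the thermal generator.
    """
    rng = np.random.default_rng(seed)
    states = np.empty(n, dtype=int)
    states[0] = ON if rng.random() < params.pi_on else OFF
    A = params.transmat
    for t in range(1, n):
        states[t] = ON if rng.random() < A[states[t - 1], ON] else OFF
    obs = rng.normal(params.mu[states], params.sigma[states])
    return obs, states


def write_fixture(
    trace: ThermalTrace, states: np.ndarray, out_dir
) -> tuple[Path, Path]:
    """Write the trace CSV and a per-point ground-truth labels CSV.

    The trace file follows the logger dialect (point number, M/D/YYYY
    H:MM:SS timestamp, egg degC, air degC); the labels file is readable by
    :func:`boutseg.trace_io.read_labels`. Returns the two paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trace_path = out_dir / "trace.csv"
    labels_path = out_dir / "labels.csv"
    with open(trace_path, "w", newline="") as fh:
        for i, ts in enumerate(trace.timestamps):
            row = [
                str(i + 1),
                ts.strftime("%m/%d/%Y %H:%M:%S"),
                f"{trace.egg_temp[i]:.3f}",
            ]
            if trace.has_air:
                row.append(f"{trace.air_temp[i]:.3f}")
            fh.write(",".join(row) + "\n")
    with open(labels_path, "w", newline="") as fh:
        for i, s in enumerate(states):
            fh.write(f"{i + 1},{_STATE_NAMES[int(s)]}\n")
    return trace_path, labels_path
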