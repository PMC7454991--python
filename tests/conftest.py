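"""Shared fixtures: small hand-built traces and simulated fixtures."""

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from boutseg import SimConfig, ThermalTrace, simulate_trace


def make_trace(egg, air=None, interval=30.0, start=datetime(2021, 6, 1, 6, 0, 0)):
    """Build a ThermalTrace from plain lists."""
    n = len(egg)
    ts = pd.DatetimeIndex([start + timedelta(seconds=interval * i) for i in range(n)])
    return ThermalTrace(ts, np.asarray(egg, float),
                        np.asarray(air, float) if air is not None else None,
                        interval=interval)


@pytest.fixture
def tiny_trace():
    """5 points, 30-s sampling, with air."""
    return make_trace([37.0, 37.5, 36.8, 35.9, 36.2],
                      air=[20.0, 20.1, 20.2, 20.1, 20.0])


@pytest.fixture(scope="session")
def clear_fixture():
    """24-h clear-preset simulation with ground truth (seed 0)."""
    return simulate_trace(SimConfig(seed=0))


@pytest.fixture
def trace_csv(tmp_path):
    """Write a small valid logger CSV and return its path."""

    def write(rows, name="trace.csv", header=None):
        path = tmp_path / name
        lines = []
        if header:
            lines.append(header)
        for r in rows:
            lines.append(",".join(str(c) for c in r))
        path.write_text("\n".join(lines) + "\n")
        return path

    return write
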