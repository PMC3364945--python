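"""Shared fixtures: default parameter sets and pooled simulation runs.

The pooled runs are session-scoped because several statistical checks share
the same study protocol (20 channels, ip3 = 0.07 uM, fast vs slow microdomain
collapse) and the simulations dominate the suite's runtime.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import puffsim as ps


@pytest.fixture(scope="session")
def gating() -> ps.GatingParameters:
    return ps.GatingParameters()


@pytest.fixture(scope="session")
def domain() -> ps.MicrodomainParameters:
    return ps.MicrodomainParameters()


def pooled_runs(k: float, seeds, duration: float, burn_in: float = 20.0):
    """Simulate independent seeds at collapse rate ``k`` and pool the results."""
    traces = []
    for seed in seeds:
        cfg = ps.SimulationConfig(
            domain=dataclasses.replace(ps.MicrodomainParameters(), k=k),
            duration=duration,
            burn_in=burn_in,
            seed=seed,
        )
        traces.append(ps.simulate(cfg))
    events = [ps.detect_events(tr) for tr in traces]
    return traces, events


def pooled_intervals(events_per_trace):
    """Onset-to-onset IPIs and dormancies pooled across traces."""
    ipis, dorms = [], []
    for events in events_per_trace:
        onsets = np.array([e.t_start for e in events])
        ends = np.array([e.t_end for e in events])
        if len(events) >= 2:
            ipis.extend(np.diff(onsets))
            dorms.extend(onsets[1:] - ends[:-1])
    return np.array(ipis), np.array(dorms)


@pytest.fixture(scope="session")
def puff_runs():
    """Fast-collapse (k = 100 /s) reference runs: 4 seeds x 150 s."""
    return pooled_runs(k=100.0, seeds=(101, 102, 103, 104), duration=150.0)


@pytest.fixture(scope="session")
def wave_runs():
    """Slow-collapse (k = 10 /s) reference runs: 4 seeds x 250 s."""
    return pooled_runs(k=10.0, seeds=(201, 202, 203, 204), duration=250.0)
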