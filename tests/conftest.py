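"""Shared fixtures and the literal brute-force detection oracle.

The oracle re-implements the mini-heatwave detection steps as plain
Python loops, point by point, with no vectorization and no shared code
with the package — it exists to cross-check the production detector.
"""

from __future__ import annotations

import statistics

import numpy as np
import pandas as pd
import pytest

from miniheat import DetectorConfig, IndoorSeries


def bruteforce_detect(times_min, temps, cfg: DetectorConfig):
    """Literal step 1–5 detection; returns [(start_min, end_min), ...]."""
    n = len(temps)
    # step 1: threshold flagging
    cand = [temps[i] >= cfg.temp_threshold for i in range(n)]
    slopes = [None] * n
    for i in range(n - 1):
        slopes[i] = (temps[i + 1] - temps[i]) / (times_min[i + 1] - times_min[i])
    # step 2: rapid-heating inclusion
    for i in range(n - 1):
        if slopes[i] > cfg.slope_in:
            cand[i] = True
    # step 3a: steep-cooling exclusion
    for i in range(n - 1):
        if slopes[i] <= cfg.slope_out:
            cand[i] = False
    # step 3b: sustained-cooling runs, below-threshold points only
    i = 0
    while i < n - 1:
        if temps[i + 1] <= temps[i]:
            j = i
            while j < n - 1 and temps[j + 1] <= temps[j]:
                j += 1
            if times_min[j] - times_min[i] >= cfg.cooling_run:
                for k in range(i, j + 1):
                    if temps[k] < cfg.temp_threshold:
                        cand[k] = False
            i = j
        else:
            i += 1
    # nominal sample step = median spacing
    if n < 2:
        step = 1.0
    else:
        step = statistics.median(
            times_min[i + 1] - times_min[i] for i in range(n - 1)
        )
    # step 4: group candidates, new event when gap > min_gap
    cidx = [i for i in range(n) if cand[i]]
    groups = []
    for i in cidx:
        if groups and times_min[i] - times_min[groups[-1][-1]] <= cfg.min_gap:
            groups[-1].append(i)
        else:
            groups.append([i])
    # step 5: duration filter on right-open [start, last + step)
    events = []
    for grp in groups:
        start = times_min[grp[0]]
        end = times_min[grp[-1]] + step
        if end - start >= cfg.min_duration:
            events.append((start, end))
    return events


def make_indoor(times_min, temps, sensor_id="T01", t0="2023-08-02"):
    """Build an IndoorSeries from minute offsets and temperatures."""
    base = pd.Timestamp(t0)
    idx = pd.DatetimeIndex([base + pd.Timedelta(minutes=float(m)) for m in times_min])
    return IndoorSeries(
        sensor_id=sensor_id,
        data=pd.DataFrame(
            {"temperature": np.asarray(temps, dtype=float),
             "relative_humidity": np.full(len(temps), 50.0)},
            index=idx,
        ),
    )


def random_walk_case(rng: np.random.Generator, max_len=2000):
    """One random 1-min series crossing 26 °C, with occasional data gaps."""
    n = int(rng.integers(50, max_len + 1))
    temps = 26.0 + np.cumsum(rng.normal(0.0, 1.5, size=n))
    times = np.arange(n, dtype=float)
    # sprinkle gaps: delete a few stretches and push later samples out
    n_gaps = int(rng.integers(0, 4))
    for _ in range(n_gaps):
        at = int(rng.integers(1, n))
        times[at:] += float(rng.integers(5, 120))
    return times, temps


def events_in_minutes(events, t0):
    """HeatEvent list -> [(start_min, end_min)] relative to t0."""
    t0 = pd.Timestamp(t0)
    return [
        (
            (ev.start - t0).total_seconds() / 60.0,
            (ev.end - t0).total_seconds() / 60.0,
        )
        for ev in events
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20230802)
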