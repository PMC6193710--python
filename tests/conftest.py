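"""Shared fixtures: tiny hand-built datasets, random stream generators and
independent brute-force oracles for the advisor engine."""

from __future__ import annotations

import numpy as np
import pytest

from alarmlab.core import (
    AlarmEvent,
    AlarmKey,
    Direction,
    MonitoringInterval,
    Parameter,
    Phase,
    PhaseDataset,
    Priority,
    SilenceEvent,
    SilenceLocation,
)

MED_HR_HIGH = AlarmKey(Parameter.HR, Direction.HIGH_LIMIT, Priority.MEDIUM)
MED_RR_LOW = AlarmKey(Parameter.RR, Direction.LOW_LIMIT, Priority.MEDIUM)
MED_SPO2_LOW = AlarmKey(Parameter.SPO2, Direction.LOW_LIMIT, Priority.MEDIUM)
HIGH_HR_HIGH = AlarmKey(Parameter.HR, Direction.HIGH_LIMIT, Priority.HIGH)


def alarm(bed="B1", key=MED_HR_HIGH, start=0.0, end=1.0, phase=Phase.PRE):
    return AlarmEvent(bed, key, start, end, phase)


def silence(bed="B1", key=MED_HR_HIGH, t=0.0, loc=SilenceLocation.BEDSIDE):
    return SilenceEvent(bed, key, t, loc)


def monitoring(bed="B1", parameter=Parameter.HR, start=0.0, end=600.0, phase=Phase.PRE):
    return MonitoringInterval(bed, parameter, start, end, phase)


def dataset(alarms=(), silences=(), mon=(), phase=Phase.PRE):
    return PhaseDataset(phase=phase, alarms=list(alarms),
                        silences=list(silences), monitoring=list(mon))


@pytest.fixture
def tiny_dataset():
    """Three covered alarms on one bed with full monitoring coverage."""
    mon = [monitoring(parameter=p) for p in
           (Parameter.HR, Parameter.RR, Parameter.SPO2)]
    alarms = [
        alarm(start=10, end=12),
        alarm(key=MED_RR_LOW, start=20, end=20.5),
        alarm(key=MED_SPO2_LOW, start=30, end=33),
    ]
    return dataset(alarms, [silence(t=11)], mon)


# ---------------------------------------------------------------------------
# Random streams + brute-force oracle for the advisor engine
# ---------------------------------------------------------------------------

_KEYS = [
    MED_HR_HIGH, MED_RR_LOW, MED_SPO2_LOW, HIGH_HR_HIGH,
    AlarmKey(Parameter.HR, Direction.LOW_LIMIT, Priority.MEDIUM),
    AlarmKey(Parameter.ART_SYS, Direction.HIGH_LIMIT, Priority.MEDIUM),
]


def random_stream(rng: np.random.Generator, max_events: int = 500,
                  horizon: float = 600.0) -> PhaseDataset:
    """A random event stream: bursty silences and alarm episodes over a few
    beds and keys, designed so all trigger rules get exercised."""
    beds = [f"B{i}" for i in range(int(rng.integers(1, 4)))]
    n_alarms = int(rng.integers(0, max_events // 2))
    n_silences = int(rng.integers(0, max_events - n_alarms))
    alarms, silences, mon = [], [], []
    for bed in beds:
        for p in Parameter:
            mon.append(monitoring(bed=bed, parameter=p, end=horizon + 60))
    for _ in range(n_alarms):
        start = float(rng.uniform(0, horizon))
        alarms.append(AlarmEvent(
            beds[int(rng.integers(len(beds)))],
            _KEYS[int(rng.integers(len(_KEYS)))],
            start, start + float(rng.exponential(8.0)) + 1e-3, Phase.PRE))
    # Cluster silences so the count rule can fire
    t = 0.0
    for _ in range(n_silences):
        t = min(t + float(rng.exponential(4.0)), horizon)
        silences.append(SilenceEvent(
            beds[int(rng.integers(len(beds)))],
            _KEYS[int(rng.integers(len(_KEYS)))],
            t,
            SilenceLocation.REMOTE if rng.random() < 0.3 else SilenceLocation.BEDSIDE))
    alarms = [a for a in alarms if a.end <= horizon + 60]
    return dataset(alarms, silences, mon)


def exact_window_coverage(intervals, lo: float, hi: float) -> float:
    """Independent union length on [lo, hi]: elementary-segment midpoint
    membership over all clipped endpoint breakpoints (no interval merging)."""
    pts = {lo, hi}
    for s, e in intervals:
        if e > lo and s < hi:
            pts.add(max(s, lo))
            pts.add(min(e, hi))
    pts = sorted(pts)
    total = 0.0
    for a, b in zip(pts, pts[1:]):
        mid = (a + b) / 2.0
        if any(s <= mid < e for s, e in intervals):
            total += b - a
    return total


def brute_force_advisor(ds: PhaseDataset, cfg) -> list[tuple]:
    """Full-rescan reference implementation of the trigger rules.

    At every silence press it rescans the complete history.  Returns
    (bed, key, time, rule-name, displayed) tuples.
    """
    out = []
    for s in sorted(ds.silences, key=lambda s: (s.time, s.bed_id, s.key, s.location)):
        if s.key.priority == Priority.HIGH:
            continue
        count = sum(
            1 for s2 in ds.silences
            if s2.bed_id == s.bed_id and s2.key == s.key
            and s.time - cfg.window_minutes < s2.time <= s.time
        )
        same = [(a.start, a.end) for a in ds.alarms
                if a.bed_id == s.bed_id and a.key == s.key]
        frac = exact_window_coverage(same, s.time - cfg.window_minutes, s.time) \
            / cfg.window_minutes
        if count >= cfg.silence_count_threshold:
            rule = "SILENCE_COUNT"
        elif frac > cfg.time_fraction_threshold:
            rule = "TIME_FRACTION"
        else:
            continue
        out.append((s.bed_id, s.key, s.time, rule,
                    s.location == SilenceLocation.BEDSIDE))
    return out
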