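"""Alarm-customization alert engine (sliding-window trigger rules).

The engine decides, at each press of the silence control, whether a
customization alert fires.  Two trigger situations exist:

* ``SILENCE_COUNT`` — the same alarm (same parameter, limit direction and
  priority) was silenced at least ``silence_count_threshold`` times within
  the trailing window, the triggering press included.
* ``TIME_FRACTION`` — the alarm limit was violated for strictly more than
  ``time_fraction_threshold`` of the trailing window.

Both rules look back ``window_minutes`` from the press.  Alerts are only
*displayed* at the bedside when the triggering press happened at the
bedside; a remote silence still counts toward the silence tally.  The
engine is a pure detector over medium-priority limit alarms: it never
evaluates high-priority (crisis) keys and never modifies alarm settings.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from enum import Enum

from .core import (
    AlarmEvent,
    AlarmKey,
    PhaseDataset,
    Priority,
    SilenceEvent,
    SilenceLocation,
    clipped_overlap,
)


@dataclass(frozen=True)
class AdvisorConfig:
    """Trigger thresholds; defaults are the deployed study configuration."""

    silence_count_threshold: int = 5
    time_fraction_threshold: float = 0.20
    window_minutes: float = 30.0
    #: Minimum spacing between consecutive alerts for one (bed, key);
    #: 0 disables suppression (every qualifying press re-alerts).
    refractory_minutes: float = 0.0

    def __post_init__(self) -> None:
        if self.silence_count_threshold <= 0:
            raise ValueError("silence_count_threshold must be positive")
        if not 0.0 < self.time_fraction_threshold < 1.0:
            raise ValueError("time_fraction_threshold must lie in (0, 1)")
        if self.window_minutes <= 0:
            raise ValueError("window_minutes must be positive")
        if self.refractory_minutes < 0:
            raise ValueError("refractory_minutes must be >= 0")


class TriggerRule(str, Enum):
    SILENCE_COUNT = "SILENCE_COUNT"
    TIME_FRACTION = "TIME_FRACTION"


@dataclass(frozen=True)
class AdvisorAlert:
    bed_id: str
    key: AlarmKey
    trigger_time: float
    rule: TriggerRule
    window_silence_count: int
    window_alarm_fraction: float
    displayed: bool


def window_silence_count(
    silences: list[SilenceEvent],
    bed_id: str,
    key: AlarmKey,
    t: float,
    cfg: AdvisorConfig,
) -> int:
    """Silences of (bed, key) with time in (t − W, t].

    Bedside and remote presses both count.
    """
    lo = t - cfg.window_minutes
    return sum(
        1
        for s in silences
        if s.bed_id == bed_id and s.key == key and lo < s.time <= t
    )


def window_alarm_fraction(
    alarms: list[AlarmEvent],
    bed_id: str,
    key: AlarmKey,
    t: float,
    cfg: AdvisorConfig,
) -> float:
    """Fraction of [t − W, t] covered by alarm episodes of (bed, key).

    Overlapping episodes are unioned before measuring, so the result
    never exceeds 1.
    """
    lo = t - cfg.window_minutes
    covered = clipped_overlap(
        ((a.start, a.end) for a in alarms if a.bed_id == bed_id and a.key == key),
        lo,
        t,
    )
    return covered / cfg.window_minutes


def evaluate_silence(
    ds: PhaseDataset, s: SilenceEvent, cfg: AdvisorConfig
) -> AdvisorAlert | None:
    """Evaluate both trigger rules at one silence press.

    High-priority keys never alert (the advisor covers warning alarms
    only).  When both rules fire simultaneously the reported rule is
    SILENCE_COUNT.  The time-fraction rule is strict: a window exactly at
    the threshold does not fire.
    """
    if s.key.priority == Priority.HIGH:
        return None
    count = window_silence_count(ds.silences, s.bed_id, s.key, s.time, cfg)
    fraction = window_alarm_fraction(ds.alarms, s.bed_id, s.key, s.time, cfg)
    if count >= cfg.silence_count_threshold:
        rule = TriggerRule.SILENCE_COUNT
    elif fraction > cfg.time_fraction_threshold:
        rule = TriggerRule.TIME_FRACTION
    else:
        return None
    return AdvisorAlert(
        bed_id=s.bed_id,
        key=s.key,
        trigger_time=s.time,
        rule=rule,
        window_silence_count=count,
        window_alarm_fraction=fraction,
        displayed=s.location == SilenceLocation.BEDSIDE,
    )


class _KeyIndex:
    """Per-(bed, key) sorted time indexes for O(log n) window queries."""

    def __init__(self, ds: PhaseDataset):
        self.silence_times: dict[tuple[str, AlarmKey], list[float]] = {}
        self.alarm_intervals: dict[tuple[str, AlarmKey], list[tuple[float, float]]] = {}
        for s in sorted(ds.silences, key=lambda s: s.time):
            self.silence_times.setdefault((s.bed_id, s.key), []).append(s.time)
        for a in sorted(ds.alarms, key=lambda a: a.start):
            self.alarm_intervals.setdefault((a.bed_id, a.key), []).append(
                (a.start, a.end)
            )

    def count(self, bed_id: str, key: AlarmKey, t: float, window: float) -> int:
        times = self.silence_times.get((bed_id, key), [])
        return bisect_right(times, t) - bisect_right(times, t - window)

    def fraction(self, bed_id: str, key: AlarmKey, t: float, window: float) -> float:
        ivs = self.alarm_intervals.get((bed_id, key), [])
        lo = t - window
        # Episodes starting after t cannot overlap [lo, t].
        hi_idx = bisect_left(ivs, (t, float("inf")))
        return clipped_overlap(ivs[:hi_idx], lo, t) / window


def run_advisor(ds: PhaseDataset, cfg: AdvisorConfig | None = None) -> list[AdvisorAlert]:
    """Apply the trigger rules to every silence press, in time order.

    Deterministic: presses are processed sorted by (time, bed, key,
    location); output is sorted by trigger time.  With a nonzero
    refractory period, alerts for one (bed, key) within
    ``refractory_minutes`` of the previous alert are suppressed.
    """
    cfg = cfg or AdvisorConfig()
    index = _KeyIndex(ds)
    last_alert: dict[tuple[str, AlarmKey], float] = {}
    alerts: list[AdvisorAlert] = []
    ordered = sorted(ds.silences, key=lambda s: (s.time, s.bed_id, s.key, s.location))
    for s in ordered:
        if s.key.priority == Priority.HIGH:
            continue
        count = index.count(s.bed_id, s.key, s.time, cfg.window_minutes)
        fraction = index.fraction(s.bed_id, s.key, s.time, cfg.window_minutes)
        if count >= cfg.silence_count_threshold:
            rule = TriggerRule.SILENCE_COUNT
        elif fraction > cfg.time_fraction_threshold:
            rule = TriggerRule.TIME_FRACTION
        else:
            continue
        if cfg.refractory_minutes > 0:
            prev = last_alert.get((s.bed_id, s.key))
            if prev is not None and s.time - prev < cfg.refractory_minutes:
                continue
        last_alert[(s.bed_id, s.key)] = s.time
        alerts.append(
            AdvisorAlert(
                bed_id=s.bed_id,
                key=s.key,
                trigger_time=s.time,
                rule=rule,
                window_silence_count=count,
                window_alarm_fraction=fraction,
                displayed=s.location == SilenceLocation.BEDSIDE,
            )
        )
    return alerts
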