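"""Domain model for physiologic-monitor alarm event logs.

The unit of analysis is a monitored ICU bed.  Three event streams describe
a study phase: limit-violation alarm episodes, presses of the silence
control, and per-bed monitoring coverage intervals (the source of exposure
hours).  All times are minutes since an arbitrary phase-local epoch, and
every interval is half-open ``[start, end)`` so abutting intervals neither
overlap nor leave gaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence


class Parameter(str, Enum):
    """Monitored physiologic parameter with configurable alarm limits."""

    HR = "HR"
    RR = "RR"
    SPO2 = "SPO2"
    ART_SYS = "ART_SYS"
    ART_DIA = "ART_DIA"
    ART_MEAN = "ART_MEAN"
    PVC = "PVC"


#: The three arterial-pressure limits are reported as one "Arterial" group.
ARTERIAL_PARAMETERS = frozenset(
    {Parameter.ART_SYS, Parameter.ART_DIA, Parameter.ART_MEAN}
)

#: Parameters monitored continuously for every bed (standard of care);
#: their coverage intervals define overall bed-hour exposure.
CORE_PARAMETERS = frozenset({Parameter.HR, Parameter.RR, Parameter.SPO2})


class Direction(str, Enum):
    HIGH_LIMIT = "HIGH_LIMIT"
    LOW_LIMIT = "LOW_LIMIT"


class Priority(str, Enum):
    """Alarm priority: MEDIUM ("yellow" warning) or HIGH ("red" crisis)."""

    MEDIUM = "MEDIUM"
    HIGH = "HIGH"


class Phase(str, Enum):
    PRE = "PRE"
    POST = "POST"


class SilenceLocation(str, Enum):
    BEDSIDE = "BEDSIDE"
    REMOTE = "REMOTE"


@dataclass(frozen=True, order=True)
class AlarmKey:
    """Identity of "the same alarm" for advisor counting.

    Two alarms are the same when parameter, limit direction and priority
    all agree.
    """

    parameter: Parameter
    direction: Direction
    priority: Priority


@dataclass(frozen=True)
class AlarmEvent:
    """One limit-violation alarm episode on one bed, interval [start, end)."""

    bed_id: str
    key: AlarmKey
    start: float
    end: float
    phase: Phase

    @property
    def duration_minutes(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class SilenceEvent:
    """One press of the silence control, attributed to an alarm key."""

    bed_id: str
    key: AlarmKey
    time: float
    location: SilenceLocation


@dataclass(frozen=True)
class MonitoringInterval:
    """Interval of active monitoring for one (bed, parameter)."""

    bed_id: str
    parameter: Parameter
    start: float
    end: float
    phase: Phase

    @property
    def hours(self) -> float:
        return (self.end - self.start) / 60.0


@dataclass
class PhaseDataset:
    """All event streams for one study phase."""

    phase: Phase
    alarms: list[AlarmEvent] = field(default_factory=list)
    silences: list[SilenceEvent] = field(default_factory=list)
    monitoring: list[MonitoringInterval] = field(default_factory=list)


@dataclass(frozen=True)
class Violation:
    """One failed invariant, naming the offending record and the rule."""

    rule: str
    record: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.rule}: {self.record}"


# ---------------------------------------------------------------------------
# Interval utilities (shared by validation, the advisor and the metrics)
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of half-open intervals as a sorted list of disjoint intervals.

    Abutting intervals ([0, 5) and [5, 9)) merge into one.
    """
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[float, float]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def union_length(intervals: Iterable[tuple[float, float]]) -> float:
    return sum(e - s for s, e in merge_intervals(intervals))


def clipped_overlap(
    intervals: Iterable[tuple[float, float]], lo: float, hi: float
) -> float:
    """Total length of the union of ``intervals`` clipped to [lo, hi]."""
    return union_length(
        (max(s, lo), min(e, hi)) for s, e in intervals if min(e, hi) > max(s, lo)
    )


def _contained(start: float, end: float, merged: Sequence[tuple[float, float]]) -> bool:
    """Is [start, end) inside the union given as merged disjoint intervals?"""
    for s, e in merged:
        if s <= start and end <= e:
            return True
    return False


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_dataset(ds: PhaseDataset) -> list[Violation]:
    """Check every type invariant; return one Violation per failure.

    Validation reports, it never raises.  An empty list means the dataset
    is well-formed: positive durations, finite times, phase-consistent
    records, non-overlapping monitoring per (bed, parameter), and every
    alarm covered by monitoring of its own bed and parameter.
    """
    violations: list[Violation] = []

    for mi in ds.monitoring:
        if not (math.isfinite(mi.start) and math.isfinite(mi.end)):
            violations.append(Violation("nonfinite time", repr(mi)))
        elif mi.end <= mi.start:
            violations.append(Violation("nonpositive duration", repr(mi)))
        if mi.phase != ds.phase:
            violations.append(Violation("phase mismatch", repr(mi)))

    # Overlap check within each (bed, parameter)
    by_bp: dict[tuple[str, Parameter], list[MonitoringInterval]] = {}
    for mi in ds.monitoring:
        by_bp.setdefault((mi.bed_id, mi.parameter), []).append(mi)
    for ivs in by_bp.values():
        ivs_sorted = sorted(ivs, key=lambda m: m.start)
        for prev, cur in zip(ivs_sorted, ivs_sorted[1:]):
            if cur.start < prev.end:
                violations.append(Violation("overlapping monitoring", repr(cur)))

    coverage = {
        bp: merge_intervals((m.start, m.end) for m in ivs)
        for bp, ivs in by_bp.items()
    }

    for a in ds.alarms:
        if not (math.isfinite(a.start) and math.isfinite(a.end)):
            violations.append(Violation("nonfinite time", repr(a)))
            continue
        if a.end <= a.start:
            violations.append(Violation("nonpositive duration", repr(a)))
        if a.phase != ds.phase:
            violations.append(Violation("phase mismatch", repr(a)))
        merged = coverage.get((a.bed_id, a.key.parameter), [])
        if a.end > a.start and not _contained(a.start, a.end, merged):
            violations.append(Violation("uncovered alarm", repr(a)))

    for s in ds.silences:
        if not math.isfinite(s.time):
            violations.append(Violation("nonfinite time", repr(s)))

    return violations


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Python's built-in ``round`` uses banker's rounding; exposure-weighted
    table cells are reproduced with the conventional half-away rule.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
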