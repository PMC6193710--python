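"""Pre/post alarm-burden metrics: exposure-weighted counts, rates and
frequency-threshold histograms.

The reporting unit is the *bed hour*: one hour of monitored exposure for
one bed.  Because the two study phases have different monitoring hours,
post-phase totals are weighted by the ratio of pre to post exposure so
raw counts become comparable; rates per bed hour divide each phase's
total by its own exposure.  Arterial-pressure rows use arterial-line
hours as exposure, every other row uses overall bed hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    ARTERIAL_PARAMETERS,
    CORE_PARAMETERS,
    AlarmEvent,
    Parameter,
    PhaseDataset,
    Priority,
    merge_intervals,
    round_half_away,
)
from .resampling import BootstrapResult, bootstrap_mean, bootstrap_two_sample_p


class UndefinedExposureError(ValueError):
    """Raised when a rate or weight is requested with zero exposure hours."""


class UndefinedBaselineError(ValueError):
    """Raised when a percent reduction is requested with a zero pre rate."""


@dataclass(frozen=True)
class GroupSpec:
    """A reporting group: which parameters/priorities it counts and which
    exposure (overall vs arterial-line hours) normalizes it."""

    label: str
    parameters: frozenset[Parameter]
    priorities: frozenset[Priority]
    exposure: str  # "overall" | "arterial"


_ALL = frozenset(Parameter) - {Parameter.PVC}
_ADVISOR = CORE_PARAMETERS | ARTERIAL_PARAMETERS
_BOTH = frozenset({Priority.MEDIUM, Priority.HIGH})
_MED = frozenset({Priority.MEDIUM})
_HIGH = frozenset({Priority.HIGH})

#: Standard report rows.  PVC alarms are admitted by the data model but
#: excluded from every group by default (inaudible on the study unit).
STANDARD_GROUPS: dict[str, GroupSpec] = {
    g.label: g
    for g in [
        GroupSpec("All Medium and High Priority", _ALL, _BOTH, "overall"),
        GroupSpec("All High Priority", _ALL, _HIGH, "overall"),
        GroupSpec("All Medium Priority", _ALL, _MED, "overall"),
        GroupSpec("All Alarm Advisor", _ADVISOR, _MED, "overall"),
        GroupSpec("MP Heart Rate", frozenset({Parameter.HR}), _MED, "overall"),
        GroupSpec("MP Respiratory Rate", frozenset({Parameter.RR}), _MED, "overall"),
        GroupSpec("MP SpO2", frozenset({Parameter.SPO2}), _MED, "overall"),
        GroupSpec("MP Arterial", ARTERIAL_PARAMETERS, _MED, "arterial"),
    ]
}

DEFAULT_THRESHOLDS = (1, 10, 20, 30, 40, 50, 60)


def resolve_group(group: str | GroupSpec) -> GroupSpec:
    if isinstance(group, GroupSpec):
        return group
    try:
        return STANDARD_GROUPS[group]
    except KeyError:
        raise KeyError(
            f"unknown group label {group!r}; known: {sorted(STANDARD_GROUPS)}"
        ) from None


def _in_group(a: AlarmEvent, spec: GroupSpec) -> bool:
    return a.key.parameter in spec.parameters and a.key.priority in spec.priorities


def _exposure_intervals(ds: PhaseDataset, exposure: str) -> dict[str, list[tuple[float, float]]]:
    """Per-bed union of monitoring intervals defining one exposure kind.

    Overall exposure unions the standard-of-care parameters (HR/RR/SpO2)
    so concurrently monitored parameters do not triple-count an hour;
    arterial exposure unions the three arterial-pressure channels.
    """
    params = ARTERIAL_PARAMETERS if exposure == "arterial" else CORE_PARAMETERS
    per_bed: dict[str, list[tuple[float, float]]] = {}
    for mi in ds.monitoring:
        if mi.parameter in params:
            per_bed.setdefault(mi.bed_id, []).append((mi.start, mi.end))
    return {bed: merge_intervals(ivs) for bed, ivs in per_bed.items()}


def monitored_hours(ds: PhaseDataset, group: str | GroupSpec = "All Medium and High Priority") -> float:
    """Bed hours of exposure for a reporting group (0 for an empty group)."""
    spec = resolve_group(group)
    per_bed = _exposure_intervals(ds, spec.exposure)
    return sum(e - s for ivs in per_bed.values() for s, e in ivs) / 60.0


def weight_to_reference(value_post: float, hours_ref: float, hours_post: float) -> int:
    """Scale a post-phase total to the reference (pre) exposure.

    Returns ``round_half_away(value_post * hours_ref / hours_post)``;
    applied identically to alarm counts and minutes in alarm.
    """
    if hours_post <= 0:
        raise UndefinedExposureError("post-phase exposure hours must be positive")
    return round_half_away(value_post * hours_ref / hours_post)


def rate_per_bed_hour(total: float, hours: float) -> float:
    """Events (or minutes) per bed hour; displayed at 2 decimals."""
    if hours <= 0:
        raise UndefinedExposureError("exposure hours must be positive")
    return total / hours


def percent_reduction(rate_pre: float, rate_post: float) -> float:
    """100·(pre − post)/pre at full precision; negative means an increase."""
    if rate_pre <= 0:
        raise UndefinedBaselineError("pre-phase rate must be positive")
    return 100.0 * (rate_pre - rate_post) / rate_pre


# ---------------------------------------------------------------------------
# Phase totals and summary rows
# ---------------------------------------------------------------------------

@dataclass
class PhaseTotals:
    """Aggregate raw totals for one phase: per-group alarm counts, minutes
    in alarm, and the two exposure denominators."""

    phase: str
    hours_overall: float
    hours_arterial: float
    counts: dict[str, float] = field(default_factory=dict)
    minutes: dict[str, float] = field(default_factory=dict)

    def hours_for(self, group: str | GroupSpec) -> float:
        spec = resolve_group(group)
        return self.hours_arterial if spec.exposure == "arterial" else self.hours_overall


def phase_totals(ds: PhaseDataset, groups: list[str] | None = None) -> PhaseTotals:
    """Reduce an event-level dataset to per-group totals."""
    labels = groups or list(STANDARD_GROUPS)
    totals = PhaseTotals(
        phase=ds.phase.value,
        hours_overall=monitored_hours(ds, "All Medium and High Priority"),
        hours_arterial=monitored_hours(ds, "MP Arterial"),
    )
    for label in labels:
        spec = resolve_group(label)
        members = [a for a in ds.alarms if _in_group(a, spec)]
        totals.counts[label] = float(len(members))
        totals.minutes[label] = float(sum(a.duration_minutes for a in members))
    return totals


@dataclass
class RateSummaryRow:
    """One row of the pre/post comparison table (counts or durations)."""

    group_label: str
    measure: str  # "count" | "duration"
    count_pre: float
    count_post: float
    hours_pre: float
    hours_post: float
    weighted_pre: int
    weighted_post: int
    rate_pre: float
    rate_post: float
    percent_reduction: float
    boot_pre: BootstrapResult | None = None
    boot_post: BootstrapResult | None = None
    boot_p: float | None = None


def summary_from_totals(
    pre: PhaseTotals, post: PhaseTotals, measure: str = "count",
    groups: list[str] | None = None,
) -> list[RateSummaryRow]:
    """Deterministic table columns from aggregate totals (no bootstrap).

    The pre phase is the reference: its weighted value equals its raw
    total; the post total is scaled by the exposure ratio.  Percent
    reductions are computed from unrounded rates.  A group with zero
    exposure hours (or a zero pre rate) gets NaN rate/reduction cells
    rather than an error, so empty groups stay visible in the report.
    """
    if measure not in ("count", "duration"):
        raise ValueError("measure must be 'count' or 'duration'")
    nan = float("nan")
    labels = groups or list(STANDARD_GROUPS)
    rows = []
    for label in labels:
        tp = (pre.counts if measure == "count" else pre.minutes)[label]
        to = (post.counts if measure == "count" else post.minutes)[label]
        hp, ho = pre.hours_for(label), post.hours_for(label)
        rp = rate_per_bed_hour(tp, hp) if hp > 0 else nan
        ro = rate_per_bed_hour(to, ho) if ho > 0 else nan
        rows.append(
            RateSummaryRow(
                group_label=label,
                measure=measure,
                count_pre=tp,
                count_post=to,
                hours_pre=hp,
                hours_post=ho,
                weighted_pre=round_half_away(tp),
                weighted_post=weight_to_reference(to, hp, ho) if ho > 0 else 0,
                rate_pre=rp,
                rate_post=ro,
                percent_reduction=percent_reduction(rp, ro) if rp > 0 else nan,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Bed-hour discretization (bootstrap resampling unit and histograms)
# ---------------------------------------------------------------------------

def bed_hour_values(
    ds: PhaseDataset,
    group: str | GroupSpec,
    measure: str = "count",
    min_partial_minutes: float = 30.0,
) -> np.ndarray:
    """Per-bed-hour alarm counts (or minutes in alarm), pooled over beds.

    Monitored time is partitioned into clock-aligned whole hours
    ``[60k, 60(k+1))``; an hour only partially covered by monitoring
    counts as an exposed bed hour when the covered part is at least
    ``min_partial_minutes``.  Counts attribute an alarm to the hour of
    its start; minutes split an episode across the hours it overlaps.
    """
    spec = resolve_group(group)
    per_bed = _exposure_intervals(ds, spec.exposure)

    values: list[float] = []
    bins: dict[tuple[str, int], int] = {}
    for bed, ivs in per_bed.items():
        for s, e in ivs:
            k0, k1 = int(np.floor(s / 60.0)), int(np.ceil(e / 60.0))
            for k in range(k0, k1):
                covered = min(e, 60.0 * (k + 1)) - max(s, 60.0 * k)
                if covered >= min_partial_minutes:
                    bins[(bed, k)] = len(values)
                    values.append(0.0)

    for a in ds.alarms:
        if not _in_group(a, spec):
            continue
        if measure == "count":
            idx = bins.get((a.bed_id, int(np.floor(a.start / 60.0))))
            if idx is not None:
                values[idx] += 1.0
        else:
            k0, k1 = int(np.floor(a.start / 60.0)), int(np.ceil(a.end / 60.0))
            for k in range(k0, k1):
                overlap = min(a.end, 60.0 * (k + 1)) - max(a.start, 60.0 * k)
                idx = bins.get((a.bed_id, k))
                if idx is not None and overlap > 0:
                    values[idx] += overlap
    return np.asarray(values, dtype=float)


@dataclass
class ThresholdHistogram:
    """Bed-hours with at least t alarms, per threshold t, pre and post."""

    thresholds: tuple[int, ...]
    counts_pre: list[int]
    counts_post: list[int]


def threshold_counts(
    ds: PhaseDataset,
    group: str | GroupSpec,
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS,
) -> list[int]:
    """Number of exposed bed-hours whose alarm count is ≥ each threshold."""
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    per_hour = bed_hour_values(ds, group, measure="count")
    return [int(np.sum(per_hour >= t)) for t in thresholds]


def threshold_histogram(
    pre: PhaseDataset,
    post: PhaseDataset,
    group: str | GroupSpec,
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS,
) -> ThresholdHistogram:
    return ThresholdHistogram(
        thresholds=tuple(thresholds),
        counts_pre=threshold_counts(pre, group, thresholds),
        counts_post=threshold_counts(post, group, thresholds),
    )


# ---------------------------------------------------------------------------
# Full summary with bootstrap inference
# ---------------------------------------------------------------------------

def summarize(
    pre: PhaseDataset,
    post: PhaseDataset,
    groups: list[str] | None = None,
    measure: str = "count",
    n_iter: int = 10_000,
    seed: int = 0,
) -> list[RateSummaryRow]:
    """Event-level pre/post comparison table with bootstrap inference.

    Deterministic columns come from phase totals; bootstrap means, SDs,
    CIs and two-sided p-values resample per-bed-hour values (counts or
    minutes) pooled across beds within each phase.  ``n_iter=0`` skips
    the bootstrap.
    """
    labels = groups or list(STANDARD_GROUPS)
    rows = summary_from_totals(
        phase_totals(pre, labels), phase_totals(post, labels), measure, labels
    )
    if n_iter <= 0:
        return rows
    rng_seed = np.random.SeedSequence(seed)
    for row, child in zip(rows, rng_seed.spawn(len(rows))):
        s1, s2, s3 = (int(c.generate_state(1)[0] % (2**31)) for c in child.spawn(3))
        a = bed_hour_values(pre, row.group_label, measure)
        b = bed_hour_values(post, row.group_label, measure)
        if len(a) == 0 or len(b) == 0:
            continue
        row.boot_pre = bootstrap_mean(a, n_iter=n_iter, seed=s1)
        row.boot_post = bootstrap_mean(b, n_iter=n_iter, seed=s2)
        row.boot_p = bootstrap_two_sample_p(a, b, n_iter=n_iter, seed=s3)
    return rows
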