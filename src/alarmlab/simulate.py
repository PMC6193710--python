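"""Synthetic alarm-event-stream generator.

Emulates the data-generating process of a two-month ICU monitoring phase
at desk scale: per bed and parameter, alarm episodes arrive as a
homogeneous Poisson process with exponentially distributed durations;
each episode is silenced with a fixed probability at a uniform time
inside the episode, at the bedside or remotely.  Optional gamma bed
frailty (a per-bed rate multiplier with mean 1) produces the heavy
per-bed-hour tails seen on real units, where single bed-hours with 30+
alarms occur.

The intervention's causal path is modelled explicitly: the post phase is
simulated sequentially, and whenever the advisor engine would display an
alert, the bed-parameter's subsequent alarm rate is (with a configured
probability, once per bed and parameter) multiplied by a customization
factor, representing a nurse widening that patient's limits.

Default rates and mean durations are the observed pre-phase per-bed-hour
figures of the study unit; alert-response parameters are free (the study
could not measure how nurses interacted with alerts) and are set to a
regime that yields reductions of the observed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .advisor import AdvisorConfig
from .core import (
    ARTERIAL_PARAMETERS,
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
    clipped_overlap,
)
from .metrics import PhaseTotals
from .survey import LikertResponse

#: Observed pre-phase medium-priority rates (events per bed hour).  The
#: arterial rate is per arterial-line hour.
DEFAULT_MEDIUM_RATES = {
    "HR": 36475 / 36545,      # ≈ 1.00
    "RR": 53404 / 36545,      # ≈ 1.46
    "SPO2": 40034 / 36545,    # ≈ 1.10
    "ART": 9769 / 1822,       # ≈ 5.36
}

#: Observed mean episode durations, minutes (total minutes / count).
DEFAULT_MEAN_DURATIONS = {
    "HR": 103881 / 36475,     # ≈ 2.85
    "RR": 8271 / 53404,       # ≈ 0.155
    "SPO2": 12337 / 40034,    # ≈ 0.308
    "ART": 3545 / 9769,       # ≈ 0.363
}

#: High-priority (crisis) alarms, all parameters pooled.
DEFAULT_HIGH_RATE = 38612 / 36545          # ≈ 1.06 per bed hour
DEFAULT_HIGH_MEAN_DURATION = 5008 / 38612  # ≈ 0.13 min

_GROUP_PARAMS = {
    "HR": (Parameter.HR,),
    "RR": (Parameter.RR,),
    "SPO2": (Parameter.SPO2,),
    "ART": tuple(sorted(ARTERIAL_PARAMETERS)),
}

_DIRECTIONS = {
    Parameter.HR: (Direction.HIGH_LIMIT, Direction.LOW_LIMIT),
    Parameter.RR: (Direction.HIGH_LIMIT, Direction.LOW_LIMIT),
    # The unit configures no high SpO2 limit, so SpO2 alarms are LOW only.
    Parameter.SPO2: (Direction.LOW_LIMIT,),
    Parameter.ART_SYS: (Direction.HIGH_LIMIT, Direction.LOW_LIMIT),
    Parameter.ART_DIA: (Direction.HIGH_LIMIT, Direction.LOW_LIMIT),
    Parameter.ART_MEAN: (Direction.HIGH_LIMIT, Direction.LOW_LIMIT),
}


@dataclass(frozen=True)
class AdvisorEffect:
    """Behavioural response to a displayed alert: with ``adjust_probability``
    the nurse customizes limits, multiplying the bed-parameter's subsequent
    alarm rate by ``rate_multiplier`` (applied once per bed-parameter)."""

    adjust_probability: float = 0.5
    rate_multiplier: float = 0.85

    def __post_init__(self) -> None:
        if not 0.0 <= self.adjust_probability <= 1.0:
            raise ValueError("adjust_probability must lie in [0, 1]")
        if not 0.0 < self.rate_multiplier <= 1.0:
            raise ValueError("rate_multiplier must lie in (0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    beds: int = 56
    phase_hours: float = 36545 / 56  # per bed; unit total ≈ study exposure
    medium_rates: dict = field(default_factory=lambda: dict(DEFAULT_MEDIUM_RATES))
    mean_durations: dict = field(default_factory=lambda: dict(DEFAULT_MEAN_DURATIONS))
    high_rate: float = DEFAULT_HIGH_RATE
    high_mean_duration: float = DEFAULT_HIGH_MEAN_DURATION
    silence_probability: float = 0.8
    remote_silence_fraction: float = 0.3
    advisor_effect: AdvisorEffect = field(default_factory=AdvisorEffect)
    #: Fraction of beds carrying an arterial line (≈ 1822/36545 of bed-hours).
    arterial_line_fraction: float = 0.05
    #: Gamma shape of the per-bed rate multiplier (mean 1); None disables
    #: overdispersion and every bed alarms at exactly the configured rate.
    frailty_shape: float | None = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beds <= 0 or self.phase_hours <= 0:
            raise ValueError("beds and phase_hours must be positive")
        for r in list(self.medium_rates.values()) + [self.high_rate]:
            if r < 0:
                raise ValueError("rates must be non-negative")
        for p in (self.silence_probability, self.remote_silence_fraction,
                  self.arterial_line_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _bed_ids(n: int) -> list[str]:
    return [f"B{i:03d}" for i in range(n)]


def _bed_frailty(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.frailty_shape is None:
        return np.ones(cfg.beds)
    k = cfg.frailty_shape
    return rng.gamma(shape=k, scale=1.0 / k, size=cfg.beds)


def _arterial_beds(cfg: SimulationConfig, rng: np.random.Generator) -> set[str]:
    n_art = int(round(cfg.arterial_line_fraction * cfg.beds))
    ids = _bed_ids(cfg.beds)
    return set(rng.choice(ids, size=n_art, replace=False)) if n_art else set()


def _monitoring(cfg: SimulationConfig, phase: Phase, art_beds: set[str]) -> list[MonitoringInterval]:
    end = cfg.phase_hours * 60.0
    out = []
    for bed in _bed_ids(cfg.beds):
        params = [Parameter.HR, Parameter.RR, Parameter.SPO2]
        if bed in art_beds:
            params += sorted(ARTERIAL_PARAMETERS)
        for p in params:
            out.append(MonitoringInterval(bed, p, 0.0, end, phase))
    return out


def _key(rng: np.random.Generator, parameter: Parameter, priority: Priority) -> AlarmKey:
    dirs = _DIRECTIONS[parameter]
    direction = dirs[0] if len(dirs) == 1 else dirs[int(rng.integers(len(dirs)))]
    return AlarmKey(parameter, direction, priority)


def _maybe_silence(
    rng: np.random.Generator, cfg: SimulationConfig, alarm: AlarmEvent
) -> SilenceEvent | None:
    if rng.random() >= cfg.silence_probability:
        return None
    t = float(rng.uniform(alarm.start, alarm.end))
    loc = (SilenceLocation.REMOTE if rng.random() < cfg.remote_silence_fraction
           else SilenceLocation.BEDSIDE)
    return SilenceEvent(alarm.bed_id, alarm.key, t, loc)


def _stream(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    phase: Phase,
    bed: str,
    group: str,
    base_rate_per_hour: float,
    mean_duration: float,
    priority: Priority,
    end_min: float,
    advisor_cfg: AdvisorConfig | None,
    effect: AdvisorEffect | None,
) -> tuple[list[AlarmEvent], list[SilenceEvent]]:
    """One (bed, parameter-group) episode stream, sequential in time.

    When ``advisor_cfg`` is given, every silence is evaluated against the
    trigger rules on the stream's own history; a displayed alert may
    reduce the subsequent arrival rate (limit customization), once.
    """
    alarms: list[AlarmEvent] = []
    silences: list[SilenceEvent] = []
    params = _GROUP_PARAMS.get(group, None)
    rate = base_rate_per_hour / 60.0  # per minute
    t = 0.0
    adjusted = False
    hist_silences: dict[AlarmKey, list[float]] = {}
    hist_alarms: dict[AlarmKey, list[tuple[float, float]]] = {}
    while rate > 0.0:
        t += rng.exponential(1.0 / rate)
        if t >= end_min:
            break
        parameter = (params[int(rng.integers(len(params)))] if params
                     else (Parameter.HR, Parameter.RR, Parameter.SPO2)[int(rng.integers(3))])
        key = _key(rng, parameter, priority)
        end = min(t + rng.exponential(mean_duration), end_min)
        if end <= t:
            continue
        alarm = AlarmEvent(bed, key, t, end, phase)
        alarms.append(alarm)
        hist_alarms.setdefault(key, []).append((t, end))
        sil = _maybe_silence(rng, cfg, alarm)
        if sil is None:
            continue
        silences.append(sil)
        hist_silences.setdefault(key, []).append(sil.time)
        if advisor_cfg is None or effect is None or adjusted:
            continue
        if key.priority == Priority.HIGH:
            continue
        w = advisor_cfg.window_minutes
        cnt = sum(1 for ts in hist_silences[key] if sil.time - w < ts <= sil.time)
        frac = clipped_overlap(hist_alarms[key], sil.time - w, sil.time) / w
        fired = (cnt >= advisor_cfg.silence_count_threshold
                 or frac > advisor_cfg.time_fraction_threshold)
        displayed = fired and sil.location == SilenceLocation.BEDSIDE
        if displayed and rng.random() < effect.adjust_probability:
            rate *= effect.rate_multiplier
            adjusted = True
    return alarms, silences


def _generate(
    cfg: SimulationConfig,
    phase: Phase,
    advisor_cfg: AdvisorConfig | None,
    seed_offset: int,
) -> PhaseDataset:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, seed_offset]))
    art_beds = _arterial_beds(cfg, rng)
    frailty = _bed_frailty(cfg, rng)
    end_min = cfg.phase_hours * 60.0
    ds = PhaseDataset(phase=phase, monitoring=_monitoring(cfg, phase, art_beds))
    effect = cfg.advisor_effect if advisor_cfg is not None else None
    for bed, f in zip(_bed_ids(cfg.beds), frailty):
        for group, base in cfg.medium_rates.items():
            if group == "ART" and bed not in art_beds:
                continue
            a, s = _stream(
                rng, cfg, phase, bed, group, base * f,
                cfg.mean_durations[group], Priority.MEDIUM, end_min,
                advisor_cfg, effect,
            )
            ds.alarms += a
            ds.silences += s
        if cfg.high_rate > 0:
            a, s = _stream(
                rng, cfg, phase, bed, "CORE_HIGH", cfg.high_rate * f,
                cfg.high_mean_duration, Priority.HIGH, end_min, None, None,
            )
            ds.alarms += a
            ds.silences += s
    ds.alarms.sort(key=lambda a: (a.start, a.bed_id))
    ds.silences.sort(key=lambda s: (s.time, s.bed_id))
    return ds


def generate_phase(cfg: SimulationConfig, phase: Phase = Phase.PRE) -> PhaseDataset:
    """Simulate one phase with no intervention in effect."""
    return _generate(cfg, phase, advisor_cfg=None, seed_offset=0 if phase == Phase.PRE else 1)


def generate_post_with_advisor(
    cfg: SimulationConfig, advisor_cfg: AdvisorConfig | None = None
) -> PhaseDataset:
    """Simulate the post phase with the alert → customization → fewer-alarms
    causal path active."""
    return _generate(cfg, Phase.POST, advisor_cfg or AdvisorConfig(), seed_offset=1)


def generate_study(
    cfg: SimulationConfig, advisor_cfg: AdvisorConfig | None = None
) -> tuple[PhaseDataset, PhaseDataset]:
    """Pre phase without, post phase with, the intervention."""
    return generate_phase(cfg, Phase.PRE), generate_post_with_advisor(cfg, advisor_cfg)


# ---------------------------------------------------------------------------
# Survey generator
# ---------------------------------------------------------------------------

#: Observed endorsement proportions (pre, post) per survey item.
DEFAULT_ENDORSEMENT_PROBS = {
    "too_many_alarms": (0.682, 0.545),
    "overwhelmed": (0.500, 0.477),
    "disturbs_workflow": (0.667, 0.455),
    "time_nonactionable": (0.636, 0.419),
    "adjust_limits": (0.697, 0.659),
    "unanswered_alarm": (0.439, 0.250),
}


def generate_survey(
    n_pre: int = 66,
    n_post: int = 44,
    endorsement_probs: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> list[LikertResponse]:
    """Independent Bernoulli endorsement draws per respondent and item,
    mapped onto a 1–5 scale (endorsed → 4 or 5, otherwise 1–3)."""
    probs = endorsement_probs or DEFAULT_ENDORSEMENT_PROBS
    for item, (p_pre, p_post) in probs.items():
        if not (0.0 <= p_pre <= 1.0 and 0.0 <= p_post <= 1.0):
            raise ValueError(f"endorsement probabilities for {item!r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[LikertResponse] = []
    for phase, n, col in ((Phase.PRE, n_pre, 0), (Phase.POST, n_post, 1)):
        for _ in range(n):
            for item, pp in probs.items():
                if rng.random() < pp[col]:
                    level = 4 + int(rng.integers(2))
                else:
                    level = 1 + int(rng.integers(3))
                out.append(LikertResponse(item, level, phase))
    return out


# ---------------------------------------------------------------------------
# Study-replica totals (printed raw table cells, injected not simulated)
# ---------------------------------------------------------------------------

_REPLICA = {
    # label: (count_pre, count_post, minutes_pre, minutes_post)
    "All Medium and High Priority": (236507, 240242, 300181, 313435),
    "All High Priority": (38612, 39888, 5008, 5273),
    "All Medium Priority": (197895, 200354, 295174, 308162),
    "All Alarm Advisor": (139682, 139153, 128033, 125775),
    "MP Heart Rate": (36475, 34576, 103881, 100138),
    "MP Respiratory Rate": (53404, 49233, 8271, 7493),
    "MP SpO2": (40034, 41722, 12337, 12811),
    "MP Arterial": (9769, 13622, 3545, 5333),
}


def study_replica_fixture() -> tuple[PhaseTotals, PhaseTotals]:
    """Aggregate raw totals of the source unit's two phases.

    Counts, minutes in alarm and exposure hours exactly as observed, for
    exact reproduction of the deterministic pre/post table columns.
    These are injected totals, not simulated events.
    """
    pre = PhaseTotals(phase="PRE", hours_overall=36545.0, hours_arterial=1822.0)
    post = PhaseTotals(phase="POST", hours_overall=38205.0, hours_arterial=3021.0)
    for label, (cp, co, mp, mo) in _REPLICA.items():
        pre.counts[label] = float(cp)
        post.counts[label] = float(co)
        pre.minutes[label] = float(mp)
        post.minutes[label] = float(mo)
    return pre, post


def scaled_config(cfg: SimulationConfig, bed_hours: float) -> SimulationConfig:
    """Same rates, smaller unit: rescale phase_hours to a total exposure."""
    return replace(cfg, phase_hours=bed_hours / cfg.beds)
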