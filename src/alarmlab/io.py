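"""Delimited-text readers/writers for the event-log schemas and the
end-to-end pipeline.

Schema v1 (comma-separated, UTF-8, header row, ``schema_version`` column):

* ``alarms.csv``: bed_id,parameter,direction,priority,start_min,end_min,phase,schema_version
* ``silences.csv``: bed_id,parameter,direction,priority,time_min,location,schema_version
* ``monitoring.csv``: bed_id,parameter,start_min,end_min,phase,schema_version
* ``survey.csv``: respondent_id,item_id,level,phase,schema_version
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .advisor import AdvisorConfig, run_advisor
from .core import (
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
    validate_dataset,
)
from .metrics import (
    DEFAULT_THRESHOLDS,
    RateSummaryRow,
    STANDARD_GROUPS,
    summarize,
    summary_from_totals,
    threshold_histogram,
)
from .survey import LikertResponse, chi_square_2x2, dichotomize

SCHEMA_VERSION = 1

log = logging.getLogger("alarmlab")


class SchemaError(ValueError):
    """A malformed file: the message names file, line and field."""


def _parse_enum(enum_cls, raw: str, path: Path, line: int, fieldname: str):
    try:
        return enum_cls(str(raw).strip().upper())
    except ValueError:
        raise SchemaError(
            f"{path}:{line}: unknown {fieldname} {raw!r} "
            f"(expected one of {[e.value for e in enum_cls]})"
        ) from None


def _parse_float(raw, path: Path, line: int, fieldname: str) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise SchemaError(f"{path}:{line}: {fieldname} {raw!r} is not a number") from None


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def read_dataset(
    alarms_path: str | Path,
    silences_path: str | Path | None,
    monitoring_path: str | Path,
    phase: Phase | None = None,
    validate: bool = True,
) -> PhaseDataset:
    """Parse and validate one phase's event logs.

    ``phase`` may be omitted when the files carry a consistent phase
    column.  Parse errors name the file, line (1-based, header is line 1)
    and field; with ``validate`` on, invariant violations raise too.
    """
    alarms_path = Path(alarms_path)
    monitoring_path = Path(monitoring_path)

    adf = _read_csv(alarms_path, ["bed_id", "parameter", "direction", "priority",
                                  "start_min", "end_min", "phase"])
    alarms = []
    for i, row in enumerate(adf.itertuples(index=False), start=2):
        key = AlarmKey(
            _parse_enum(Parameter, row.parameter, alarms_path, i, "parameter"),
            _parse_enum(Direction, row.direction, alarms_path, i, "direction"),
            _parse_enum(Priority, row.priority, alarms_path, i, "priority"),
        )
        alarms.append(AlarmEvent(
            bed_id=str(row.bed_id),
            key=key,
            start=_parse_float(row.start_min, alarms_path, i, "start_min"),
            end=_parse_float(row.end_min, alarms_path, i, "end_min"),
            phase=_parse_enum(Phase, row.phase, alarms_path, i, "phase"),
        ))

    silences = []
    if silences_path is not None:
        silences_path = Path(silences_path)
        sdf = _read_csv(silences_path, ["bed_id", "parameter", "direction",
                                        "priority", "time_min", "location"])
        for i, row in enumerate(sdf.itertuples(index=False), start=2):
            key = AlarmKey(
                _parse_enum(Parameter, row.parameter, silences_path, i, "parameter"),
                _parse_enum(Direction, row.direction, silences_path, i, "direction"),
                _parse_enum(Priority, row.priority, silences_path, i, "priority"),
            )
            silences.append(SilenceEvent(
                bed_id=str(row.bed_id),
                key=key,
                time=_parse_float(row.time_min, silences_path, i, "time_min"),
                location=_parse_enum(SilenceLocation, row.location, silences_path, i, "location"),
            ))

    mdf = _read_csv(monitoring_path, ["bed_id", "parameter", "start_min", "end_min", "phase"])
    monitoring = []
    for i, row in enumerate(mdf.itertuples(index=False), start=2):
        monitoring.append(MonitoringInterval(
            bed_id=str(row.bed_id),
            parameter=_parse_enum(Parameter, row.parameter, monitoring_path, i, "parameter"),
            start=_parse_float(row.start_min, monitoring_path, i, "start_min"),
            end=_parse_float(row.end_min, monitoring_path, i, "end_min"),
            phase=_parse_enum(Phase, row.phase, monitoring_path, i, "phase"),
        ))

    phases = {a.phase for a in alarms} | {m.phase for m in monitoring}
    if phase is None:
        if len(phases) != 1:
            raise SchemaError(
                f"{alarms_path}: phase not given and files carry {sorted(p.value for p in phases)}"
            )
        phase = phases.pop()
    ds = PhaseDataset(phase=phase, alarms=alarms, silences=silences, monitoring=monitoring)
    if validate:
        violations = validate_dataset(ds)
        if violations:
            head = "; ".join(str(v) for v in violations[:5])
            raise SchemaError(f"dataset failed validation ({len(violations)} violations): {head}")
    return ds


def write_dataset(ds: PhaseDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write alarms/silences/monitoring CSVs; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "alarms": out / "alarms.csv",
        "silences": out / "silences.csv",
        "monitoring": out / "monitoring.csv",
    }
    pd.DataFrame(
        [
            {"bed_id": a.bed_id, "parameter": a.key.parameter.value,
             "direction": a.key.direction.value, "priority": a.key.priority.value,
             "start_min": a.start, "end_min": a.end, "phase": a.phase.value,
             "schema_version": SCHEMA_VERSION}
            for a in ds.alarms
        ],
        columns=["bed_id", "parameter", "direction", "priority", "start_min",
                 "end_min", "phase", "schema_version"],
    ).to_csv(paths["alarms"], index=False)
    pd.DataFrame(
        [
            {"bed_id": s.bed_id, "parameter": s.key.parameter.value,
             "direction": s.key.direction.value, "priority": s.key.priority.value,
             "time_min": s.time, "location": s.location.value,
             "schema_version": SCHEMA_VERSION}
            for s in ds.silences
        ],
        columns=["bed_id", "parameter", "direction", "priority", "time_min",
                 "location", "schema_version"],
    ).to_csv(paths["silences"], index=False)
    pd.DataFrame(
        [
            {"bed_id": m.bed_id, "parameter": m.parameter.value,
             "start_min": m.start, "end_min": m.end, "phase": m.phase.value,
             "schema_version": SCHEMA_VERSION}
            for m in ds.monitoring
        ],
        columns=["bed_id", "parameter", "start_min", "end_min", "phase",
                 "schema_version"],
    ).to_csv(paths["monitoring"], index=False)
    return paths


def read_survey(path: str | Path) -> list[LikertResponse]:
    path = Path(path)
    df = _read_csv(path, ["item_id", "level", "phase"])
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        out.append(LikertResponse(
            item_id=str(row.item_id),
            level=int(_parse_float(row.level, path, i, "level")),
            phase=_parse_enum(Phase, row.phase, path, i, "phase"),
        ))
    return out


def write_survey(responses: list[LikertResponse], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {"respondent_id": "", "item_id": r.item_id, "level": r.level,
             "phase": r.phase.value, "schema_version": SCHEMA_VERSION}
            for r in responses
        ],
        columns=["respondent_id", "item_id", "level", "phase", "schema_version"],
    ).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def rows_to_frame(rows: list[RateSummaryRow]) -> pd.DataFrame:
    """Flatten summary rows to a report table (rates at 2 dp, reductions
    at 1 dp, bootstrap columns blank when not computed)."""
    recs = []
    for r in rows:
        rec = {
            "group": r.group_label,
            "measure": r.measure,
            "raw_pre": r.count_pre,
            "raw_post": r.count_post,
            "hours_pre": r.hours_pre,
            "hours_post": r.hours_post,
            "weighted_pre": r.weighted_pre,
            "weighted_post": r.weighted_post,
            "rate_pre": round(r.rate_pre, 2),
            "rate_post": round(r.rate_post, 2),
            "percent_reduction": round(r.percent_reduction, 1),
        }
        if r.boot_pre is not None:
            rec.update({
                "boot_mean_pre": round(r.boot_pre.mean, 2),
                "boot_sd_pre": round(r.boot_pre.sd_of_mean, 2),
                "boot_ci_pre": f"{r.boot_pre.ci_low:.2f}-{r.boot_pre.ci_high:.2f}",
                "boot_mean_post": round(r.boot_post.mean, 2),
                "boot_sd_post": round(r.boot_post.sd_of_mean, 2),
                "boot_ci_post": f"{r.boot_post.ci_low:.2f}-{r.boot_post.ci_high:.2f}",
                "boot_p": r.boot_p,
            })
        recs.append(rec)
    return pd.DataFrame(recs)


def run_pipeline(
    pre: PhaseDataset,
    post: PhaseDataset,
    out_dir: str | Path,
    advisor_cfg: AdvisorConfig | None = None,
    survey_responses: list[LikertResponse] | None = None,
    n_iter: int = 10_000,
    seed: int = 0,
    histogram_groups: tuple[str, ...] = (
        "All Alarm Advisor", "MP Heart Rate", "MP Respiratory Rate",
        "MP SpO2", "MP Arterial",
    ),
) -> dict[str, Path]:
    """End-to-end report bundle for a pre/post dataset pair.

    Emits count and duration comparison tables, per-group
    frequency-threshold histograms, the advisor alert log for the post
    phase, an optional survey comparison, and a run manifest.  Pure
    function of (inputs, config, seed): re-running is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    advisor_cfg = advisor_cfg or AdvisorConfig()
    paths: dict[str, Path] = {}

    for measure, name in (("count", "alarm_counts"), ("duration", "alarm_durations")):
        log.info("summarizing %s", name)
        rows = summarize(pre, post, measure=measure, n_iter=n_iter, seed=seed)
        paths[name] = out / f"{name}.csv"
        rows_to_frame(rows).to_csv(paths[name], index=False)

    hist_records = []
    for group in histogram_groups:
        h = threshold_histogram(pre, post, group, DEFAULT_THRESHOLDS)
        for t, cp, co in zip(h.thresholds, h.counts_pre, h.counts_post):
            hist_records.append({"group": group, "threshold": t,
                                 "bed_hours_pre": cp, "bed_hours_post": co})
    paths["histograms"] = out / "histograms.csv"
    pd.DataFrame(hist_records).to_csv(paths["histograms"], index=False)

    alerts = run_advisor(post, advisor_cfg)
    paths["alerts"] = out / "alerts.csv"
    pd.DataFrame(
        [
            {"bed_id": al.bed_id, "parameter": al.key.parameter.value,
             "direction": al.key.direction.value, "priority": al.key.priority.value,
             "trigger_time": al.trigger_time, "rule": al.rule.value,
             "window_silence_count": al.window_silence_count,
             "window_alarm_fraction": round(al.window_alarm_fraction, 4),
             "displayed": al.displayed}
            for al in alerts
        ],
        columns=["bed_id", "parameter", "direction", "priority", "trigger_time",
                 "rule", "window_silence_count", "window_alarm_fraction", "displayed"],
    ).to_csv(paths["alerts"], index=False)

    if survey_responses:
        items = sorted({r.item_id for r in survey_responses})
        recs = []
        for item in items:
            table = dichotomize(survey_responses, item, {4, 5})
            try:
                stat, p = chi_square_2x2(table)
            except ValueError:
                stat, p = float("nan"), float("nan")
            n_pre, n_post = table.a + table.b, table.c + table.d
            recs.append({
                "item_id": item,
                "pct_pre": round(100.0 * table.a / n_pre, 1) if n_pre else float("nan"),
                "pct_post": round(100.0 * table.c / n_post, 1) if n_post else float("nan"),
                "n_pre": n_pre, "n_post": n_post,
                "chi_square": round(stat, 3), "p": round(p, 3),
            })
        paths["survey"] = out / "survey_comparison.csv"
        pd.DataFrame(recs).to_csv(paths["survey"], index=False)

    from . import __version__

    manifest = {
        "package_version": __version__,
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "bootstrap_iterations": n_iter,
        "advisor_config": dataclasses.asdict(advisor_cfg),
        "groups": list(STANDARD_GROUPS),
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def advisor_config_from_mapping(mapping: dict) -> AdvisorConfig:
    known = {f.name for f in dataclasses.fields(AdvisorConfig)}
    unknown = set(mapping) - known
    if unknown:
        raise SchemaError(f"unknown advisor config keys: {sorted(unknown)}")
    return AdvisorConfig(**mapping)
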