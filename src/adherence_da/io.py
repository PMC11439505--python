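"""Play-log CSV readers/writers, run configuration and provenance.

The interchange format is a flat CSV with one row per participant-day:

    participant_id, study_id, day_index, duration_min, sessions, max_level, tasks

(schema version 1).  Days are 1-based and consecutive per participant; a
calendar gap in ``day_index`` is zero-filled on read and recorded in the
log's ``gap_days``, because a day without play is an informative
non-adherent day, not missing data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import DayRecord, ParticipantLog
from .errors import ConfigurationError, SchemaError, ValidationError

log = logging.getLogger(__name__)

__all__ = ["SCHEMA_COLUMNS", "RunConfig", "write_play_log", "read_play_log",
           "load_config", "write_provenance"]

SCHEMA_VERSION = 1
SCHEMA_COLUMNS = ("participant_id", "study_id", "day_index", "duration_min",
                  "sessions", "max_level", "tasks")


def write_play_log(logs: list[ParticipantLog], path: str | Path) -> Path:
    """Write a cohort to the schema-v1 CSV."""
    rows = []
    for lg in logs:
        for d in lg.days:
            rows.append((lg.participant_id, lg.study_id, d.day_index,
                         d.duration, d.sessions, d.max_level, d.tasks))
    df = pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS))
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_play_log(path: str | Path) -> list[ParticipantLog]:
    """Read a play-log CSV; zero-fill day gaps; reject malformed rows.

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` (with row numbers) for negative or
    non-numeric values.
    """
    df = pd.read_csv(path)
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    numeric = ("day_index", "duration_min", "sessions", "max_level", "tasks")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            # +2: 1-based line numbers plus the header line
            raise ValidationError(
                f"{path}: non-numeric {col!r} at line(s) {[int(i) + 2 for i in bad[:5]]}")
        df[col] = coerced
        neg = df.index[df[col] < 0]
        if len(neg):
            raise ValidationError(
                f"{path}: negative {col!r} at line(s) {[int(i) + 2 for i in neg[:5]]}")

    logs = []
    for (pid, sid), grp in df.groupby(["participant_id", "study_id"], sort=True):
        grp = grp.sort_values("day_index")
        if grp["day_index"].duplicated().any():
            raise ValidationError(f"{path}: duplicate day_index for participant {pid!r}")
        by_day = {int(r.day_index): r for r in grp.itertuples()}
        last = max(by_day)
        days, gaps = [], []
        for day in range(1, last + 1):
            if day in by_day:
                r = by_day[day]
                days.append(DayRecord(day, float(r.duration_min), int(r.sessions),
                                      int(r.max_level), int(r.tasks)))
            else:
                days.append(DayRecord(day, 0.0, 0, 0, 0))
                gaps.append(day)
        if gaps:
            log.warning("participant %s: zero-filled %d missing day(s) %s",
                        pid, len(gaps), gaps[:10])
        logs.append(ParticipantLog(str(pid), str(sid), days, gap_days=gaps))
    return logs


@dataclass
class RunConfig:
    """Resolved configuration of a full pipeline run.

    Defaults mirror the study protocol: 10-minute adherence threshold,
    30/30 chronological split, window size 7 (the dominant weekly period),
    K=4 clusters.
    """

    cohort: str | None = None
    cohort2: str | None = None
    threshold_minutes: float = 10.0
    train_days: int = 30
    test_days: int = 30
    window_size: int = 7
    fallback_window: int = 7
    K: int = 4
    extractor: str = "flatten-pca"
    gaf_span: str = "full"
    protocol: str = "within_study"
    seed: int = 0
    output_dir: str = "runs"
    model: dict = field(default_factory=dict)   # CNNConfig overrides
    dann: dict = field(default_factory=dict)    # DANNConfig overrides


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run config; unknown keys are an error."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigurationError(f"{path}: unknown config keys {unknown}")
    cfg = RunConfig(**raw)
    for p in (cfg.cohort, cfg.cohort2):
        if p is not None and not Path(p).exists():
            raise ConfigurationError(f"{path}: referenced file {p!r} does not exist")
    return cfg


def write_provenance(run_dir: str | Path, config: RunConfig | dict,
                     seeds: dict[str, int] | None = None) -> Path:
    """Echo the fully resolved config, seeds and package version into the
    run directory so outputs are bit-reproducible on the same platform."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "package_version": __version__,
        "schema_version": SCHEMA_VERSION,
        "config": dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config),
        "seeds": seeds or {},
    }
    out = run_dir / "provenance.json"
    out.write_text(json.dumps(record, indent=2, sort_keys=True))
    return out
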