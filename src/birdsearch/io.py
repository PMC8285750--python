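"""Configuration loading and session-log serialization.

Configs and session headers are JSON; event and hand-trace tables are CSV —
human-diffable and toolchain-neutral.  Floats are written with Python's
shortest round-trip representation, so logs are byte-stable under a fixed
seed and read back exactly.  Every run manifest embeds the package version,
a hash of the resolved config, and the master seed.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .difficulty import DifficultyTable, default_table
from .simulator import (
    AgentProfile,
    CohortSpec,
    HandTrace,
    RoundRecord,
    SessionRecord,
    TargetEvent,
    TaskConfig,
    elderly_cohort,
    neglect_cohort,
    young_cohort,
)

EVENT_COLUMNS = [
    "participant_id", "cohort", "round", "level", "spawn_time_s",
    "azimuth_deg", "elevation_deg", "direction", "speed_deg_s",
    "lifetime_s", "hemispace", "found", "search_time_s",
]
TRACE_COLUMNS = ["t_s", "x_m", "y_m"]

_COHORT_PRESETS = {
    "young": young_cohort,
    "elderly": elderly_cohort,
    "neglect": neglect_cohort,
}

_AGENT_KEYS = {f.name for f in dataclasses.fields(AgentProfile)}
_CONFIG_KEYS = {f.name for f in dataclasses.fields(TaskConfig)}
_COHORT_KEYS = {"label", "n", "agent", "lateral_bias_range", "total_targets"} | _CONFIG_KEYS
_RUN_KEYS = {"cohorts", "difficulty_table", "plateau_tolerance", "plots"}


@dataclass(frozen=True)
class RunConfig:
    """Validated top-level configuration for a simulation run."""

    cohorts: tuple[CohortSpec, ...]
    table: DifficultyTable = field(default_factory=default_table)
    plateau_tolerance: int = 1
    plots: bool = False

    def to_dict(self) -> dict:
        return {
            "cohorts": [_cohort_to_dict(c) for c in self.cohorts],
            "difficulty_table": self.table.to_dict(),
            "plateau_tolerance": self.plateau_tolerance,
            "plots": self.plots,
        }

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _cohort_to_dict(c: CohortSpec) -> dict:
    d = {"label": c.label, "n": c.n, "agent": dataclasses.asdict(c.agent)}
    d.update(dataclasses.asdict(c.config))
    if c.lateral_bias_range is not None:
        d["lateral_bias_range"] = list(c.lateral_bias_range)
    if c.total_targets is not None:
        d["total_targets"] = c.total_targets
    return d


def _parse_cohort(d: dict) -> CohortSpec:
    unknown = set(d) - _COHORT_KEYS
    if unknown:
        raise ValueError(f"unknown cohort config key(s): {sorted(unknown)}")
    if "label" not in d or "n" not in d:
        raise ValueError("cohort config requires 'label' and 'n'")
    preset = _COHORT_PRESETS.get(d["label"])
    base = preset(n=d["n"]) if preset else CohortSpec(label=d["label"], n=d["n"])
    agent = dataclasses.replace(base.agent, **d.get("agent", {}))
    cfg_over = {k: d[k] for k in _CONFIG_KEYS if k in d}
    config = dataclasses.replace(base.config, **cfg_over)
    lbr = d.get("lateral_bias_range", base.lateral_bias_range)
    if lbr is not None:
        lbr = (float(lbr[0]), float(lbr[1]))
    return CohortSpec(
        label=d["label"], n=int(d["n"]), agent=agent, config=config,
        lateral_bias_range=lbr,
        total_targets=d.get("total_targets", base.total_targets),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run config, rejecting unknown keys."""
    raw = json.loads(Path(path).read_text())
    unknown = set(raw) - _RUN_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "cohorts" not in raw or not raw["cohorts"]:
        raise ValueError("config requires a non-empty 'cohorts' list")
    table = (DifficultyTable.from_dict(raw["difficulty_table"])
             if "difficulty_table" in raw else default_table())
    return RunConfig(
        cohorts=tuple(_parse_cohort(c) for c in raw["cohorts"]),
        table=table,
        plateau_tolerance=int(raw.get("plateau_tolerance", 1)),
        plots=bool(raw.get("plots", False)),
    )


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_session(session: SessionRecord, out_dir: str | Path) -> Path:
    """Write a session as ``<pid>.json`` + ``<pid>_events.csv``
    (+ ``<pid>_trace.csv`` when a hand trace exists).  Returns the header
    path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pid = session.participant_id
    header = {
        "package_version": __version__,
        "participant_id": pid,
        "cohort": session.cohort,
        "seed": session.seed,
        "agent": dataclasses.asdict(session.agent),
        "config": dataclasses.asdict(session.config),
        "metadata": session.metadata,
        "n_rounds_played": len(session.rounds),
    }
    header_path = out / f"{pid}.json"
    header_path.write_text(json.dumps(header, indent=2, sort_keys=True) + "\n")

    with open(out / f"{pid}_events.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(EVENT_COLUMNS)
        for ev in session.iter_events():
            w.writerow([
                pid, session.cohort, ev.round_index, ev.level,
                _fmt(ev.spawn_time), _fmt(ev.azimuth), _fmt(ev.elevation),
                ev.direction, _fmt(ev.speed), _fmt(ev.lifetime),
                ev.hemispace, _fmt(ev.found), _fmt(ev.search_time),
            ])

    if session.hand_trace is not None and len(session.hand_trace):
        with open(out / f"{pid}_trace.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(TRACE_COLUMNS)
            tr = session.hand_trace
            for t, x, y in zip(tr.t, tr.x, tr.y):
                w.writerow([_fmt(float(t)), _fmt(float(x)), _fmt(float(y))])
    return header_path


def read_session(out_dir: str | Path, participant_id: str) -> SessionRecord:
    """Read a session written by :func:`write_session`."""
    out = Path(out_dir)
    header = json.loads((out / f"{participant_id}.json").read_text())
    if header["participant_id"] != participant_id:
        raise ValueError(
            f"header participant_id {header['participant_id']!r} does not "
            f"match requested {participant_id!r}"
        )
    config = TaskConfig(**header["config"])
    agent = AgentProfile(**header["agent"])

    events_path = out / f"{participant_id}_events.csv"
    rounds: dict[int, RoundRecord] = {}
    with open(events_path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            cols = next(reader)
        except StopIteration:
            raise ValueError(f"{events_path}: empty events file") from None
        if cols != EVENT_COLUMNS:
            raise ValueError(f"{events_path}: unexpected header {cols}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(EVENT_COLUMNS):
                raise ValueError(
                    f"{events_path}:{lineno}: expected {len(EVENT_COLUMNS)} "
                    f"fields, got {len(row)}"
                )
            rec = dict(zip(EVENT_COLUMNS, row))
            if rec["participant_id"] != participant_id:
                raise ValueError(
                    f"{events_path}:{lineno}: participant_id "
                    f"{rec['participant_id']!r} does not match header"
                )
            try:
                ev = TargetEvent(
                    round_index=int(rec["round"]),
                    level=int(rec["level"]),
                    spawn_time=float(rec["spawn_time_s"]),
                    azimuth=float(rec["azimuth_deg"]),
                    elevation=float(rec["elevation_deg"]),
                    direction=int(rec["direction"]),
                    speed=float(rec["speed_deg_s"]),
                    lifetime=float(rec["lifetime_s"]),
                    found=rec["found"] == "1",
                    search_time=(float(rec["search_time_s"])
                                 if rec["search_time_s"] else None),
                )
            except ValueError as exc:
                raise ValueError(f"{events_path}:{lineno}: {exc}") from None
            rounds.setdefault(ev.round_index, RoundRecord(level=ev.level, events=[]))
            rounds[ev.round_index].events.append(ev)

    trace = None
    trace_path = out / f"{participant_id}_trace.csv"
    if trace_path.exists():
        t, x, y = [], [], []
        with open(trace_path, newline="") as fh:
            reader = csv.reader(fh)
            cols = next(reader)
            if cols != TRACE_COLUMNS:
                raise ValueError(f"{trace_path}: unexpected header {cols}")
            for lineno, row in enumerate(reader, start=2):
                if len(row) != 3:
                    raise ValueError(f"{trace_path}:{lineno}: expected 3 fields")
                t.append(float(row[0])); x.append(float(row[1])); y.append(float(row[2]))
        trace = HandTrace(t=np.array(t), x=np.array(x), y=np.array(y))

    return SessionRecord(
        participant_id=participant_id,
        cohort=header["cohort"],
        agent=agent,
        config=config,
        rounds=[rounds[k] for k in sorted(rounds)],
        hand_trace=trace,
        seed=header["seed"],
        metadata=header.get("metadata", {}),
    )


def list_sessions(out_dir: str | Path) -> list[str]:
    """Participant ids of all sessions stored in a directory."""
    out = Path(out_dir)
    return sorted(
        p.stem for p in out.glob("*.json")
        if p.stem != "run_manifest" and (out / f"{p.stem}_events.csv").exists()
    )
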