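"""Serialization: TIFF stacks with JSON sidecars, trial logs as CSV/JSON, YAML configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .agent import SensorEvent
from .engine import ExperimentRecord, Session, Trial
from .ois import ImageStack, ResponseMap

EVENT_SEP = ">"
TIME_SEP = ";"


# ---------------------------------------------------------------- imaging ---

def write_stack(
    path: str | Path,
    stack: ImageStack,
    truth: Optional[np.ndarray] = None,
    config: Optional[object] = None,
) -> Path:
    """Write a stack as multi-frame 32-bit TIFF with a JSON sidecar.

    The sidecar carries the frame rate, an echo of the generating config (if
    any) and the path of the ground-truth amplitude map, itself stored as a
    single-frame float TIFF next to the stack.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data.astype(np.float32))
    sidecar = {"frame_rate": stack.frame_rate}
    if config is not None:
        sidecar["config"] = dataclasses.asdict(config)
    if truth is not None:
        truth_path = path.with_name(path.stem + "_truth.tif")
        tifffile.imwrite(truth_path, np.asarray(truth, dtype=np.float32))
        sidecar["truth_path"] = truth_path.name
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=list))
    return path


def read_stack(path: str | Path) -> tuple[ImageStack, Optional[np.ndarray]]:
    """Read a stack written by :func:`write_stack`; returns (stack, truth or None)."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    data = tifffile.imread(path).astype(float)
    truth = None
    if "truth_path" in sidecar:
        truth = tifffile.imread(path.with_name(sidecar["truth_path"])).astype(float)
    return ImageStack(data, float(sidecar["frame_rate"])), truth


def write_response_map(path: str | Path, response: ResponseMap) -> Path:
    """Magnitude and phase as float TIFFs plus a JSON summary."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, response.magnitude.astype(np.float32))
    tifffile.imwrite(path.with_name(path.stem + "_phase.tif"),
                     response.phase.astype(np.float32))
    meta = {"stim_frequency": response.stim_frequency, "bin_factor": response.bin_factor}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


# ------------------------------------------------------------- behavioral ---

def records_to_frame(records: list[ExperimentRecord]) -> pd.DataFrame:
    """Flatten experiment records to one tidy row per trial."""
    rows = []
    for rec in records:
        for session in rec.sessions:
            for i, trial in enumerate(session.trials, start=1):
                rows.append(
                    {
                        "mouse_id": rec.mouse_id,
                        "genotype": rec.genotype,
                        "session": session.session_index,
                        "trial_index": i,
                        "distance_cm": trial.distance,
                        "outcome": trial.outcome,
                        "reward": trial.reward_delivered,
                        "event_sequence": EVENT_SEP.join(
                            str(ev.sensor_id) for ev in trial.events
                        ),
                        "timestamps": TIME_SEP.join(
                            f"{ev.timestamp:.6f}" for ev in trial.events
                        ),
                        "session_termination": session.termination,
                    }
                )
    return pd.DataFrame(rows)


def frame_to_records(trials: pd.DataFrame) -> list[ExperimentRecord]:
    """Rebuild experiment records from a tidy trial log."""
    records = []
    for (mouse, genotype), mouse_df in trials.groupby(["mouse_id", "genotype"], sort=False):
        sessions = []
        for session_index, sess_df in mouse_df.groupby("session", sort=True):
            sess_df = sess_df.sort_values("trial_index")
            trial_objs = []
            for _, row in sess_df.iterrows():
                ids = [int(s) for s in str(row["event_sequence"]).split(EVENT_SEP)]
                times = [float(s) for s in str(row["timestamps"]).split(TIME_SEP)]
                events = tuple(SensorEvent(i, t) for i, t in zip(ids, times))
                trial_objs.append(
                    Trial(
                        distance=float(row["distance_cm"]),
                        outcome=str(row["outcome"]),
                        events=events,
                        reward_delivered=str(row["outcome"]) == "success",
                    )
                )
            crossed = [t.distance for t in trial_objs if t.outcome == "success"]
            sessions.append(
                Session(
                    trials=trial_objs,
                    termination=str(sess_df["session_termination"].iloc[0]),
                    max_distance_crossed=max(crossed) if crossed else None,
                    session_index=int(session_index),
                )
            )
        records.append(ExperimentRecord(mouse_id=str(mouse), genotype=str(genotype),
                                        sessions=sessions))
    return records


def write_trials_csv(path: str | Path, trials: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, index=False)
    return path


def read_trials_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"mouse_id": str, "genotype": str, "event_sequence": str, "timestamps": str},
    )
    df["session"] = df["session"].astype(int)
    df["trial_index"] = df["trial_index"].astype(int)
    df["distance_cm"] = df["distance_cm"].astype(float)
    return df


def write_records_json(path: str | Path, records: list[ExperimentRecord]) -> Path:
    """Nested mouse -> session -> trial JSON serialization."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = [
        {
            "mouse_id": rec.mouse_id,
            "genotype": rec.genotype,
            "sessions": [
                {
                    "session_index": s.session_index,
                    "termination": s.termination,
                    "max_distance_crossed": s.max_distance_crossed,
                    "trials": [
                        {
                            "distance_cm": t.distance,
                            "outcome": t.outcome,
                            "reward_delivered": t.reward_delivered,
                            "events": [[ev.sensor_id, ev.timestamp] for ev in t.events],
                        }
                        for t in s.trials
                    ],
                }
                for s in rec.sessions
            ],
        }
        for rec in records
    ]
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_records_json(path: str | Path) -> list[ExperimentRecord]:
    payload = json.loads(Path(path).read_text())
    records = []
    for rec in payload:
        sessions = []
        for s in rec["sessions"]:
            trials = [
                Trial(
                    distance=float(t["distance_cm"]),
                    outcome=t["outcome"],
                    events=tuple(SensorEvent(int(i), float(ts)) for i, ts in t["events"]),
                    reward_delivered=bool(t["reward_delivered"]),
                )
                for t in s["trials"]
            ]
            sessions.append(
                Session(
                    trials=trials,
                    termination=s["termination"],
                    max_distance_crossed=s["max_distance_crossed"],
                    session_index=int(s["session_index"]),
                )
            )
        records.append(
            ExperimentRecord(mouse_id=rec["mouse_id"], genotype=rec["genotype"],
                             sessions=sessions)
        )
    return records


def validate_trial_log(trials: pd.DataFrame) -> None:
    """Replay-validate a trial log: re-classify events, check rewards/accounting.

    Raises ``ValueError`` on the first inconsistency (outcome disagreeing
    with its sensor trace, reward without success, duplicate trial keys).
    """
    from .engine import classify_trial

    dup = trials.duplicated(subset=["mouse_id", "session", "trial_index"])
    if dup.any():
        raise ValueError("duplicate (mouse, session, trial_index) rows in log")
    for idx, row in trials.iterrows():
        ids = [int(s) for s in str(row["event_sequence"]).split(EVENT_SEP)]
        times = [float(s) for s in str(row["timestamps"]).split(TIME_SEP)]
        events = [SensorEvent(i, t) for i, t in zip(ids, times)]
        outcome = classify_trial(events)
        if outcome != row["outcome"]:
            raise ValueError(
                f"row {idx}: recorded outcome {row['outcome']!r} but events "
                f"{ids} classify as {outcome!r}"
            )
        if "reward" in trials.columns and bool(row["reward"]) != (outcome == "success"):
            raise ValueError(f"row {idx}: reward flag inconsistent with outcome")


# ----------------------------------------------------------------- configs ---

def _yamlable(value):
    if isinstance(value, tuple):
        return [_yamlable(v) for v in value]
    if isinstance(value, dict):
        return {k: _yamlable(v) for k, v in value.items()}
    return value


def save_config_yaml(path: str | Path, config: object) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(_yamlable(dataclasses.asdict(config)), sort_keys=False))
    return path


def load_config_yaml(path: str | Path, cls: type) -> object:
    data = yaml.safe_load(Path(path).read_text())
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields in YAML: {sorted(unknown)}")
    for f in dataclasses.fields(cls):
        if f.name in data and isinstance(data[f.name], list):
            data[f.name] = tuple(data[f.name])
    return cls(**data)
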