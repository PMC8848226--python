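"""File formats: IMU CSV, trajectory CSV, session-log JSON, questionnaire CSV.

All formats are plain text: comma-separated, UTF-8, '.' decimal.  The
IMU dialect carries one sample per row as
``t,gx,gy,gz,ax,ay,az,mx,my,mz`` (seconds, deg/s, g, normalised field);
ground-truth head angles travel as ``t,alpha,rot,incl`` (degrees);
session logs are JSON with an optional ``t,x,y`` trajectory CSV next to
them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .engine import GameConfig, SessionLog, TargetOutcome, TargetSpec
from .fusion import ImuStream
from .mapping import CursorPosition, MappingConfig
from .questionnaires import (MmseRecord, NdiResponse, SeqResponse,
                             mmse_classify, score_ndi, score_seq, validate_vas)

__all__ = [
    "IMU_COLUMNS",
    "write_imu_csv",
    "read_imu_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_angles_csv",
    "read_angles_csv",
    "write_session_log",
    "read_session_log",
    "game_config_from_dict",
    "score_questionnaire_csv",
    "read_session_scores_csv",
    "write_session_scores_csv",
]

IMU_COLUMNS = ["t", "gx", "gy", "gz", "ax", "ay", "az", "mx", "my", "mz"]


def write_imu_csv(stream: ImuStream, path) -> None:
    rows = [
        [s.t, *s.gyro, *s.accel, *s.mag]
        for s in stream
    ]
    pd.DataFrame(rows, columns=IMU_COLUMNS).to_csv(path, index=False)


def read_imu_csv(path) -> ImuStream:
    df = pd.read_csv(path)
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"IMU CSV is missing columns: {missing}")
    return ImuStream.from_arrays(
        df["t"].to_numpy(float),
        df[["gx", "gy", "gz"]].to_numpy(float),
        df[["ax", "ay", "az"]].to_numpy(float),
        df[["mx", "my", "mz"]].to_numpy(float),
    )


def write_trajectory_csv(trajectory: Sequence[tuple[float, float, float]], path) -> None:
    pd.DataFrame(trajectory, columns=["t", "x", "y"]).to_csv(path, index=False)


def read_trajectory_csv(path) -> list[tuple[float, float, float]]:
    df = pd.read_csv(path)
    return [tuple(r) for r in df[["t", "x", "y"]].to_numpy(float)]


def write_angles_csv(trajectory, path) -> None:
    """Ground-truth Euler angles as ``t,alpha,rot,incl`` (degrees)."""
    rows = [(t, e.alpha, e.rot, e.incl) for t, e in trajectory]
    pd.DataFrame(rows, columns=["t", "alpha", "rot", "incl"]).to_csv(path, index=False)


def read_angles_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("t", "alpha", "rot", "incl") if c not in df.columns]
    if missing:
        raise ValueError(f"angle CSV is missing columns: {missing}")
    return df


def game_config_from_dict(d: dict) -> GameConfig:
    d = dict(d)
    mapping = d.pop("mapping", None)
    if mapping is not None and not isinstance(mapping, MappingConfig):
        mapping = MappingConfig(**mapping)
    known = set(GameConfig.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown GameConfig keys: {sorted(unknown)}")
    if mapping is not None:
        d["mapping"] = mapping
    return GameConfig(**d)


def write_session_log(log: SessionLog, path, trajectory_csv=None) -> None:
    Path(path).write_text(log.to_json())
    if trajectory_csv is not None:
        write_trajectory_csv(log.trajectory, trajectory_csv)


def read_session_log(path, trajectory_csv=None) -> SessionLog:
    payload = json.loads(Path(path).read_text())
    cfg = game_config_from_dict(payload["config"])
    targets = [
        TargetSpec(index=t["index"],
                   position=CursorPosition(**t["position"]),
                   spawn_t=t["spawn_t"], deadline_t=t["deadline_t"])
        for t in payload["targets"]
    ]
    outcomes = [TargetOutcome(**o) for o in payload["outcomes"]]
    trajectory = read_trajectory_csv(trajectory_csv) if trajectory_csv else []
    return SessionLog(config=cfg, targets=targets, trajectory=trajectory,
                      outcomes=outcomes)


def score_questionnaire_csv(path) -> list[dict]:
    """Score a mixed questionnaire sheet.

    One row per respondent: ``subject,instrument,item1..itemN`` with
    N = 13 for SEQ and 10 for NDI; MMSE rows carry
    ``subject,instrument,score,age,education``; VAS rows carry
    ``subject,instrument,value``.
    """
    df = pd.read_csv(path)
    if "instrument" not in df.columns or "subject" not in df.columns:
        raise ValueError("questionnaire CSV needs 'subject' and 'instrument' columns")
    out: list[dict] = []
    for _, row in df.iterrows():
        inst = str(row["instrument"]).lower()
        rec: dict = {"subject": row["subject"], "instrument": inst}
        if inst == "seq":
            items = [row[f"item{i}"] for i in range(1, 14)]
            rec["score"] = score_seq(SeqResponse(items))
        elif inst == "ndi":
            items = [row[f"item{i}"] for i in range(1, 11)]
            rec.update(score_ndi(NdiResponse(items)))
        elif inst == "mmse":
            res = mmse_classify(
                MmseRecord(int(row["score"]), float(row["age"]),
                           str(row.get("education", "standard")))
            )
            rec.update(res)
            rec["score"] = int(row["score"])
        elif inst == "vas":
            v = validate_vas(float(row["value"]))
            rec["value"] = v.value
            rec["poor_control"] = v.poor_control
        else:
            raise ValueError(f"unknown instrument {inst!r}")
        out.append(rec)
    return out


def write_session_scores_csv(scores: dict[str, Sequence[float]], path) -> None:
    """Per-subject session scores as ``subject,s1..sK``."""
    n = {len(v) for v in scores.values()}
    if len(n) != 1:
        raise ValueError("all subjects must have the same number of sessions")
    k = n.pop()
    rows = [{"subject": s, **{f"s{i+1}": v[i] for i in range(k)}}
            for s, v in scores.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_session_scores_csv(path) -> pd.DataFrame:
    """Session scores as a subjects × sessions DataFrame (index = subject)."""
    df = pd.read_csv(path)
    if "subject" not in df.columns:
        raise ValueError("session-score CSV needs a 'subject' column")
    cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    if not cols:
        raise ValueError("session-score CSV needs s1..sK columns")
    cols = sorted(cols, key=lambda c: int(c[1:]))
    out = df.set_index("subject")[cols]
    return out.astype(float)
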