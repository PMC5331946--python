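"""File round-tripping: CSV tables with JSON sidecars, YAML/JSON run configs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .schedule import ScheduleConfig, TaskSchedule, TimingConfig, TrialTiming
from .simulate import BehavioralSession, BoldSeries

__all__ = [
    "write_session", "read_session", "write_bold", "read_bold",
    "read_config", "write_json", "config_hash",
]

SESSION_COLUMNS = [
    "trial", "rew_mag_1", "rew_mag_2", "eff_mag_1", "eff_mag_2",
    "prob_1", "prob_2", "choice", "reward_type", "clicking_rate",
    "outcome_onset_s",
]


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(_jsonify(obj), indent=1, sort_keys=True))


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(_jsonify(obj), sort_keys=True).encode()).hexdigest()[:12]


def write_session(session: BehavioralSession, path: str | Path) -> None:
    """Write a session as CSV plus a JSON sidecar with timing/config/seed."""
    path = Path(path)
    session.to_frame().to_csv(path, index=False, float_format="%.12g")
    sidecar = {
        "seed": session.schedule.seed,
        "group_label": session.group_label,
        "participant_id": session.participant_id,
        "schedule_config": session.schedule.config,
        "timing": [dataclasses.asdict(tt) for tt in session.timing],
    }
    write_json(path.with_suffix(".json"), sidecar)


def read_session(path: str | Path) -> BehavioralSession:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"session file {path} is missing columns: {missing}")
    extra = [c for c in df.columns if c not in SESSION_COLUMNS]
    if extra:
        warnings.warn(f"session file {path} has unknown columns "
                      f"(preserved in the table, ignored here): {extra}")
    bad = df[~df["reward_type"].isin(["real", "hypothetical"])]
    if len(bad):
        raise ValueError(
            f"invalid reward_type at rows {bad.index.tolist()[:5]} in {path}")
    sidecar_path = path.with_suffix(".json")
    seed, group, pid, timing, cfg = -1, "", "", None, None
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        seed = meta.get("seed", -1)
        group = meta.get("group_label", "")
        pid = meta.get("participant_id", "")
        if "timing" in meta:
            timing = [TrialTiming(**tt) for tt in meta["timing"]]
        if "schedule_config" in meta:
            sc = dict(meta["schedule_config"])
            sc["timing"] = TimingConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in sc["timing"].items()})
            sc["bounds"] = tuple(sc["bounds"])
            sc["prob_grid"] = tuple(sc["prob_grid"])
            cfg = ScheduleConfig(**sc)
    schedule = TaskSchedule.from_frame(df, seed=seed, config=cfg)
    n = len(df)
    if timing is None:
        onsets = df["outcome_onset_s"].to_numpy(dtype=float)
        timing = [TrialTiming(0, 0, 2, 2, 5, 2, float(o)) for o in onsets]
    return BehavioralSession(
        schedule=schedule,
        choice=df["choice"].to_numpy(dtype=int) - 1,
        reward_type=list(df["reward_type"]),
        reward_outcome=schedule.reward_mag.copy(),
        effort_outcome=schedule.effort_mag.copy(),
        clicking_rate=df["clicking_rate"].to_numpy(dtype=float),
        timing=timing, group_label=group, participant_id=pid,
    )


def write_bold(bold: BoldSeries, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": bold.times, "signal": bold.signal}).to_csv(
        path, index=False, float_format="%.12g")
    write_json(path.with_suffix(".json"), {
        "tr_s": bold.tr_s, "onsets": bold.onsets,
        "planted_betas": bold.planted_betas,
        "noise_sd": bold.noise_sd, "ar1_rho": bold.ar1_rho,
    })


def read_bold(path: str | Path) -> BoldSeries:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "signal"):
        if col not in df.columns:
            raise ValueError(f"BOLD file {path} is missing column '{col}'")
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    t = df["time_s"].to_numpy(dtype=float)
    tr = float(meta.get("tr_s", t[1] - t[0] if len(t) > 1 else 2.0))
    return BoldSeries(
        tr_s=tr, signal=df["signal"].to_numpy(dtype=float),
        onsets=np.asarray(meta.get("onsets", []), dtype=float),
        planted_betas=meta.get("planted_betas", {}),
        noise_sd=float(meta.get("noise_sd", np.nan)),
        ar1_rho=float(meta.get("ar1_rho", np.nan)),
    )


def read_config(path: str | Path) -> dict:
    """Read a YAML or JSON run configuration into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text) or {}
    return json.loads(text)
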