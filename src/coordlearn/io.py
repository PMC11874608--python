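"""On-disk formats and study configuration.

Trials are stored one CSV per trial (columns ``time_s, left_pos, right_pos``)
next to a ``manifest.json`` describing each file's participant, group,
session, phase and trial number, plus any ground-truth generator parameters.
Everything is plain text so a study is diffable and versionable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError
from .synthetic import StudyDataset, TrialTimeSeries

__all__ = ["StudyConfig", "write_trials", "write_study", "read_trials"]

_TRIAL_COLUMNS = ("time_s", "left_pos", "right_pos")


@dataclass(frozen=True)
class StudyConfig:
    """Defaults for one virtual study, mirroring the experimental design:
    1 Hz movements of 300-pixel amplitude sampled at 60 Hz for 20 s; 5
    assessment trials per phase and 30 training trials per session; feedback
    bandwidth faded 30° down to 10° in 5° steps; scoring bandwidth 20°
    (10° for the bias-control reanalysis)."""

    frequency: float = 1.0
    sample_rate: float = 60.0
    duration: float = 20.0
    amplitude: float = 300.0
    assessment_trials_per_phase: int = 5
    training_trials: int = 30
    bandwidth_schedule: tuple[float, ...] = (30.0, 25.0, 20.0, 15.0, 10.0)
    scoring_bandwidth: float = 20.0
    staircase_initial_difference: float = 30.0
    staircase_step_up: float = 10.0
    staircase_down_ratio: float = 0.5488
    staircase_reversals: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        values = [self.frequency, self.sample_rate, self.duration, self.amplitude,
                  self.assessment_trials_per_phase, self.training_trials,
                  self.scoring_bandwidth]
        if any(v <= 0 for v in values):
            raise ParseError("all study-config values must be positive")
        bw = self.bandwidth_schedule
        if any(b2 >= b1 for b1, b2 in zip(bw, bw[1:])):
            raise ParseError("bandwidth schedule must be strictly decreasing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        if "bandwidth_schedule" in raw:
            raw["bandwidth_schedule"] = tuple(raw["bandwidth_schedule"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["bandwidth_schedule"] = list(data["bandwidth_schedule"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _trial_filename(meta: dict) -> str:
    return (f"{meta['participant']}_s{meta['session']:02d}_"
            f"p{int(round(meta['phase'])):03d}_t{meta['trial']:02d}.csv")


def write_trials(trials: list[tuple[TrialTimeSeries, dict]],
                 directory: str | Path) -> Path:
    """Write trials plus a manifest to ``directory``.

    Each element pairs a trial with its metadata dict (keys ``participant``,
    ``group``, ``session``, ``phase``, ``trial``; optional ``ground_truth``).
    Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for trial, meta in trials:
        meta = dict(meta)
        meta.setdefault("phase", trial.target_phase)
        meta.setdefault("session", trial.session_index)
        meta.setdefault("trial", trial.trial_index)
        fname = _trial_filename(meta)
        pd.DataFrame({
            "time_s": trial.time,
            "left_pos": trial.left_position,
            "right_pos": trial.right_position,
        }).to_csv(directory / fname, index=False, float_format="%.6f")
        entries.append({"file": fname, "target_phase": trial.target_phase, **meta})
    manifest = directory / "manifest.json"
    manifest.write_text(json.dumps({"trials": entries}, indent=1))
    return manifest


def write_study(dataset: StudyDataset, directory: str | Path) -> Path:
    """Flatten a simulated study into the trial-CSV + manifest layout,
    carrying each participant's ground-truth skill trajectory."""
    rows = []
    for participant in dataset.participants:
        truth = [dataclasses.asdict(s) for s in participant.skill_trajectory]
        for s_idx, session in enumerate(participant.sessions, start=1):
            for phase, phase_trials in session["trials"].items():
                for trial in phase_trials:
                    rows.append((trial, {
                        "participant": participant.participant_id,
                        "group": participant.age_group,
                        "session": s_idx,
                        "session_label": session["label"],
                        "phase": float(phase),
                        "trial": trial.trial_index,
                        "ground_truth": truth[s_idx - 1],
                    }))
    return write_trials(rows, directory)


def read_trials(path: str | Path) -> Iterator[tuple[TrialTimeSeries, dict]]:
    """Read a manifest directory (or manifest file) back into validated trials.

    Malformed files raise ``ParseError`` naming the offending trial and, for
    bad rows, the line number.
    """
    path = Path(path)
    manifest_path = path / "manifest.json" if path.is_dir() else path
    if not manifest_path.exists():
        raise ParseError(f"no manifest at {manifest_path}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"manifest {manifest_path} is not valid JSON: {exc}") from exc
    directory = manifest_path.parent
    for entry in manifest.get("trials", []):
        fname = entry.get("file")
        fpath = directory / fname
        if not fpath.exists():
            raise ParseError(f"manifest names missing trial file {fname!r}")
        try:
            frame = pd.read_csv(fpath)
        except Exception as exc:
            raise ParseError(f"trial {fname!r}: unreadable CSV ({exc})") from exc
        if frame.empty:
            raise ParseError(f"trial {fname!r}: file is empty")
        missing = [c for c in _TRIAL_COLUMNS if c not in frame.columns]
        if missing:
            raise ParseError(f"trial {fname!r}: missing columns {missing}")
        bad = frame[list(_TRIAL_COLUMNS)].apply(
            lambda col: ~np.isfinite(pd.to_numeric(col, errors="coerce"))
        )
        if bad.to_numpy().any():
            line = int(bad.any(axis=1).idxmax()) + 2  # header + 1-based
            raise ParseError(f"trial {fname!r}: non-numeric value near line {line}")
        time = frame["time_s"].to_numpy(float)
        if np.any(np.diff(time) <= 0):
            raise ParseError(f"trial {fname!r}: time_s is not strictly increasing")
        trial = TrialTimeSeries(
            time=time,
            left_position=frame["left_pos"].to_numpy(float),
            right_position=frame["right_pos"].to_numpy(float),
            target_phase=float(entry.get("target_phase", entry.get("phase", 0.0))),
            session_index=int(entry.get("session", 1)),
            trial_index=int(entry.get("trial", 1)),
        )
        yield trial, entry
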