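"""Reading and writing trial tables and study manifests.

Trial tables are plain CSV with columns ``subject_id,condition,trial,
stimulus,response`` (1-based trial index, magnitudes in linear units).  A
study manifest is a JSON file listing the trial-table files, the seeds that
produced them and, for synthetic data, the true observer parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .observer import ObserverParams
from .sequences import StimulusSequence, TrialSequence

__all__ = ["read_trials", "write_trials", "write_study", "read_study"]

REQUIRED_COLUMNS = ["subject_id", "condition", "trial", "stimulus", "response"]


def trials_to_frame(trials: list[TrialSequence]) -> pd.DataFrame:
    rows = []
    for seq in trials:
        rows.append(pd.DataFrame({
            "subject_id": seq.subject_id,
            "condition": seq.condition,
            "trial": np.arange(1, len(seq) + 1),
            "stimulus": seq.stimulus_values,
            "response": seq.responses,
        }))
    return pd.concat(rows, ignore_index=True)


def write_trials(trials: list[TrialSequence], path) -> None:
    """Write trial sequences to one CSV trial table."""
    trials_to_frame(trials).to_csv(path, index=False)


def frame_to_trials(df: pd.DataFrame, generator_kind: str = "iid") -> list[TrialSequence]:
    """Validate a trial table and group it into TrialSequence objects."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    problems: list[str] = []
    for col in ("stimulus", "response"):
        bad = df.index[~(pd.to_numeric(df[col], errors="coerce") > 0)]
        for row in bad:
            problems.append(f"row {row + 2}: nonpositive or invalid {col}")
    dup = df.duplicated(subset=["subject_id", "condition", "trial"], keep=False)
    for row in df.index[dup]:
        problems.append(
            f"row {row + 2}: duplicate (subject_id, condition, trial) key "
            f"{tuple(df.loc[row, ['subject_id', 'condition', 'trial']])}"
        )
    if problems:
        raise ValueError("invalid trial table:\n" + "\n".join(problems))
    out = []
    for (subject, condition), grp in df.groupby(["subject_id", "condition"], sort=True):
        grp = grp.sort_values("trial")
        stim = StimulusSequence(grp["stimulus"].to_numpy(float), generator_kind)
        out.append(TrialSequence(str(subject), str(condition), stim,
                                 grp["response"].to_numpy(float)))
    return out


def read_trials(path) -> list[TrialSequence]:
    """Read a CSV trial table, grouped by subject × condition, sorted by trial.

    Validation problems (missing columns, nonpositive magnitudes, duplicate
    trial keys) are collected and reported together with their row numbers.
    """
    df = pd.read_csv(path)
    return frame_to_trials(df)


def write_study(trials: list[TrialSequence], manifest: dict, out_dir) -> Path:
    """Write a study as one trial table per condition plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for condition in sorted({t.condition for t in trials}):
        fname = f"trials_{condition}.csv"
        write_trials([t for t in trials if t.condition == condition], out / fname)
        files[condition] = fname
    manifest = {**manifest, "files": files}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_study(manifest_path) -> tuple[list[TrialSequence], dict]:
    """Load a study written by :func:`write_study`, truth parameters attached."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    truth_by_subject = {
        s["subject_id"]: ObserverParams(**s["truth"])
        for s in manifest.get("subjects", [])
    }
    trials: list[TrialSequence] = []
    for condition, fname in manifest["files"].items():
        for seq in read_trials(manifest_path.parent / fname):
            seq.truth = truth_by_subject.get(seq.subject_id)
            trials.append(seq)
    return trials, manifest
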