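"""Tidy CSV schema shared by the simulator and the fitters.

``trials.csv`` holds one row per trial (all sessions, all participants);
``participants.csv`` holds one row per participant with group, pre/post
questionnaire scalars and — for synthetic cohorts — the ground-truth
generative parameters.  Real data converted by hand to this schema can be
fed through the fitting pipeline unchanged.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .errors import SchemaError
from .simulate import ParticipantData

TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "session",
    "block",
    "trial_index",
    "pain",
    "recipient_id",
    "demonstrator_rating",
    "prediction",
    "empathy_rating",
]
PARTICIPANT_COLUMNS = [
    "participant_id",
    "group",
    "helping_pre",
    "helping_post",
    "pain_intensity_pre",
    "pain_intensity_post",
]
GT_COLUMNS = [
    "gt_model",
    "gt_alpha",
    "gt_p0",
    "gt_w1_pos",
    "gt_w1_neg",
    "gt_w2_pos",
    "gt_w2_neg",
    "gt_gamma",
    "gt_empathy_t0",
    "gt_nonpain_t0",
    "gt_pred_noise_sd",
    "gt_empathy_noise_sd",
]

_RATING_COLUMNS = ("demonstrator_rating", "prediction", "empathy_rating")


def cohort_trials_frame(cohort: Sequence[ParticipantData]) -> pd.DataFrame:
    """Concatenate per-participant trial tables into one tidy frame."""
    return pd.concat([p.trials for p in cohort], ignore_index=True)[TRIAL_COLUMNS]


def cohort_participants_frame(cohort: Sequence[ParticipantData]) -> pd.DataFrame:
    """One row of metadata (and ground truth, if any) per participant."""
    rows = []
    for p in cohort:
        row = {
            "participant_id": p.participant_id,
            "group": p.group,
            "helping_pre": p.helping_pre,
            "helping_post": p.helping_post,
            "pain_intensity_pre": p.pain_intensity_pre,
            "pain_intensity_post": p.pain_intensity_post,
        }
        if p.observer is not None:
            o = p.observer
            row.update(
                gt_model=o.model_id,
                gt_alpha=o.alpha,
                gt_p0=o.p0,
                gt_w1_pos=o.w1_pos,
                gt_w1_neg=o.w1_neg,
                gt_w2_pos=o.w2_pos,
                gt_w2_neg=o.w2_neg,
                gt_gamma=o.gamma,
                gt_empathy_t0=o.empathy_t0,
                gt_nonpain_t0=o.nonpain_t0,
                gt_pred_noise_sd=o.pred_noise_sd,
                gt_empathy_noise_sd=o.empathy_noise_sd,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(cohort: Sequence[ParticipantData], outdir: Union[str, Path]) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials_path = outdir / "trials.csv"
    participants_path = outdir / "participants.csv"
    cohort_trials_frame(cohort).to_csv(trials_path, index=False)
    cohort_participants_frame(cohort).to_csv(participants_path, index=False)
    return {"trials": trials_path, "participants": participants_path}


def read_trials(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a tidy trial CSV."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing trial columns {missing}")
    for col in _RATING_COLUMNS:
        values = df[col].dropna()
        bad = values[(values < 0) | (values > 100)]
        if not bad.empty:
            raise SchemaError(
                f"{path}: column {col!r} has out-of-range value {bad.iloc[0]!r} "
                f"at row {int(bad.index[0])}"
            )
    if df["session"].isna().any() or df["trial_index"].isna().any():
        raise SchemaError(f"{path}: session/trial_index must not be missing")
    return df


def read_participants(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing participant columns {missing}")
    return df


class _NumpyJSONEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyJSONEncoder) + "\n")
    return path
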