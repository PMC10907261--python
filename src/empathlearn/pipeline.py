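"""Per-participant and cohort-level fitting pipeline.

Binds the stages together: baseline means -> Rescorla-Wagner fit of the
prediction series -> prediction errors on painful trials -> MAP fits of the
candidate empathy-update models -> evidence matrix for group-level model
selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import LEARNING, PAINFUL
from .errors import InputError
from .rw import RWFit, RWPriors, fit_rw
from .update_models import (
    UpdateModelFit,
    UpdateModelSpec,
    UpdatePriors,
    canonical_model_id,
    first_half_mask_from_trial_indices,
    fit_update_model,
)

log = logging.getLogger("empathlearn")

DEFAULT_MODELS = ("M1_single", "M2_signsplit", "M3_signsplit_halfsplit")


@dataclass
class ParticipantFits:
    """All fits for one participant."""

    participant_id: str
    group: str
    baseline_mean: float
    rw: RWFit
    updates: dict[str, UpdateModelFit]
    pe_painful: np.ndarray = field(repr=False, default=None)


def fit_participant(
    trials: pd.DataFrame,
    models: Sequence[str] = DEFAULT_MODELS,
    half_boundary: int = 24,
    rw_trials: str = "all",
    n_restarts: int = 10,
    seed: int = 0,
    update_priors: UpdatePriors = UpdatePriors(),
) -> ParticipantFits:
    """Fit the RW model and every candidate update model for one participant.

    ``trials`` is that participant's slice of the tidy trial table.  The RW
    series covers all learning trials by default (``rw_trials="all"``; the
    demonstrator rates painful and non-painful videos alike) or only the
    painful ones (``rw_trials="painful"``).  Empathy-update models are fitted
    on painful-trial empathy ratings with Empathy_t0 fixed to the baseline
    painful mean.
    """
    pid = str(trials["participant_id"].iloc[0])
    group = str(trials["group"].iloc[0])
    baseline = trials[(trials["session"] == "baseline") & (trials["pain"] == PAINFUL)]
    if baseline["empathy_rating"].notna().sum() == 0:
        raise InputError(f"{pid}: no baseline painful empathy ratings")
    baseline_mean = float(baseline["empathy_rating"].mean())

    learn = trials[trials["session"] == LEARNING].sort_values("trial_index")
    if rw_trials == "painful":
        rw_learn = learn[learn["pain"] == PAINFUL]
    elif rw_trials == "all":
        rw_learn = learn
    else:
        raise InputError(f"rw_trials must be 'all' or 'painful', got {rw_trials!r}")

    ratings = rw_learn["demonstrator_rating"].to_numpy(float)
    if np.isnan(ratings).any():
        raise InputError(f"{pid}: missing demonstrator ratings in the learning session")
    predictions = rw_learn["prediction"].to_numpy(float)
    rw_fit = fit_rw(
        predictions,
        ratings,
        priors=RWPriors(p0_mean=baseline_mean),
        n_restarts=n_restarts,
        seed=seed,
    )

    pain_mask = (rw_learn["pain"] == PAINFUL).to_numpy()
    pe_painful = rw_fit.prediction_errors[pain_mask]
    pain_trial_idx = rw_learn.loc[pain_mask, "trial_index"].to_numpy(int)
    empathy = rw_learn.loc[pain_mask, "empathy_rating"].to_numpy(float)
    first_half = first_half_mask_from_trial_indices(pain_trial_idx, half_boundary)

    # fit in nesting order so each richer model warm-starts from the nested
    # MAP solutions (a richer model then never fits worse than a nested one)
    richness = {"M1_single": 0, "M2_signsplit": 1, "M3_signsplit_halfsplit": 2}
    ordered = sorted({canonical_model_id(m) for m in models}, key=richness.__getitem__)
    updates: dict[str, UpdateModelFit] = {}
    for mid in ordered:
        updates[mid] = fit_update_model(
            empathy,
            pe_painful,
            spec=UpdateModelSpec(model_id=mid, half_boundary=half_boundary),
            priors=update_priors,
            empathy_t0=baseline_mean,
            first_half=first_half,
            n_restarts=n_restarts,
            seed=seed + 1,
            warm_starts=list(updates.values()),
        )
    return ParticipantFits(
        participant_id=pid,
        group=group,
        baseline_mean=baseline_mean,
        rw=rw_fit,
        updates=updates,
        pe_painful=pe_painful,
    )


@dataclass
class CohortFits:
    fits: dict[str, ParticipantFits]
    evidence: pd.DataFrame          # participants x models, LAME entries
    parameters: pd.DataFrame        # fitted parameters per participant
    failures: dict[str, str]

    def pe_table(self, trials: pd.DataFrame) -> pd.DataFrame:
        """Painful learning trials with fitted PEs and empathy changes merged in."""
        learn = trials[(trials["session"] == LEARNING) & (trials["pain"] == PAINFUL)].copy()
        frames = []
        for pid, sub in learn.groupby("participant_id", sort=True):
            fit = self.fits.get(str(pid))
            if fit is None:
                continue
            sub = sub.sort_values("trial_index").copy()
            sub["pe"] = fit.pe_painful
            frames.append(sub)
        return pd.concat(frames, ignore_index=True)


def fit_cohort(
    trials: pd.DataFrame,
    models: Sequence[str] = DEFAULT_MODELS,
    half_boundary: int = 24,
    rw_trials: str = "all",
    n_restarts: int = 10,
    seed: int = 0,
) -> CohortFits:
    """Fit every participant in a tidy trial table; failures are logged and
    skipped so one bad record does not abort the run."""
    fits: dict[str, ParticipantFits] = {}
    failures: dict[str, str] = {}
    model_ids = [canonical_model_id(m) for m in models]
    for i, (pid, sub) in enumerate(trials.groupby("participant_id", sort=True)):
        try:
            fits[str(pid)] = fit_participant(
                sub,
                models=model_ids,
                half_boundary=half_boundary,
                rw_trials=rw_trials,
                n_restarts=n_restarts,
                seed=seed + 7919 * i,
            )
        except (InputError, RuntimeError) as exc:  # pragma: no cover - defensive
            log.warning("skipping participant %s: %s", pid, exc)
            failures[str(pid)] = str(exc)

    if not fits:
        raise InputError("no participant could be fitted")

    evidence = pd.DataFrame(
        {m: [f.updates[m].lame for f in fits.values()] for m in model_ids},
        index=list(fits.keys()),
    )
    rows = []
    for f in fits.values():
        row = {
            "participant_id": f.participant_id,
            "group": f.group,
            "baseline_mean": f.baseline_mean,
            "alpha": f.rw.map_params.alpha,
            "p0": f.rw.map_params.p0,
            "sigma_pred": f.rw.map_params.sigma_pred,
            "rw_r2": f.rw.r2,
            "rw_lame": f.rw.lame,
        }
        for m, ufit in f.updates.items():
            short = {"M1_single": "m1", "M2_signsplit": "m2", "M3_signsplit_halfsplit": "m3"}[m]
            for wname, wval in ufit.map_params.weights.items():
                row[f"{short}_{wname}"] = wval
            row[f"{short}_gamma"] = ufit.map_params.gamma
            row[f"{short}_sigma"] = ufit.map_params.sigma_emp
            row[f"{short}_r2"] = ufit.r2
            row[f"{short}_lame"] = ufit.lame
        rows.append(row)
    parameters = pd.DataFrame(rows)
    return CohortFits(fits=fits, evidence=evidence, parameters=parameters, failures=failures)
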