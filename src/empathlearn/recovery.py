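"""Parameter- and model-recovery simulations.

The recovery harness closes the loop on the whole machinery: cohorts are
simulated from known ground truth, pushed through the identical fitting
pipeline used for real data, and the fitted parameters / selected models
are compared against the truth.  Parameter recovery is summarized by
Pearson correlations between true and fitted values; model recovery by the
random-effects exceedance probabilities and a confusion matrix over
generative regimes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import TrialScheduleSpec
from .io import cohort_participants_frame, cohort_trials_frame
from .model_selection import BMSResult, bms_random_effects
from .pipeline import DEFAULT_MODELS, fit_cohort
from .simulate import CohortPriors, simulate_cohort

ACTIVE_WEIGHT = {"high": "w1_pos", "low": "w1_neg"}


@dataclass
class ParameterRecoveryResult:
    table: pd.DataFrame          # true_* and fit_* columns, one row per subject
    correlations: dict[str, float]


def recover_parameters(
    n_subjects: int = 50,
    seed: int = 0,
    priors: CohortPriors = CohortPriors(),
    spec: TrialScheduleSpec = TrialScheduleSpec(),
    group: str = "high",
    model_id: str = "M3_signsplit_halfsplit",
    n_restarts: int = 10,
) -> ParameterRecoveryResult:
    """Simulate ``n_subjects`` observers and correlate true vs fitted
    alpha, active first-half weight and gamma."""
    cohort = simulate_cohort(
        n_subjects, priors=priors, spec=spec, seed=seed, groups=(group,), model_id=model_id
    )
    trials = cohort_trials_frame(cohort)
    truth = cohort_participants_frame(cohort).set_index("participant_id")
    fits = fit_cohort(trials, models=(model_id,), n_restarts=n_restarts, seed=seed + 1)

    wname = ACTIVE_WEIGHT[group]
    short = {"M1_single": "m1", "M2_signsplit": "m2", "M3_signsplit_halfsplit": "m3"}[model_id]
    params = fits.parameters.set_index("participant_id")
    fit_w_col = f"{short}_{wname}" if model_id != "M1_single" else f"{short}_w"
    table = pd.DataFrame(
        {
            "true_alpha": truth["gt_alpha"],
            "fit_alpha": params["alpha"],
            "true_w1": truth[f"gt_{wname}" if model_id != "M1_single" else "gt_w1_pos"],
            "fit_w1": params[fit_w_col],
            "true_gamma": truth["gt_gamma"],
            "fit_gamma": params[f"{short}_gamma"],
        }
    ).dropna()
    correlations = {
        name: float(np.corrcoef(table[f"true_{name}"], table[f"fit_{name}"])[0, 1])
        for name in ("alpha", "w1", "gamma")
    }
    return ParameterRecoveryResult(table=table.reset_index(), correlations=correlations)


def xp_for_generated_cohort(
    n_subjects: int = 26,
    seed: int = 0,
    priors: CohortPriors = CohortPriors(),
    spec: TrialScheduleSpec = TrialScheduleSpec(),
    group: str = "high",
    generating_model: str = "M3_signsplit_halfsplit",
    candidate_models: Sequence[str] = DEFAULT_MODELS,
    n_restarts: int = 10,
    n_bms_samples: int = 100_000,
) -> BMSResult:
    """Simulate one cohort from a generating model, fit all candidates and
    run random-effects model selection over the LAME matrix."""
    cohort = simulate_cohort(
        n_subjects, priors=priors, spec=spec, seed=seed, groups=(group,),
        model_id=generating_model,
    )
    trials = cohort_trials_frame(cohort)
    fits = fit_cohort(trials, models=candidate_models, n_restarts=n_restarts, seed=seed + 1)
    return bms_random_effects(fits.evidence, n_samples=n_bms_samples, seed=seed + 2)


@dataclass
class ModelRecoveryResult:
    confusion: pd.DataFrame      # rows: generating model, cols: selected model (counts)
    xp_records: pd.DataFrame     # generating model, cohort seed, XP per candidate


def recover_models(
    generating_models: Sequence[str] = DEFAULT_MODELS,
    n_cohorts: int = 10,
    n_per_cohort: int = 26,
    seed: int = 0,
    priors: CohortPriors = CohortPriors(),
    group: str = "high",
    candidate_models: Sequence[str] = DEFAULT_MODELS,
    n_restarts: int = 10,
    n_bms_samples: int = 100_000,
) -> ModelRecoveryResult:
    """Confusion matrix of random-effects model selection across cohorts
    simulated from each generating model in turn."""
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(0, index=list(generating_models), columns=list(candidate_models))
    records = []
    for gen in generating_models:
        for c in range(n_cohorts):
            cohort_seed = int(rng.integers(2**31))
            bms = xp_for_generated_cohort(
                n_subjects=n_per_cohort,
                seed=cohort_seed,
                priors=priors,
                group=group,
                generating_model=gen,
                candidate_models=candidate_models,
                n_restarts=n_restarts,
                n_bms_samples=n_bms_samples,
            )
            winner = bms.model_names[int(np.argmax(bms.exceedance_probability))]
            counts.loc[gen, winner] += 1
            rec = {"generating_model": gen, "cohort_seed": cohort_seed, "winner": winner}
            rec.update(dict(zip(bms.model_names, bms.exceedance_probability)))
            records.append(rec)
    return ModelRecoveryResult(confusion=counts, xp_records=pd.DataFrame(records))
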