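"""Model-independent behavioral analyses.

These analyses do not rely on the learning models: per-participant linear
trends of predictions/empathy ratings over the learning session, the pooled
association between observational prediction errors and subsequent changes
of empathy ratings, session change scores, and the rank correlation between
empathy change and the change in willingness to help.

Group-level inference uses per-participant OLS slopes combined by two-sample
and one-sample t tests (a deliberate simplification of by-participant
random-intercept mixed models: directions and effect sizes are preserved,
exact p-values differ).  The pooled PE regression uses
participant-clustered robust standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .design import GENERALIZATION, LEARNING, PAINFUL
from .errors import AbsentSeriesError, InputError

_SERIES_COLUMNS = {"prediction": "prediction", "empathy": "empathy_rating"}


@dataclass(frozen=True)
class TrendResult:
    """Per-participant learning-session slopes and their group contrast."""

    slopes: pd.DataFrame                # participant_id, group, slope
    group_means: dict[str, float]
    group_difference: tuple[float, float]   # (t, p), two-sample
    per_group_trend: dict[str, tuple[float, float]]  # one-sample t of slopes vs 0


def fit_trends(
    trials: pd.DataFrame,
    series: str = "empathy",
    pain: str = PAINFUL,
    min_trials: int = 10,
) -> TrendResult:
    """OLS slope of a rating series over trial number, per participant.

    Slopes are computed over the (by default painful) learning trials; the
    group contrast is a two-sample t test on the slopes and each group's
    trend a one-sample t test against zero.
    """
    if series not in _SERIES_COLUMNS:
        raise InputError(f"series must be one of {sorted(_SERIES_COLUMNS)}, got {series!r}")
    col = _SERIES_COLUMNS[series]
    learn = trials[(trials["session"] == LEARNING) & (trials["pain"] == pain)]
    if col not in trials.columns or learn[col].notna().sum() == 0:
        raise AbsentSeriesError(f"series {series!r} is absent from the learning trials")

    records = []
    for pid, sub in learn.groupby("participant_id", sort=True):
        sub = sub.dropna(subset=[col])
        if len(sub) < min_trials:
            continue
        slope = float(np.polyfit(sub["trial_index"].to_numpy(float), sub[col].to_numpy(float), 1)[0])
        records.append({"participant_id": pid, "group": sub["group"].iloc[0], "slope": slope})
    slopes = pd.DataFrame.from_records(records)
    if slopes.empty:
        raise InputError("no participant had enough trials for a trend fit")

    group_means = slopes.groupby("group")["slope"].mean().to_dict()
    per_group = {}
    for g, sub in slopes.groupby("group"):
        if len(sub) < 2:
            raise InputError(f"group {g!r} has fewer than 2 participants")
        t, p = stats.ttest_1samp(sub["slope"], 0.0)
        per_group[g] = (float(t), float(p))
    groups = sorted(per_group)
    if len(groups) >= 2:
        a = slopes.loc[slopes["group"] == groups[0], "slope"]
        b = slopes.loc[slopes["group"] == groups[1], "slope"]
        t, p = stats.ttest_ind(a, b)
        diff = (float(t), float(p))
    else:
        diff = (float("nan"), float("nan"))
    return TrendResult(
        slopes=slopes, group_means=group_means, group_difference=diff, per_group_trend=per_group
    )


def delta_empathy_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Trial-wise empathy changes aligned with same-trial prediction errors.

    For each participant, painful learning trials are ordered by trial
    index and the change score at trial t is empathy(t) - empathy(previous
    painful trial); the first painful trial is dropped.  A ``pe`` column,
    if present in ``trials``, is carried through.
    """
    learn = trials[(trials["session"] == LEARNING) & (trials["pain"] == PAINFUL)].copy()
    out = []
    for pid, sub in learn.groupby("participant_id", sort=True):
        sub = sub.sort_values("trial_index")
        d = sub["empathy_rating"].diff()
        sub = sub.assign(d_empathy=d).iloc[1:]
        out.append(sub)
    if not out:
        raise InputError("no painful learning trials found")
    return pd.concat(out, ignore_index=True)


@dataclass(frozen=True)
class PERegressionResult:
    """Pooled PE -> empathy-change regression with clustered errors."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    nobs: int
    formula: str


def pe_change_regression(
    table: pd.DataFrame,
    study_col: Optional[str] = None,
) -> PERegressionResult:
    """Regress trial-wise empathy changes on same-trial prediction errors.

    ``table`` needs columns ``participant_id``, ``pe`` and ``d_empathy``
    (see :func:`delta_empathy_table`).  With ``study_col`` given, a
    PE x study interaction tests whether the PE coupling differs between
    cohorts (e.g. human- vs computer-demonstrator studies).  Standard
    errors are cluster-robust by participant.
    """
    required = {"participant_id", "pe", "d_empathy"}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"table lacks columns {sorted(missing)}")
    data = table.dropna(subset=["pe", "d_empathy"]).copy()
    if data["participant_id"].nunique() < 2:
        raise InputError("need >= 2 participants for a pooled regression")

    formula = "d_empathy ~ pe"
    if study_col is not None:
        if study_col not in data.columns:
            raise InputError(f"study column {study_col!r} not in table")
        formula = f"d_empathy ~ pe * C({study_col})"
    fit = smf.ols(formula, data=data).fit(
        cov_type="cluster", cov_kwds={"groups": data["participant_id"]}
    )
    return PERegressionResult(
        params=fit.params, bse=fit.bse, pvalues=fit.pvalues, nobs=int(fit.nobs), formula=formula
    )


def compute_change_scores(trials: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    """Per-participant session change scores.

    empathy_change = generalization painful mean - baseline painful mean;
    helping_change and pain_intensity_change come from the participants
    table (post - pre).
    """
    painful = trials[trials["pain"] == PAINFUL]
    means = (
        painful.groupby(["participant_id", "session"])["empathy_rating"].mean().unstack()
    )
    for session in ("baseline", GENERALIZATION):
        if session not in means.columns:
            raise InputError(f"trials lack a {session} session")
    scores = pd.DataFrame(
        {"empathy_change": means[GENERALIZATION] - means["baseline"]}
    ).reset_index()
    meta = participants.set_index("participant_id")
    scores["group"] = scores["participant_id"].map(meta["group"])
    scores["helping_change"] = scores["participant_id"].map(
        meta["helping_post"] - meta["helping_pre"]
    )
    scores["pain_intensity_change"] = scores["participant_id"].map(
        meta["pain_intensity_post"] - meta["pain_intensity_pre"]
    )
    return scores


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    pvalue: float
    n: int
    warnings: tuple[str, ...] = ()


def change_vs_helping(scores: pd.DataFrame) -> dict[str, SpearmanResult]:
    """Spearman correlation of empathy change with helping-time change.

    Returned keys are ``"overall"`` plus one per group.  Zero variance in
    either score is flagged rather than raising.
    """
    required = {"empathy_change", "helping_change"}
    if required - set(scores.columns):
        raise InputError(f"scores lack columns {sorted(required - set(scores.columns))}")

    def _one(sub: pd.DataFrame) -> SpearmanResult:
        x = sub["empathy_change"].to_numpy(float)
        y = sub["helping_change"].to_numpy(float)
        if np.ptp(x) < 1e-12 or np.ptp(y) < 1e-12:
            return SpearmanResult(float("nan"), float("nan"), len(sub), ("zero-variance",))
        res = stats.spearmanr(x, y)
        return SpearmanResult(float(res.statistic), float(res.pvalue), len(sub))

    if len(scores) < 5:
        raise InputError(f"need >= 5 participants, got {len(scores)}")
    out = {"overall": _one(scores)}
    if "group" in scores.columns:
        for g, sub in scores.groupby("group"):
            # a group too small for a meaningful rank correlation is flagged,
            # not fatal, so the overall statistic is still reported
            if len(sub) < 5:
                out[str(g)] = SpearmanResult(float("nan"), float("nan"), len(sub),
                                             ("too-few-participants",))
            else:
                out[str(g)] = _one(sub)
    return out
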