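"""Synthetic observers with known ground-truth parameters.

A synthetic participant is generated by forward-running the package's own
models: predictions follow the Rescorla-Wagner recursion over the
demonstrator series, empathy ratings on painful learning trials follow one
of the discounted prediction-error update models, and every emitted rating
gets additive Gaussian response noise and is clipped to the 0-100 scale.
The ground truth is stored alongside the data so that parameter- and
model-recovery can be tested without any external download.

Generalization-session painful ratings persist at the learning-session
average of the latent model trajectory (the update models themselves are
silent about post-learning trials, but empirically learned changes
persist); helping time and perceived pain intensity are coupled to that
latent empathy change so that the model-independent behavioral analyses
have a signal to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .demonstrator import DemonstratorAlgorithm, generate_demonstrator_ratings
from .design import (
    BASELINE,
    GENERALIZATION,
    LEARNING,
    PAINFUL,
    Trial,
    TrialScheduleSpec,
    generate_schedule,
    learning_trials,
)
from .errors import ConfigurationError, InputError
from .rw import RWParams, rw_forward
from .update_models import (
    UpdateModelSpec,
    UpdateParams,
    WEIGHT_NAMES,
    canonical_model_id,
    first_half_mask_from_trial_indices,
    predict_empathy,
)

# couplings from latent empathy change to the pre/post questionnaire scalars
HELPING_COUPLING = 0.5        # minutes per rating point of empathy change
HELPING_NOISE_SD = 8.0        # minutes; yields a population Spearman rho near 0.35
PAIN_INTENSITY_COUPLING = 0.07  # 0-10 scale points per rating point
PAIN_INTENSITY_NOISE_SD = 0.8


@dataclass(frozen=True)
class GroundTruthObserver:
    """Generative parameters of one synthetic participant.

    ``w1_pos`` doubles as the single weight of the one-weight model and as
    ``w_pos`` of the sign-split model when ``model_id`` selects those
    ablations (``w1_neg`` likewise maps to ``w_neg``).
    """

    group: str
    alpha: float = 0.4
    p0: float = 50.0
    w1_pos: float = 0.0
    w1_neg: float = 0.0
    w2_pos: float = 0.0
    w2_neg: float = 0.0
    gamma: float = 0.7
    empathy_t0: float = 50.0
    nonpain_t0: float = 15.0
    pred_noise_sd: float = 8.0
    empathy_noise_sd: float = 8.0
    model_id: str = "M3_signsplit_halfsplit"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ConfigurationError(f"gamma must lie in [0, 1], got {self.gamma}")
        if self.pred_noise_sd < 0 or self.empathy_noise_sd < 0:
            raise ConfigurationError("noise SDs must be non-negative")
        for name in ("p0", "empathy_t0", "nonpain_t0"):
            value = getattr(self, name)
            if not 0.0 <= value <= 100.0:
                raise ConfigurationError(f"{name} must lie in [0, 100], got {value}")
        object.__setattr__(self, "model_id", canonical_model_id(self.model_id))

    def update_weights(self) -> dict[str, float]:
        """Weight dict for the generating update model."""
        if self.model_id == "M1_single":
            return {"w": self.w1_pos}
        if self.model_id == "M2_signsplit":
            return {"w_pos": self.w1_pos, "w_neg": self.w1_neg}
        return {
            "w1_pos": self.w1_pos,
            "w1_neg": self.w1_neg,
            "w2_pos": self.w2_pos,
            "w2_neg": self.w2_neg,
        }


@dataclass
class ParticipantData:
    """One participant's full three-session record plus metadata."""

    participant_id: str
    group: str
    trials: pd.DataFrame
    helping_pre: float
    helping_post: float
    pain_intensity_pre: float
    pain_intensity_post: float
    observer: Optional[GroundTruthObserver] = field(default=None, repr=False)


def _clip(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 100.0)


def simulate_participant(
    observer: GroundTruthObserver,
    schedule: Sequence[Trial],
    demonstrator_ratings: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
    participant_id: str = "sim",
    half_boundary: int = 24,
) -> ParticipantData:
    """Forward-simulate one participant over a trial schedule.

    If ``demonstrator_ratings`` is None, the demonstrator algorithm is run
    on the participant's *realized* baseline means (as in the real task,
    where the algorithm consumed the baseline ratings); otherwise the given
    learning-trial rating series is used as-is.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    schedule = list(schedule)
    learn = learning_trials(schedule)
    if not learn:
        raise InputError("schedule contains no learning trials")

    # --- baseline session: empathy around the ground-truth anchors
    rows: list[dict] = []
    base_pain_vals: list[float] = []
    base_nonpain_vals: list[float] = []
    for tr in schedule:
        if tr.session != BASELINE:
            continue
        anchor = observer.empathy_t0 if tr.pain == PAINFUL else observer.nonpain_t0
        rating = float(_clip(np.array([rng.normal(anchor, observer.empathy_noise_sd)]))[0])
        (base_pain_vals if tr.pain == PAINFUL else base_nonpain_vals).append(rating)
        rows.append(_row(tr, empathy=rating))

    if demonstrator_ratings is None:
        algo = DemonstratorAlgorithm(
            group=observer.group if observer.group in ("high", "low") else "neutral",
            baseline_mean_pain=float(np.mean(base_pain_vals)),
            baseline_mean_nonpain=float(np.mean(base_nonpain_vals)),
        )
        demonstrator_ratings = generate_demonstrator_ratings(algo, learn, rng=rng)
    demonstrator_ratings = np.asarray(demonstrator_ratings, dtype=float)
    if demonstrator_ratings.shape != (len(learn),):
        raise InputError(
            f"demonstrator_ratings has shape {demonstrator_ratings.shape}, "
            f"expected ({len(learn)},)"
        )

    # --- learning session: latent RW predictions and PEs over all trials
    latent_p, latent_pe = rw_forward(
        RWParams(alpha=observer.alpha, p0=observer.p0), demonstrator_ratings
    )
    observed_pred = _clip(latent_p + rng.normal(0.0, observer.pred_noise_sd, size=latent_p.size)) \
        if observer.pred_noise_sd > 0 else _clip(latent_p)

    pain_mask = np.array([tr.pain == PAINFUL for tr in learn])
    pain_indices = np.array([tr.trial_index for tr in learn])[pain_mask]
    spec = UpdateModelSpec(model_id=observer.model_id, half_boundary=half_boundary)
    params = UpdateParams(
        weights=observer.update_weights(),
        gamma=observer.gamma,
        empathy_t0=observer.empathy_t0,
        sigma_emp=max(observer.empathy_noise_sd, 1e-6),
    )
    latent_e = predict_empathy(
        spec,
        params,
        latent_pe[pain_mask],
        first_half=first_half_mask_from_trial_indices(pain_indices, half_boundary),
    )

    emp_noise = rng.normal(0.0, observer.empathy_noise_sd, size=len(learn)) \
        if observer.empathy_noise_sd > 0 else np.zeros(len(learn))
    e_iter = iter(latent_e)
    for i, tr in enumerate(learn):
        latent = next(e_iter) if tr.pain == PAINFUL else observer.nonpain_t0
        rows.append(
            _row(
                tr,
                empathy=float(_clip(np.array([latent + emp_noise[i]]))[0]),
                demonstrator=float(demonstrator_ratings[i]),
                prediction=float(observed_pred[i]),
            )
        )

    # --- generalization: persist at the learning-session average of the
    # latent trajectory (empathy_shift), new recipient, no demonstrator
    empathy_shift = float(np.mean(latent_e) - observer.empathy_t0) if latent_e.size else 0.0
    for tr in schedule:
        if tr.session != GENERALIZATION:
            continue
        anchor = (
            observer.empathy_t0 + empathy_shift if tr.pain == PAINFUL else observer.nonpain_t0
        )
        rows.append(_row(tr, empathy=float(_clip(np.array([rng.normal(anchor, observer.empathy_noise_sd)]))[0])))

    helping_pre = float(rng.uniform(15.0, 30.0))
    helping_post = float(
        np.clip(helping_pre + HELPING_COUPLING * empathy_shift + rng.normal(0.0, HELPING_NOISE_SD),
                0.0, 60.0)
    )
    pain_pre = float(np.clip(rng.normal(6.6, 1.0), 0.0, 10.0))
    pain_post = float(
        np.clip(pain_pre + PAIN_INTENSITY_COUPLING * empathy_shift
                + rng.normal(0.0, PAIN_INTENSITY_NOISE_SD), 0.0, 10.0)
    )

    trials_df = pd.DataFrame(rows)
    trials_df.insert(0, "participant_id", participant_id)
    trials_df.insert(1, "group", observer.group)
    return ParticipantData(
        participant_id=participant_id,
        group=observer.group,
        trials=trials_df,
        helping_pre=helping_pre,
        helping_post=helping_post,
        pain_intensity_pre=pain_pre,
        pain_intensity_post=pain_post,
        observer=observer,
    )


def _row(tr: Trial, empathy: float, demonstrator: Optional[float] = None,
         prediction: Optional[float] = None) -> dict:
    return {
        "session": tr.session,
        "block": tr.block,
        "trial_index": tr.trial_index,
        "pain": tr.pain,
        "recipient_id": tr.recipient_id,
        "demonstrator_rating": demonstrator,
        "prediction": prediction,
        "empathy_rating": empathy,
    }


@dataclass(frozen=True)
class CohortPriors:
    """Uniform sampling ranges for ground-truth observer parameters.

    Defaults define the recovery-simulation regime: moderate learning rates
    and discounts, active weights drawn from U(0.2, 1.0) with the
    group-atypical weights fixed at 0 (high-empathy observers learn from
    positive, low-empathy observers from negative prediction errors), and a
    5-point response noise on both rating series.
    """

    alpha: tuple[float, float] = (0.1, 0.7)
    gamma: tuple[float, float] = (0.3, 0.95)
    w_active: tuple[float, float] = (0.2, 1.0)
    empathy_t0: tuple[float, float] = (35.0, 65.0)
    p0: tuple[float, float] = (35.0, 65.0)
    nonpain_t0: tuple[float, float] = (10.0, 20.0)
    pred_noise_sd: float = 5.0
    empathy_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        for name in ("alpha", "gamma", "w_active", "empathy_t0", "p0", "nonpain_t0"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"prior range for {name} is degenerate: ({lo}, {hi})")
        if self.pred_noise_sd < 0 or self.empathy_noise_sd < 0:
            raise ConfigurationError("noise SDs must be non-negative")


def draw_observer(
    priors: CohortPriors,
    group: str,
    rng: np.random.Generator,
    model_id: str = "M3_signsplit_halfsplit",
) -> GroundTruthObserver:
    """Draw one ground-truth observer from the prior ranges.

    For the sign-split models the group-typical weights (positive-PE
    weights in the high group, negative-PE weights in the low group) are
    active draws and the atypical weights are 0; the single-weight model
    uses one active draw regardless of group.
    """
    model_id = canonical_model_id(model_id)
    u = lambda rng_range: float(rng.uniform(*rng_range))  # noqa: E731
    weights = dict.fromkeys(("w1_pos", "w1_neg", "w2_pos", "w2_neg"), 0.0)
    if model_id == "M1_single":
        weights["w1_pos"] = u(priors.w_active)
    elif model_id == "M2_signsplit":
        key = "w1_pos" if group == "high" else "w1_neg"
        weights[key] = u(priors.w_active)
    else:
        first, second = ("w1_pos", "w2_pos") if group == "high" else ("w1_neg", "w2_neg")
        weights[first] = u(priors.w_active)
        weights[second] = u(priors.w_active)
    return GroundTruthObserver(
        group=group,
        alpha=u(priors.alpha),
        p0=u(priors.p0),
        gamma=u(priors.gamma),
        empathy_t0=u(priors.empathy_t0),
        nonpain_t0=u(priors.nonpain_t0),
        pred_noise_sd=priors.pred_noise_sd,
        empathy_noise_sd=priors.empathy_noise_sd,
        model_id=model_id,
        **weights,
    )


def simulate_cohort(
    n_per_group: int,
    priors: CohortPriors = CohortPriors(),
    spec: TrialScheduleSpec = TrialScheduleSpec(),
    seed: int = 0,
    groups: Sequence[str] = ("high", "low"),
    model_id: str = "M3_signsplit_halfsplit",
) -> list[ParticipantData]:
    """Simulate a cohort of synthetic participants.

    Each participant gets an independent child random stream (and an
    independent schedule permutation) derived from the master ``seed``, so
    the cohort is reproducible as a whole and participant-by-participant.
    """
    if n_per_group < 1:
        raise ConfigurationError(f"n_per_group must be >= 1, got {n_per_group}")
    children = np.random.SeedSequence(seed).spawn(n_per_group * len(groups))
    cohort: list[ParticipantData] = []
    i = 0
    for group in groups:
        for j in range(n_per_group):
            rng = np.random.default_rng(children[i])
            schedule_seed = int(rng.integers(2**31))
            schedule = generate_schedule(replace(spec, seed=schedule_seed))
            observer = draw_observer(priors, group, rng, model_id=model_id)
            cohort.append(
                simulate_participant(
                    observer,
                    schedule,
                    rng=rng,
                    participant_id=f"{group}_{j + 1:03d}",
                )
            )
            i += 1
    return cohort
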