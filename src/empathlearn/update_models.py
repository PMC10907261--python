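"""Discounted prediction-error models of trial-wise empathy ratings.

The participant's own empathy rating on learning trial t is modeled as a
linear function of the time-discounted cumulative observational prediction
errors up to and including trial t (within a trial the participant observes
the demonstrator before rating, so the current PE contributes), anchored at
the participant's baseline mean Empathy_t0:

* ``M1_single``             E_t = E_t0 + W * S_all(t)
* ``M2_signsplit``          E_t = E_t0 + W_pos * S_pos(t) + W_neg * S_neg(t)
* ``M3_signsplit_halfsplit``  as M2, but with weights (W1_pos, W1_neg) while
  t lies in the first half of the learning session and (W2_pos, W2_neg)
  afterwards.

S_sign(t) = sum_{tau <= t} gamma^(t - tau) * delta_tau, restricted to
strictly positive / strictly negative / all prediction errors.  The
discount gamma in [0, 1] makes recent prediction errors count more
(gamma = 0 keeps only the latest PE; gamma = 1 weighs all equally) and is
shared across signs and halves.  Weights W are in rating units per PE unit;
positive W_pos raises empathy after positive PEs, positive W_neg lowers it
after negative PEs (the sums themselves are negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.signal import lfilter
from scipy.special import expit, logit
from scipy.stats import spearmanr

from . import fitting
from .errors import ConfigurationError, InputError
from .rw import _r2

MIN_TRIALS = 10

MODEL_IDS = ("M1_single", "M2_signsplit", "M3_signsplit_halfsplit")
_ALIASES = {"M1": "M1_single", "M2": "M2_signsplit", "M3": "M3_signsplit_halfsplit"}
WEIGHT_NAMES: dict[str, tuple[str, ...]] = {
    "M1_single": ("w",),
    "M2_signsplit": ("w_pos", "w_neg"),
    "M3_signsplit_halfsplit": ("w1_pos", "w1_neg", "w2_pos", "w2_neg"),
}


def canonical_model_id(model_id: str) -> str:
    mid = _ALIASES.get(model_id, model_id)
    if mid not in MODEL_IDS:
        raise ConfigurationError(f"unknown model id {model_id!r}; expected one of {MODEL_IDS}")
    return mid


@dataclass(frozen=True)
class UpdateModelSpec:
    """Which candidate model to evaluate and how the session is split.

    ``half_boundary`` is the last session trial index belonging to the first
    half (default 24 of 48, the end of block 2, where the recipient
    changes).  When the modeled series is a subsequence of the session
    (e.g. painful trials only), pass an explicit ``first_half`` mask to
    :func:`predict_empathy` / :func:`fit_update_model` built from the
    session trial indices.
    """

    model_id: str = "M3_signsplit_halfsplit"
    half_boundary: int = 24
    include_nonpain: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_id", canonical_model_id(self.model_id))
        if self.half_boundary < 1:
            raise ConfigurationError("half_boundary must be a positive trial index")

    @property
    def weight_names(self) -> tuple[str, ...]:
        return WEIGHT_NAMES[self.model_id]


@dataclass(frozen=True)
class UpdateParams:
    """Parameters of one empathy-update model."""

    weights: Mapping[str, float]
    gamma: float
    empathy_t0: float
    sigma_emp: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ConfigurationError(f"gamma must lie in [0, 1], got {self.gamma}")
        if self.sigma_emp <= 0:
            raise ConfigurationError("sigma_emp must be positive")
        object.__setattr__(self, "weights", dict(self.weights))

    def validate_for(self, spec: UpdateModelSpec) -> None:
        expected = set(spec.weight_names)
        got = set(self.weights)
        if got != expected:
            raise ConfigurationError(
                f"weight set {sorted(got)} does not match {spec.model_id} "
                f"(expected {sorted(expected)})"
            )


@dataclass(frozen=True)
class UpdatePriors:
    """Priors for MAP estimation: W ~ Normal(0, weight_sd),
    gamma ~ Beta(1.1, 1.1), log sigma ~ Normal(log 5, 1);
    Empathy_t0 is fixed to the participant's baseline painful-trial mean."""

    weight_sd: float = 2.0
    gamma_a: float = 1.1
    gamma_b: float = 1.1
    log_sigma_mean: float = float(np.log(5.0))
    log_sigma_sd: float = 1.0


@dataclass
class UpdateModelFit:
    """MAP fit of one empathy-update model for one participant."""

    spec: UpdateModelSpec
    map_params: UpdateParams
    trajectory: np.ndarray       # model empathy ratings E_t (not clipped)
    lpp: float
    lame: float
    r2: float
    log_likelihood: float        # Gaussian log likelihood at the MAP
    n_trials: int
    warnings: tuple[str, ...] = ()
    hessian: Optional[np.ndarray] = field(default=None, repr=False)


def discounted_pe_series(pe_series: Sequence[float], gamma: float, sign: str = "all") -> np.ndarray:
    """S(t) for every t: the recursion S(t) = gamma * S(t-1) + delta_t(sign).

    Zero PEs contribute to neither the ``pos`` nor the ``neg`` sum.
    """
    if not 0.0 <= gamma <= 1.0:
        raise InputError(f"gamma must lie in [0, 1], got {gamma}")
    pe = np.asarray(pe_series, dtype=float)
    if sign == "pos":
        x = np.where(pe > 0, pe, 0.0)
    elif sign == "neg":
        x = np.where(pe < 0, pe, 0.0)
    elif sign == "all":
        x = pe
    else:
        raise InputError(f"sign must be 'pos', 'neg' or 'all', got {sign!r}")
    return lfilter([1.0], [1.0, -gamma], x)


def discounted_pe_sums(pe_series: Sequence[float], gamma: float, t: int, sign: str = "all") -> float:
    """Discounted, sign-filtered cumulative PE sum at 1-based trial ``t``."""
    pe = np.asarray(pe_series, dtype=float)
    if not 1 <= t <= pe.size:
        raise InputError(f"t = {t} out of range for a series of length {pe.size}")
    return float(discounted_pe_series(pe, gamma, sign)[t - 1])


def _first_half_mask(spec: UpdateModelSpec, n: int, first_half) -> np.ndarray:
    if first_half is None:
        return np.arange(1, n + 1) <= spec.half_boundary
    mask = np.asarray(first_half, dtype=bool)
    if mask.shape != (n,):
        raise InputError(f"first_half mask has shape {mask.shape}, expected ({n},)")
    return mask


def predict_empathy(
    spec: UpdateModelSpec,
    params: UpdateParams,
    pe_series: Sequence[float],
    first_half=None,
) -> np.ndarray:
    """Model empathy-rating trajectory E_t over the modeled trials.

    ``first_half`` marks which entries of ``pe_series`` belong to the first
    half of the learning session (only used by the half-split model); by
    default the series position is compared against ``spec.half_boundary``.
    The output is *not* clipped to [0, 100] — clipping applies only when
    emitting simulated ratings, never inside fitting.
    """
    params.validate_for(spec)
    pe = np.asarray(pe_series, dtype=float)
    w = params.weights
    if spec.model_id == "M1_single":
        return params.empathy_t0 + w["w"] * discounted_pe_series(pe, params.gamma, "all")
    s_pos = discounted_pe_series(pe, params.gamma, "pos")
    s_neg = discounted_pe_series(pe, params.gamma, "neg")
    if spec.model_id == "M2_signsplit":
        return params.empathy_t0 + w["w_pos"] * s_pos + w["w_neg"] * s_neg
    mask = _first_half_mask(spec, pe.size, first_half)
    w_pos = np.where(mask, w["w1_pos"], w["w2_pos"])
    w_neg = np.where(mask, w["w1_neg"], w["w2_neg"])
    return params.empathy_t0 + w_pos * s_pos + w_neg * s_neg


def expand_weights(weights: Mapping[str, float], to_model: str) -> dict[str, float]:
    """Map a nested model's weights into a richer model's weight set.

    The one-weight model embeds into the sign-split one as w_pos = w_neg = w,
    and the sign-split model into the half-split one as w1 = w2 per sign.
    """
    to_model = canonical_model_id(to_model)
    w = dict(weights)
    if set(w) == set(WEIGHT_NAMES[to_model]):
        return w
    if set(w) == {"w"}:
        w = {"w_pos": w["w"], "w_neg": w["w"]}
    if to_model == "M2_signsplit":
        return w
    if set(w) == {"w_pos", "w_neg"}:
        return {"w1_pos": w["w_pos"], "w1_neg": w["w_neg"],
                "w2_pos": w["w_pos"], "w2_neg": w["w_neg"]}
    raise ConfigurationError(f"cannot embed weights {sorted(weights)} into {to_model}")


def fit_update_model(
    empathy_ratings: Sequence[float],
    pe_series: Sequence[float],
    spec: UpdateModelSpec = UpdateModelSpec(),
    priors: UpdatePriors = UpdatePriors(),
    empathy_t0: Optional[float] = None,
    first_half=None,
    n_restarts: int = 10,
    seed: int = 0,
    r2_method: str = "pearson",
    warm_starts: Sequence["UpdateModelFit"] = (),
) -> UpdateModelFit:
    """MAP-fit one empathy-update model for one participant.

    ``empathy_ratings`` and ``pe_series`` must be aligned over the modeled
    trials (by default the painful learning trials).  ``empathy_t0`` — the
    participant's mean baseline painful-trial rating — is a fixed constant
    of the model, not a fitted parameter.  NaN ratings are dropped from the
    likelihood.

    ``warm_starts`` takes fits of nested models on the same data; their MAP
    solutions are embedded (see :func:`expand_weights`) and added as start
    points, which guarantees in practice that a richer model never fits
    worse than a nested one.
    """
    ratings = np.asarray(empathy_ratings, dtype=float)
    pe = np.asarray(pe_series, dtype=float)
    if ratings.shape != pe.shape:
        raise InputError(
            f"empathy ratings ({ratings.shape}) and PE series ({pe.shape}) misaligned"
        )
    mask_obs = np.isfinite(ratings)
    if mask_obs.sum() < MIN_TRIALS:
        raise InputError(f"need >= {MIN_TRIALS} modeled trials, got {int(mask_obs.sum())}")
    if empathy_t0 is None:
        raise InputError("empathy_t0 (baseline painful-trial mean) is required")

    half_mask = _first_half_mask(spec, pe.size, first_half)
    weight_names = spec.weight_names
    k_w = len(weight_names)

    warnings: list[str] = []
    if not np.any(pe > 0) and any("pos" in nm for nm in weight_names):
        warnings.append("w_pos-prior-dominated-no-positive-pes")
    if not np.any(pe < 0) and any("neg" in nm for nm in weight_names):
        warnings.append("w_neg-prior-dominated-no-negative-pes")

    def unpack(z: np.ndarray):
        weights = dict(zip(weight_names, z[:k_w]))
        return weights, expit(z[k_w]), np.exp(z[k_w + 1])

    def trajectory_at(weights: Mapping[str, float], gamma: float) -> np.ndarray:
        s_all = discounted_pe_series(pe, gamma, "all")
        if spec.model_id == "M1_single":
            return empathy_t0 + weights["w"] * s_all
        s_pos = discounted_pe_series(pe, gamma, "pos")
        s_neg = s_all - s_pos  # neg sum = all - pos, one filter call saved
        if spec.model_id == "M2_signsplit":
            return empathy_t0 + weights["w_pos"] * s_pos + weights["w_neg"] * s_neg
        w_pos = np.where(half_mask, weights["w1_pos"], weights["w2_pos"])
        w_neg = np.where(half_mask, weights["w1_neg"], weights["w2_neg"])
        return empathy_t0 + w_pos * s_pos + w_neg * s_neg

    def neg_log_post(z: np.ndarray) -> float:
        weights, gamma, sigma = unpack(z)
        traj = trajectory_at(weights, gamma)
        nll = fitting.gaussian_nll(ratings[mask_obs] - traj[mask_obs], sigma)
        log_prior = (
            sum(fitting.normal_logpdf(wv, 0.0, priors.weight_sd) for wv in weights.values())
            + fitting.beta_logpdf_with_jacobian(z[k_w], priors.gamma_a, priors.gamma_b)
            + fitting.normal_logpdf(z[k_w + 1], priors.log_sigma_mean, priors.log_sigma_sd)
        )
        return nll - log_prior

    rng = np.random.default_rng(seed)
    starts = [np.concatenate([np.full(k_w, 0.1), [logit(0.5)], [np.log(5.0)]])]
    for prev in warm_starts:
        pw = expand_weights(prev.map_params.weights, spec.model_id)
        g = float(np.clip(prev.map_params.gamma, 1e-6, 1 - 1e-6))
        starts.append(
            np.concatenate(
                [
                    [pw[name] for name in weight_names],
                    [logit(g)],
                    [np.log(max(prev.map_params.sigma_emp, 1e-2))],
                ]
            )
        )
    for _ in range(max(0, n_restarts - 1)):
        starts.append(
            np.concatenate(
                [
                    rng.normal(0.0, 1.0, size=k_w),
                    [logit(np.clip(rng.beta(priors.gamma_a, priors.gamma_b), 1e-4, 1 - 1e-4))],
                    [rng.normal(priors.log_sigma_mean, priors.log_sigma_sd)],
                ]
            )
        )
    bounds = (
        [(-50.0, 50.0)] * k_w
        + [(-fitting.LOGIT_BOUND, fitting.LOGIT_BOUND)]
        + [fitting.LOG_SIGMA_BOUNDS]
    )
    result = fitting.map_fit(neg_log_post, starts, bounds)
    warnings.extend(result.warnings)

    weights, gamma, sigma = unpack(result.z)
    params = UpdateParams(
        weights=weights, gamma=float(gamma), empathy_t0=float(empathy_t0), sigma_emp=float(sigma)
    )
    traj = trajectory_at(weights, gamma)
    log_lik = -fitting.gaussian_nll(ratings[mask_obs] - traj[mask_obs], sigma)
    r2, r2_warn = _r2(traj[mask_obs], ratings[mask_obs], method=r2_method)
    warnings.extend(r2_warn)

    return UpdateModelFit(
        spec=spec,
        map_params=params,
        trajectory=traj,
        lpp=result.lpp,
        lame=result.lame,
        r2=r2,
        log_likelihood=float(log_lik),
        n_trials=int(mask_obs.sum()),
        warnings=tuple(warnings),
        hessian=result.hessian,
    )


@dataclass(frozen=True)
class WeightChangeResult:
    """Spearman association between a fitted weight and empathy change."""

    rho: float
    pvalue: float
    n: int
    warnings: tuple[str, ...] = ()


def weight_change_correlation(
    fits: Sequence[UpdateModelFit],
    empathy_change_scores: Sequence[float],
    weight: str = "w1_pos",
) -> WeightChangeResult:
    """Rank-correlate a first-half weight with per-participant empathy change.

    ``empathy_change_scores`` is generalization-mean minus baseline-mean
    empathy (painful trials), one entry per fit.  ``fits`` may also be a
    plain sequence of weight values.
    """
    if len(fits) != len(empathy_change_scores):
        raise InputError("one fit and one change score per participant required")
    if len(fits) < 5:
        raise InputError(f"need >= 5 participants, got {len(fits)}")
    values = np.array(
        [f.map_params.weights[weight] if isinstance(f, UpdateModelFit) else float(f) for f in fits]
    )
    changes = np.asarray(empathy_change_scores, dtype=float)
    if np.ptp(values) < 1e-12 or np.ptp(changes) < 1e-12:
        return WeightChangeResult(rho=float("nan"), pvalue=float("nan"), n=len(values),
                                  warnings=("zero-variance",))
    res = spearmanr(values, changes)
    return WeightChangeResult(rho=float(res.statistic), pvalue=float(res.pvalue), n=len(values))


def first_half_mask_from_trial_indices(trial_indices: Sequence[int], half_boundary: int = 24) -> np.ndarray:
    """Boolean mask over a modeled subsequence from session trial indices."""
    return np.asarray(trial_indices, dtype=int) <= int(half_boundary)
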