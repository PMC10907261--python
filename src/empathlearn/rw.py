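"""Rescorla-Wagner model of trial-wise predictions of demonstrator ratings.

On every learning trial the participant predicts the demonstrator's empathy
rating before seeing it.  The prediction series is modeled by the delta
rule: with prediction P_t and observed demonstrator rating R_t, the
observational prediction error is delta_t = R_t - P_t and the next
prediction is P_{t+1} = P_t + alpha * delta_t.  A positive delta means the
demonstrator was more empathic than expected.

The free parameters (learning rate alpha, initial prediction p0 and a
Gaussian observation noise SD) are estimated per participant by MAP, and
the prediction-error series extracted at the MAP feeds the empathy-update
models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit, logit
from scipy.stats import pearsonr

from . import fitting
from .design import Trial
from .errors import ConfigurationError, InputError

MIN_TRIALS = 10


@dataclass(frozen=True)
class RWParams:
    """Rescorla-Wagner parameters for one participant."""

    alpha: float
    p0: float
    sigma_pred: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not 0.0 <= self.p0 <= 100.0:
            raise ConfigurationError(f"p0 must lie in [0, 100], got {self.p0}")
        if self.sigma_pred <= 0:
            raise ConfigurationError("sigma_pred must be positive")


@dataclass(frozen=True)
class RWPriors:
    """Priors for MAP estimation (natural scale).

    alpha ~ Beta(1.1, 1.1) (near-flat, vanishing at the boundaries),
    p0 ~ Normal(p0_mean, p0_sd) centered on the participant's baseline
    painful-trial mean, log sigma ~ Normal(log 5, 1).
    """

    alpha_a: float = 1.1
    alpha_b: float = 1.1
    p0_mean: float = 50.0
    p0_sd: float = 10.0
    log_sigma_mean: float = float(np.log(5.0))
    log_sigma_sd: float = 1.0


@dataclass
class RWFit:
    """MAP fit of the prediction series for one participant."""

    map_params: RWParams
    model_predictions: np.ndarray   # P_t at the MAP, one per learning trial
    prediction_errors: np.ndarray   # delta_t = R_t - P_t at the MAP
    lpp: float                      # negative log posterior at the optimum
    lame: float                     # Laplace log model evidence
    r2: float
    n_trials: int
    warnings: tuple[str, ...] = ()
    hessian: Optional[np.ndarray] = field(default=None, repr=False)


def rw_forward(params: RWParams, demonstrator_ratings: Sequence[float]):
    """Run the delta rule forward over a rating series.

    Returns ``(P, delta)`` with P_1 = p0, delta_t = R_t - P_t and
    P_{t+1} = P_t + alpha * delta_t.  Pure and deterministic.
    """
    ratings = np.asarray(demonstrator_ratings, dtype=float)
    if ratings.size == 0:
        raise InputError("demonstrator rating series is empty")
    a = params.alpha
    # P satisfies P[t] = (1-a) P[t-1] + a R[t-1]; as an IIR filter
    # y[n] = a x[n-1] + (1-a) y[n-1] with initial output p0.
    predictions, _ = lfilter([0.0, a], [1.0, -(1.0 - a)], ratings, zi=np.array([params.p0]))
    deltas = ratings - predictions
    return predictions, deltas


def _r2(model: np.ndarray, observed: np.ndarray, method: str = "pearson") -> tuple[float, list[str]]:
    warnings: list[str] = []
    if method == "pearson":
        if np.std(model) < 1e-12 or np.std(observed) < 1e-12:
            return 0.0, ["r2-degenerate-constant-series"]
        r = pearsonr(model, observed).statistic
        return float(r**2), warnings
    if method == "sse":
        sst = float(np.sum((observed - observed.mean()) ** 2))
        if sst < 1e-12:
            return 0.0, ["r2-degenerate-constant-series"]
        sse = float(np.sum((observed - model) ** 2))
        return float(np.clip(1.0 - sse / sst, 0.0, 1.0)), warnings
    raise ConfigurationError(f"unknown r2 method {method!r}")


def fit_rw(
    observed_predictions: Sequence[float],
    demonstrator_ratings: Sequence[float],
    priors: RWPriors = RWPriors(),
    n_restarts: int = 10,
    seed: int = 0,
    r2_method: str = "pearson",
) -> RWFit:
    """MAP-fit the Rescorla-Wagner model to one participant's predictions.

    ``observed_predictions`` may contain NaN for missed responses; the
    Gaussian likelihood runs over non-missing trials only (at least
    ``MIN_TRIALS`` required), while the latent P_t trajectory always runs
    over the full demonstrator series.
    """
    ratings = np.asarray(demonstrator_ratings, dtype=float)
    observed = np.asarray(observed_predictions, dtype=float)
    if observed.shape != ratings.shape:
        raise InputError(
            f"predictions ({observed.shape}) and demonstrator ratings ({ratings.shape}) misaligned"
        )
    mask = np.isfinite(observed)
    if mask.sum() < MIN_TRIALS:
        raise InputError(f"need >= {MIN_TRIALS} non-missing predictions, got {int(mask.sum())}")

    warnings: list[str] = []
    if np.ptp(ratings) < 1e-9 and np.ptp(observed[mask]) < 1e-9:
        warnings.append("alpha-unidentifiable-constant-series")

    def unpack(z: np.ndarray):
        return expit(z[0]), z[1], np.exp(z[2])

    def neg_log_post(z: np.ndarray) -> float:
        alpha, p0, sigma = unpack(z)
        predictions, _ = lfilter([0.0, alpha], [1.0, -(1.0 - alpha)], ratings, zi=np.array([p0]))
        nll = fitting.gaussian_nll(observed[mask] - predictions[mask], sigma)
        log_prior = (
            fitting.beta_logpdf_with_jacobian(z[0], priors.alpha_a, priors.alpha_b)
            + fitting.normal_logpdf(p0, priors.p0_mean, priors.p0_sd)
            + fitting.normal_logpdf(z[2], priors.log_sigma_mean, priors.log_sigma_sd)
        )
        return nll - log_prior

    rng = np.random.default_rng(seed)
    starts = [np.array([logit(0.3), priors.p0_mean, np.log(5.0)])]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(
            np.array(
                [
                    logit(np.clip(rng.beta(priors.alpha_a, priors.alpha_b), 1e-4, 1 - 1e-4)),
                    rng.normal(priors.p0_mean, priors.p0_sd),
                    rng.normal(priors.log_sigma_mean, priors.log_sigma_sd),
                ]
            )
        )
    bounds = [
        (-fitting.LOGIT_BOUND, fitting.LOGIT_BOUND),
        (-100.0, 200.0),
        fitting.LOG_SIGMA_BOUNDS,
    ]
    result = fitting.map_fit(neg_log_post, starts, bounds)
    warnings.extend(result.warnings)

    alpha, p0, sigma = unpack(result.z)
    # trajectory and PEs are evaluated at the raw MAP; the stored p0 is
    # clipped to the rating scale only if the optimum strays outside it
    predictions, _ = lfilter([0.0, alpha], [1.0, -(1.0 - alpha)], ratings, zi=np.array([p0]))
    deltas = ratings - predictions
    if not 0.0 <= p0 <= 100.0:
        warnings.append("p0-outside-rating-scale")
    params = RWParams(alpha=float(alpha), p0=float(np.clip(p0, 0.0, 100.0)), sigma_pred=float(sigma))
    r2, r2_warn = _r2(predictions[mask], observed[mask], method=r2_method)
    warnings.extend(r2_warn)

    return RWFit(
        map_params=params,
        model_predictions=predictions,
        prediction_errors=deltas,
        lpp=result.lpp,
        lame=result.lame,
        r2=r2,
        n_trials=int(mask.sum()),
        warnings=tuple(warnings),
        hessian=result.hessian,
    )


def prediction_errors_table(fit: RWFit, schedule: Sequence[Trial]) -> pd.DataFrame:
    """Tidy per-trial observational prediction errors at the MAP.

    ``schedule`` must list the learning trials that the fit was run over, in
    presentation order.  The sign convention is delta = observed
    demonstrator rating - model prediction: positive delta means the
    demonstrator was more empathic than predicted.
    """
    trials = [tr for tr in schedule if tr.session == "learning"] or list(schedule)
    if len(trials) != fit.prediction_errors.size:
        raise InputError(
            f"schedule has {len(trials)} learning trials but fit covers "
            f"{fit.prediction_errors.size}"
        )
    return pd.DataFrame(
        {
            "trial_index": [tr.trial_index for tr in trials],
            "block": [tr.block for tr in trials],
            "pain": [tr.pain for tr in trials],
            "demonstrator_rating": [tr.demonstrator_rating for tr in trials],
            "model_prediction": fit.model_predictions,
            "pe": fit.prediction_errors,
        }
    )
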