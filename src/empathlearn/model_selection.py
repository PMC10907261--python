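"""Model evidence and group-level Bayesian model selection.

Per-participant fits are compared by the Laplace approximation to the log
model evidence (LAME), which trades goodness-of-fit against complexity
through the curvature of the posterior at its mode.  At the group level a
random-effects scheme treats the generating model as a random variable per
participant and fits a Dirichlet distribution over model frequencies by the
standard variational update (Stephan et al. 2009, NeuroImage); the
exceedance probability (XP) of model m is the posterior probability that m
is the most frequent generating model in the population, estimated by
Monte-Carlo draws from the fitted Dirichlet.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import digamma, logsumexp

from .errors import InputError

EvidenceLike = Union[np.ndarray, pd.DataFrame]


def laplace_evidence(
    log_posterior_at_map: float,
    hessian_of_neg_log_posterior: Optional[np.ndarray] = None,
    jitter: float = 1e-6,
    return_pd_flag: bool = False,
):
    """Laplace approximation to the log model evidence.

    LAME = log p(y, theta_MAP) + (k/2) log(2 pi) - (1/2) log det H, where H
    is the Hessian of the negative log posterior at the MAP and k the number
    of free parameters.  A model with no free parameters (``hessian`` None
    or empty) has LAME equal to its log likelihood.

    A non-positive-definite Hessian (flat or saddle directions at the
    reported optimum) is regularized by shifting its eigenvalues up to
    ``jitter``; ``return_pd_flag=True`` additionally reports whether the
    raw Hessian was positive definite.
    """
    lp = float(log_posterior_at_map)
    if hessian_of_neg_log_posterior is None or np.size(hessian_of_neg_log_posterior) == 0:
        return (lp, True) if return_pd_flag else lp

    hess = np.atleast_2d(np.asarray(hessian_of_neg_log_posterior, dtype=float))
    k = hess.shape[0]
    if hess.shape != (k, k):
        raise InputError(f"hessian must be square, got shape {hess.shape}")

    eigvals, eigvecs = np.linalg.eigh(0.5 * (hess + hess.T))
    pd_ok = bool(np.all(eigvals > 0))
    if not pd_ok:
        eigvals = np.maximum(eigvals, jitter)
    log_det = float(np.sum(np.log(eigvals)))
    lame = lp + 0.5 * k * np.log(2.0 * np.pi) - 0.5 * log_det
    return (lame, pd_ok) if return_pd_flag else lame


@dataclass(frozen=True)
class BMSResult:
    """Group-level random-effects model-selection result."""

    model_names: tuple[str, ...]
    dirichlet_alpha: np.ndarray        # posterior concentration per model
    expected_frequencies: np.ndarray   # E[r_m], sums to 1
    exceedance_probability: np.ndarray  # P(model m most frequent), sums to 1
    n_mc_samples: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "model_names": list(self.model_names),
            "dirichlet_alpha": [float(a) for a in self.dirichlet_alpha],
            "expected_frequencies": [float(f) for f in self.expected_frequencies],
            "exceedance_probability": [float(x) for x in self.exceedance_probability],
            "n_mc_samples": int(self.n_mc_samples),
            "seed": int(self.seed),
        }


def _as_matrix(evidence: EvidenceLike) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(evidence, pd.DataFrame):
        names = tuple(str(c) for c in evidence.columns)
        mat = evidence.to_numpy(dtype=float)
    else:
        mat = np.asarray(evidence, dtype=float)
        names = tuple(f"model_{i + 1}" for i in range(mat.shape[1])) if mat.ndim == 2 else ()
    if mat.ndim != 2:
        raise InputError("evidence must be a 2-D (participants x models) array or DataFrame")
    if not np.all(np.isfinite(mat)):
        raise InputError("evidence matrix contains non-finite entries")
    return mat, names


def bms_random_effects(
    evidence: EvidenceLike,
    n_samples: int = 100_000,
    seed: int = 0,
    alpha0: float = 1.0,
    max_iter: int = 1_000,
    tol: float = 1e-10,
) -> BMSResult:
    """Random-effects Bayesian model selection over a log-evidence matrix.

    Parameters
    ----------
    evidence
        (n_participants, n_models) log evidences (e.g. LAME values); a
        DataFrame's columns name the models.
    n_samples
        Monte-Carlo draws from the posterior Dirichlet used to estimate
        exceedance probabilities.
    seed
        Seed for the Monte-Carlo step; results are deterministic given
        (evidence, n_samples, seed).
    alpha0
        Symmetric Dirichlet prior concentration (1 = uniform prior over
        frequencies).
    """
    mat, names = _as_matrix(evidence)
    n, m = mat.shape
    if n < 2 or m < 2:
        raise InputError(f"need >= 2 participants and >= 2 models, got {n} x {m}")
    if n_samples < 1:
        raise InputError("n_samples must be positive")

    # variational updates: responsibilities u_nm, concentration alpha_m
    log_ev = mat - mat.max(axis=1, keepdims=True)
    alpha = np.full(m, float(alpha0))
    for _ in range(max_iter):
        eln_r = digamma(alpha) - digamma(alpha.sum())
        log_u = log_ev + eln_r
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        alpha_new = alpha0 + np.exp(log_u).sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    freqs = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=int(n_samples))
    winners = np.argmax(draws, axis=1)
    xp = np.bincount(winners, minlength=m).astype(float) / float(n_samples)

    return BMSResult(
        model_names=names,
        dirichlet_alpha=alpha,
        expected_frequencies=freqs,
        exceedance_probability=xp,
        n_mc_samples=int(n_samples),
        seed=int(seed),
    )


@dataclass(frozen=True)
class FixedEffectsResult:
    """Summed log evidence per model and pairwise log Bayes factors."""

    model_names: tuple[str, ...]
    total_log_evidence: np.ndarray
    log_bayes_factors: np.ndarray  # [i, j] = total LE(model i) - total LE(model j)

    @property
    def winner(self) -> str:
        return self.model_names[int(np.argmax(self.total_log_evidence))]


def fixed_effects_comparison(evidence: EvidenceLike) -> FixedEffectsResult:
    """Fixed-effects comparison: sum log evidences over participants.

    Assumes every participant's data were generated by the same model;
    serves as a diagnostic companion to :func:`bms_random_effects`.
    Pairwise log Bayes factors are invariant to adding a per-participant
    constant to all models.
    """
    mat, names = _as_matrix(evidence)
    totals = mat.sum(axis=0)
    lbf = totals[:, None] - totals[None, :]
    return FixedEffectsResult(model_names=names, total_log_evidence=totals, log_bayes_factors=lbf)
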