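"""Shared MAP-fitting machinery.

Both the Rescorla-Wagner model and the empathy-update models are fitted by
minimizing the negative log posterior (LPP) in an unconstrained parameter
space: unit-interval parameters (learning rate, discount) are logit
transformed, noise SDs are log transformed, and priors are evaluated on the
natural scale with the change-of-variable Jacobian included.  The optimum is
located by multi-start L-BFGS-B; the Laplace approximation to the log model
evidence (LAME) is evaluated at the optimum from a finite-difference Hessian
in the transformed space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit, logit  # noqa: F401  (logit re-exported for callers)

from .model_selection import laplace_evidence

# Box bounds in transformed space keep the objective finite: |logit| <= 16
# pins probabilities away from exact 0/1, and sigma is kept in [1e-2, 1e3]
# rating units so the Gaussian likelihood never overflows.
LOGIT_BOUND = 16.0
LOG_SIGMA_BOUNDS = (np.log(1e-2), np.log(1e3))


@dataclass
class MAPResult:
    """Outcome of a multi-start MAP optimization."""

    z: np.ndarray                # optimum in unconstrained space
    lpp: float                   # negative log posterior at the optimum
    lame: float                  # Laplace approximation to the log evidence
    hessian: np.ndarray          # Hessian of the negative log posterior at z
    n_restarts: int
    warnings: tuple[str, ...] = ()


def finite_difference_hessian(
    f: Callable[[np.ndarray], float],
    z: np.ndarray,
    rel_step: float = 1e-4,
) -> np.ndarray:
    """Central finite-difference Hessian of ``f`` at ``z``.

    Step for coordinate i is ``rel_step * max(1, |z_i|)``.
    """
    z = np.asarray(z, dtype=float)
    k = z.size
    h = rel_step * np.maximum(1.0, np.abs(z))
    hess = np.empty((k, k))
    f0 = f(z)

    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        hess[i, i] = (f(z + ei) + f(z - ei) - 2.0 * f0) / h[i] ** 2

    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            hess[i, j] = hess[j, i] = (
                f(z + ei + ej) - f(z + ei - ej) - f(z - ei + ej) + f(z - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return hess


def map_fit(
    neg_log_post: Callable[[np.ndarray], float],
    starts: Sequence[np.ndarray],
    bounds: Sequence[tuple[float, float]],
    hessian_rel_step: float = 1e-4,
) -> MAPResult:
    """Minimize a negative log posterior from several start points.

    The best converged optimum over all starts is kept; the Laplace evidence
    is computed there.  A non-positive-definite Hessian is regularized inside
    :func:`~empathlearn.model_selection.laplace_evidence` (jitter), which is
    recorded as a warning.
    """
    best: Optional[optimize.OptimizeResult] = None
    for z0 in starts:
        res = optimize.minimize(
            neg_log_post,
            np.asarray(z0, dtype=float),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("all optimization restarts failed")

    warnings: list[str] = []
    hess = finite_difference_hessian(neg_log_post, best.x, rel_step=hessian_rel_step)
    lame, pd_ok = laplace_evidence(-best.fun, hess, return_pd_flag=True)
    if not pd_ok:
        warnings.append("hessian-not-positive-definite")
    return MAPResult(
        z=np.asarray(best.x, dtype=float),
        lpp=float(best.fun),
        lame=float(lame),
        hessian=hess,
        n_restarts=len(list(starts)),
        warnings=tuple(warnings),
    )


def gaussian_nll(residuals: np.ndarray, sigma: float) -> float:
    """Negative log likelihood of iid Gaussian residuals with SD ``sigma``."""
    n = residuals.size
    return float(
        0.5 * np.sum(residuals**2) / sigma**2 + n * np.log(sigma) + 0.5 * n * np.log(2.0 * np.pi)
    )


def beta_logpdf_with_jacobian(z: float, a: float, b: float) -> float:
    """Log prior density of a Beta(a, b) variable parameterized by its logit.

    Includes the Jacobian |dx/dz| = x(1-x), so with x = expit(z) the density
    is x^a (1-x)^b / B(a, b).  Stable for large |z|.
    """
    from scipy.special import betaln

    # log x = -log1p(exp(-z)); log(1-x) = -log1p(exp(z))
    log_x = -np.logaddexp(0.0, -z)
    log_1mx = -np.logaddexp(0.0, z)
    return float(a * log_x + b * log_1mx - betaln(a, b))


def normal_logpdf(x: float, mean: float, sd: float) -> float:
    return float(-0.5 * ((x - mean) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2.0 * np.pi))
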