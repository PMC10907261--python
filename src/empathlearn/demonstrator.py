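"""The pre-defined algorithm generating demonstrator empathy ratings.

Demonstrator ratings in the learning session are not real: they are drawn
around the participant's own baseline-session means.  For painful videos the
mean is shifted by three times a fixed SD of 5 rating points — up in the
high-empathy group, down in the low-empathy group — and for non-painful
videos the mean is the participant's non-painful baseline mean.  Draws use
SD = 5, are clipped to the 0-100 scale and rounded to integers (a discrete
slider display).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .design import LEARNING, PAINFUL, Trial
from .errors import ConfigurationError, InputError

GROUP_SIGN = {"high": 1.0, "low": -1.0, "neutral": 0.0}


@dataclass(frozen=True)
class DemonstratorAlgorithm:
    """Parameters of the demonstrator-rating generator for one participant."""

    group: str
    baseline_mean_pain: float
    baseline_mean_nonpain: float
    offset_sd: float = 5.0
    offset_multiplier: float = 3.0
    noise_sd: float = 5.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.group not in GROUP_SIGN:
            raise ConfigurationError(f"unknown group {self.group!r}; expected one of {sorted(GROUP_SIGN)}")
        for name in ("baseline_mean_pain", "baseline_mean_nonpain"):
            value = getattr(self, name)
            if not 0.0 <= value <= 100.0:
                raise InputError(f"{name} must lie in [0, 100], got {value}")
        if self.noise_sd < 0 or self.offset_sd < 0:
            raise ConfigurationError("SDs must be non-negative")

    @property
    def pain_mean(self) -> float:
        """Mean of the painful-trial distribution (baseline ± offset by group)."""
        return self.baseline_mean_pain + GROUP_SIGN[self.group] * self.offset_multiplier * self.offset_sd


def generate_demonstrator_ratings(
    algo: DemonstratorAlgorithm,
    schedule: list[Trial],
    rng: Optional[np.random.Generator] = None,
    raw: bool = False,
) -> np.ndarray:
    """Draw one demonstrator rating per learning trial, in presentation order.

    Parameters
    ----------
    algo
        Generator parameters (group, baseline means, SDs).
    schedule
        Full or learning-only trial list; only learning trials are used.
    rng
        Random generator; defaults to one seeded from ``algo.seed``.
    raw
        If True, return the raw Gaussian draws (no clipping, no rounding);
        used to verify the distributional properties of the algorithm.

    Returns
    -------
    numpy.ndarray of shape (n_learning_trials,) — float draws if ``raw``,
    else integer-valued floats clipped to [0, 100].
    """
    trials = [tr for tr in schedule if tr.session == LEARNING]
    if not trials:
        raise InputError("schedule contains no learning trials")
    if rng is None:
        rng = np.random.default_rng(algo.seed)

    means = np.where(
        np.array([tr.pain == PAINFUL for tr in trials]),
        algo.pain_mean,
        algo.baseline_mean_nonpain,
    )
    draws = rng.normal(means, algo.noise_sd)
    if raw:
        return draws
    return np.round(np.clip(draws, 0.0, 100.0))
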