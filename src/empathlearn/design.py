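"""Trial schedules for the three-session observational empathy-learning design.

The task has three sessions:

* **baseline** — the participant rates how bad they feel while watching a
  recipient receive painful (18 trials) or non-painful (12 trials)
  stimulation; no demonstrator is present.
* **learning** — four blocks of 12 trials (9 painful + 3 non-painful per
  block, 48 trials in total).  On every trial the participant first predicts
  the demonstrator's empathy rating, sees the demonstrator's actual rating,
  and then rates their own feeling.  Two recipients appear, one per pair of
  blocks, to prevent habituation.
* **generalization** — identical to baseline but with a new recipient and no
  demonstrator, probing whether learned empathy changes persist.

All ratings live on a 0-100 visual-analogue scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError

PAINFUL = "painful"
NONPAINFUL = "nonpainful"
BASELINE = "baseline"
LEARNING = "learning"
GENERALIZATION = "generalization"
SESSIONS = (BASELINE, LEARNING, GENERALIZATION)


@dataclass(frozen=True)
class TrialScheduleSpec:
    """Counts defining one participant's trial schedule.

    Defaults reproduce the published design: a 30-trial baseline
    (18 painful / 12 non-painful), a 48-trial learning session in four
    12-trial blocks (9 painful + 3 non-painful each — the only integer
    split giving 36/12 over four equal blocks), and a 30-trial
    generalization session.
    """

    n_baseline_pain: int = 18
    n_baseline_nonpain: int = 12
    n_learning_blocks: int = 4
    trials_per_block: int = 12
    pain_per_block: int = 9
    n_generalization_pain: int = 18
    n_generalization_nonpain: int = 12
    n_recipients_learning: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_baseline_pain": self.n_baseline_pain,
            "n_baseline_nonpain": self.n_baseline_nonpain,
            "n_learning_blocks": self.n_learning_blocks,
            "trials_per_block": self.trials_per_block,
            "pain_per_block": self.pain_per_block,
            "n_generalization_pain": self.n_generalization_pain,
            "n_generalization_nonpain": self.n_generalization_nonpain,
            "n_recipients_learning": self.n_recipients_learning,
        }
        for name, value in counts.items():
            if int(value) != value or value < 0:
                raise ConfigurationError(f"{name} must be a non-negative integer, got {value!r}")
        if self.pain_per_block > self.trials_per_block:
            raise ConfigurationError(
                f"pain_per_block ({self.pain_per_block}) exceeds trials_per_block "
                f"({self.trials_per_block})"
            )
        if self.n_learning_blocks < 1 or self.trials_per_block < 1:
            raise ConfigurationError("learning session must contain at least one block and trial")
        if self.n_recipients_learning < 1 or self.n_recipients_learning > self.n_learning_blocks:
            raise ConfigurationError(
                "n_recipients_learning must be between 1 and n_learning_blocks"
            )

    @property
    def n_learning_trials(self) -> int:
        return self.n_learning_blocks * self.trials_per_block

    @property
    def n_learning_pain(self) -> int:
        return self.n_learning_blocks * self.pain_per_block


@dataclass(frozen=True)
class Trial:
    """One experimental trial, the atomic record of every pipeline stage.

    ``demonstrator_rating`` and ``prediction`` are only defined for learning
    trials (``None`` elsewhere); all ratings live in [0, 100].
    """

    session: str
    trial_index: int  # 1-based position within its session
    pain: str
    recipient_id: str
    block: Optional[int] = None  # 1-based, learning session only
    demonstrator_rating: Optional[float] = None
    prediction: Optional[float] = None
    empathy_rating: Optional[float] = None


def _session_trials(rng: np.random.Generator, session: str, n_pain: int, n_nonpain: int,
                    recipient: str) -> list[Trial]:
    pains = [PAINFUL] * n_pain + [NONPAINFUL] * n_nonpain
    order = rng.permutation(len(pains))
    return [
        Trial(session=session, trial_index=i + 1, pain=pains[j], recipient_id=recipient)
        for i, j in enumerate(order)
    ]


def generate_schedule(spec: TrialScheduleSpec) -> list[Trial]:
    """Generate the full ordered trial list for one participant.

    The painful/non-painful order within each session (and within each
    learning block) is a seeded uniform permutation, so two calls with the
    same spec (including seed) return identical schedules.  Learning
    recipients are assigned contiguously, ``recipient_A`` for the first half
    of the blocks and ``recipient_B`` for the second (with the default two
    recipients over four blocks); generalization uses a fresh recipient.
    """
    rng = np.random.default_rng(spec.seed)
    trials: list[Trial] = []

    trials.extend(_session_trials(rng, BASELINE, spec.n_baseline_pain,
                                  spec.n_baseline_nonpain, "recipient_baseline"))

    blocks_per_recipient = math.ceil(spec.n_learning_blocks / spec.n_recipients_learning)
    nonpain_per_block = spec.trials_per_block - spec.pain_per_block
    t = 0
    for b in range(spec.n_learning_blocks):
        recipient = "recipient_" + chr(ord("A") + b // blocks_per_recipient)
        pains = [PAINFUL] * spec.pain_per_block + [NONPAINFUL] * nonpain_per_block
        order = rng.permutation(len(pains))
        for j in order:
            t += 1
            trials.append(Trial(session=LEARNING, trial_index=t, pain=pains[j],
                                recipient_id=recipient, block=b + 1))

    trials.extend(_session_trials(rng, GENERALIZATION, spec.n_generalization_pain,
                                  spec.n_generalization_nonpain, "recipient_new"))
    return trials


def learning_trials(schedule: list[Trial]) -> list[Trial]:
    """The learning-session trials of a schedule, in presentation order."""
    return [tr for tr in schedule if tr.session == LEARNING]
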