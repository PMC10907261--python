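"""Run configuration: YAML in, validated dataclasses out."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .design import TrialScheduleSpec
from .errors import ConfigurationError
from .simulate import CohortPriors


@dataclass(frozen=True)
class FittingOptions:
    models: tuple[str, ...] = ("M1_single", "M2_signsplit", "M3_signsplit_halfsplit")
    n_restarts: int = 10
    rw_trials: str = "all"
    half_boundary: int = 24


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run: a seed and the sub-configs."""

    seed: int = 0
    schedule: TrialScheduleSpec = field(default_factory=TrialScheduleSpec)
    priors: CohortPriors = field(default_factory=CohortPriors)
    n_per_group: int = 26
    groups: tuple[str, ...] = ("high", "low")
    generating_model: str = "M3_signsplit_halfsplit"
    fitting: FittingOptions = field(default_factory=FittingOptions)
    n_bms_samples: int = 100_000
    recovery_n_subjects: int = 50
    recovery_n_cohorts: int = 10
    output_dir: str = "runs/default"

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ConfigurationError(f"n_per_group must be >= 1, got {self.n_per_group}")
        if self.n_bms_samples < 1:
            raise ConfigurationError("n_bms_samples must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schedule"] = asdict(self.schedule)
        d["priors"] = asdict(self.priors)
        d["fitting"] = asdict(self.fitting)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _tuples(d: dict, keys: Sequence[str]) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def load_config(path: Union[str, Path, None] = None, overrides: Optional[dict] = None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file plus keyword overrides."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})

    schedule = TrialScheduleSpec(**raw.pop("schedule", {}))
    priors = CohortPriors(**_tuples(raw.pop("priors", {}), ()))
    fitting_kwargs = raw.pop("fitting", {})
    if "models" in fitting_kwargs:
        fitting_kwargs["models"] = tuple(fitting_kwargs["models"])
    fitting = FittingOptions(**fitting_kwargs)
    if "groups" in raw:
        raw["groups"] = tuple(raw["groups"])
    try:
        return RunConfig(schedule=schedule, priors=priors, fitting=fitting, **raw)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc


def with_seed(config: RunConfig, seed: Optional[int]) -> RunConfig:
    return config if seed is None else replace(config, seed=int(seed))
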