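"""Study configuration: grids, error rates, replicate rules and seeding.

A :class:`StudyConfig` captures the full simulation experiment — the pilot-size
grids for continuous and binary outcomes, the standardized effect sizes for
definitive-trial planning, the type-I error and target power, the confidence
level used for the variance inflation factor, and the master seed.  Defaults
reproduce the reference study conditions: balanced two-arm normal pilots of
10..80 per group in steps of 5 with 10,000 replicates each, and single-arm
binomial pilots of 10..200 in steps of 5 with true event rates 0.10..0.50 in
steps of 0.05, replicated until the event rate is estimated to within a
standard error of 0.001.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError

__all__ = ["StudyConfig", "load_config"]


def _default_normal_sizes() -> list[int]:
    return list(range(10, 81, 5))


def _default_binary_sizes() -> list[int]:
    return list(range(10, 201, 5))


def _default_thetas() -> list[float]:
    return [round(0.10 + 0.05 * k, 2) for k in range(9)]


@dataclass
class StudyConfig:
    """Full experiment specification.

    Attributes
    ----------
    normal_group_sizes : per-group sizes for the two-arm continuous pilots.
    normal_reps : Monte-Carlo replicates per continuous pilot size.
    true_mean, true_sd : the known truth under which pilots are simulated.
    binary_sizes : single-arm sizes for the binomial pilots.
    binary_thetas : true event rates studied.
    binary_se_target : the standard-error target that sets per-theta replicate
        counts (``ceil(theta*(1-theta)/se^2)``, floored at ``binary_min_reps``).
    effect_sizes : standardized effect sizes for definitive-trial planning.
    alpha : two-sided type-I error of the definitive trial.
    target_power : power the definitive trial is planned for.
    power_floor : power level used when reporting assurance.
    inflation_confidence : one-sided confidence level of the SD inflation factor.
    seed : master seed; every grid cell derives an independent substream.
    """

    normal_group_sizes: list[int] = field(default_factory=_default_normal_sizes)
    normal_reps: int = 10_000
    true_sd: float = 1.0
    true_mean: float = 0.0
    binary_sizes: list[int] = field(default_factory=_default_binary_sizes)
    binary_thetas: list[float] = field(default_factory=_default_thetas)
    binary_se_target: float = 0.001
    binary_min_reps: int = 10_000
    effect_sizes: list[float] = field(default_factory=lambda: [0.2, 0.35, 0.5])
    alpha: float = 0.05
    target_power: float = 0.90
    power_floor: float = 0.80
    inflation_confidence: float = 0.80
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.normal_group_sizes:
            raise ConfigError("normal_group_sizes: must be nonempty")
        for n in self.normal_group_sizes:
            if int(n) != n or n < 2:
                raise ConfigError(
                    f"normal_group_sizes: each size must be an integer >= 2, got {n!r}"
                )
        if self.normal_reps < 1:
            raise ConfigError(f"normal_reps: must be >= 1, got {self.normal_reps}")
        if not self.true_sd > 0:
            raise ConfigError(f"true_sd: must be positive, got {self.true_sd}")
        for n in self.binary_sizes:
            if int(n) != n or n < 1:
                raise ConfigError(
                    f"binary_sizes: each size must be an integer >= 1, got {n!r}"
                )
        for th in self.binary_thetas:
            if not 0.0 < th < 1.0:
                raise ConfigError(
                    f"binary_thetas: each theta must lie strictly in (0,1), got {th!r}"
                )
        if not self.binary_se_target > 0:
            raise ConfigError(
                f"binary_se_target: must be positive, got {self.binary_se_target}"
            )
        for d in self.effect_sizes:
            if not d > 0:
                raise ConfigError(f"effect_sizes: must be positive, got {d!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha: must lie in (0,1), got {self.alpha}")
        if not 0.0 < self.power_floor < self.target_power < 1.0:
            raise ConfigError(
                "target_power/power_floor: need 0 < power_floor < target_power < 1, "
                f"got floor={self.power_floor}, target={self.target_power}"
            )
        if not 0.5 <= self.inflation_confidence < 1.0:
            raise ConfigError(
                "inflation_confidence: must lie in [0.5, 1), "
                f"got {self.inflation_confidence}"
            )
        if not 0.0 < self.ci_level < 1.0:
            raise ConfigError(f"ci_level: must lie in (0,1), got {self.ci_level}")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


def load_config(path: str | Path, seed: int | None = None) -> StudyConfig:
    """Read a YAML or JSON config file; ``seed`` (if given) overrides the file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    cfg = StudyConfig.from_dict(data)
    if seed is not None:
        cfg.seed = int(seed)
    return cfg
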