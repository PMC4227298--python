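"""Definitive-trial planning from pilot SD estimates.

Sample sizes use the two-sample normal-approximation formula with per-group
ceiling rounding,

    n = ceil( 2 * (z_{1-alpha/2} + z_{power})^2 * sd^2 / delta^2 ),

where delta is the target mean difference (standardized when sd is the
population SD).  True power of a plan under the known truth is the matching
normal-approximation expression

    power = Phi( delta * sqrt(n/2) / sigma - z_{1-alpha/2} ),

ignoring the opposite-tail term Phi(-delta*sqrt(n/2)/sigma - z), which is
below 1e-4 in absolute value throughout the studied range.  A t-based variant
of the sample-size formula (noncentral iteration) is available behind
``use_t=True`` but is off by default: the normal approximation is the
convention that reproduces the standard 1,052-total benchmark for
delta = 0.2, sigma = 1, 90% power, 5% two-sided alpha.

Assurance — the probability over the pilot's sampling distribution that the
planned trial attains at least a stated power floor — is computed two ways:
exactly through the chi-square CDF of SD_p^2, and by Monte-Carlo over
simulated pilots.  The two must agree within sampling error; tests enforce it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidParameterError
from .sd_estimation import inflation_factor, pooled_sd
from .simulate import simulate_normal_pilot

__all__ = [
    "SampleSizePlans",
    "PlanningSummary",
    "required_sample_size",
    "true_power",
    "plan_from_pilot",
    "assurance",
    "summarize_plans",
]

logger = logging.getLogger(__name__)

PERCENTILES = (0.0, 2.5, 25.0, 50.0, 75.0, 97.5, 100.0)


@dataclass(frozen=True)
class SampleSizePlans:
    """A batch of definitive-trial plans, one per pilot replicate.

    ``n_excluded`` counts degenerate pilots (SD_p = 0) that were dropped; they
    cannot arise under the continuous model and signal upstream misuse.
    """

    effect_size: float
    alpha: float
    target_power: float
    inflated: bool
    sd_used: np.ndarray
    n_per_group: np.ndarray
    true_power: np.ndarray
    n_excluded: int = 0

    @property
    def n_total(self) -> np.ndarray:
        return 2 * self.n_per_group

    def __len__(self) -> int:
        return self.n_per_group.shape[0]


@dataclass(frozen=True)
class PlanningSummary:
    """Percentile summaries of power and size over a batch of plans."""

    pilot_total: int
    percentiles: tuple[float, ...]
    true_power: tuple[float, ...]
    n_total: tuple[float, ...]
    n_grand: tuple[float, ...]  # definitive total + pilot total
    assurance_at_floor: float
    power_floor: float
    n_plans: int
    n_excluded: int


def _check_probability(name: str, value: float) -> None:
    if not 0.0 < value < 1.0:
        raise InvalidParameterError(f"{name} must lie in (0,1), got {value}")


def _squared_z_sum(alpha: float, power: float) -> float:
    return (stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power)) ** 2


def required_sample_size(
    effect_size: float,
    sd: float = 1.0,
    alpha: float = 0.05,
    power: float = 0.90,
    *,
    use_t: bool = False,
) -> int:
    """Per-group sample size for a two-arm superiority trial (ceiling rule).

    Returns at least 2.  ``use_t=True`` iterates the noncentral-t power
    function instead of the normal approximation (slightly larger n).
    """
    if not effect_size > 0:
        raise InvalidParameterError(f"effect_size must be positive, got {effect_size}")
    if not sd > 0:
        raise InvalidParameterError(f"sd must be positive, got {sd}")
    _check_probability("alpha", alpha)
    _check_probability("power", power)
    n = max(2, math.ceil(2.0 * _squared_z_sum(alpha, power) * sd * sd / effect_size**2))
    if use_t:
        while _t_power(n, effect_size, sd, alpha) < power:
            n += 1
    return n


def _t_power(n: int, effect_size: float, sd: float, alpha: float) -> float:
    df = 2 * (n - 1)
    nc = effect_size / sd * math.sqrt(n / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, nc))


def true_power(n_per_group, effect_size: float, true_sd: float = 1.0, alpha: float = 0.05):
    """Normal-approximation power of a two-arm trial under the known true SD."""
    if not effect_size > 0:
        raise InvalidParameterError(f"effect_size must be positive, got {effect_size}")
    if not true_sd > 0:
        raise InvalidParameterError(f"true_sd must be positive, got {true_sd}")
    _check_probability("alpha", alpha)
    n = np.asarray(n_per_group, dtype=float)
    if np.any(n < 2):
        raise InvalidParameterError("n_per_group must be >= 2")
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    out = stats.norm.cdf(effect_size * np.sqrt(n / 2.0) / true_sd - z_crit)
    return out if out.ndim else float(out)


def plan_from_pilot(
    sd_p,
    df: int,
    effect_size: float,
    alpha: float = 0.05,
    target_power: float = 0.90,
    *,
    inflate: bool = False,
    inflation_confidence: float = 0.80,
    true_sd: float = 1.0,
) -> SampleSizePlans:
    """Plan one definitive trial per pilot SD estimate.

    ``sd_p`` is an array of pooled-SD estimates sharing the same pilot design
    (hence one ``df``).  With ``inflate`` the SD is first multiplied by the
    one-sided upper-confidence-limit factor at ``inflation_confidence``.
    True power is evaluated under ``true_sd``.
    """
    sd_p = np.atleast_1d(np.asarray(sd_p, dtype=float))
    if sd_p.size == 0:
        raise InvalidParameterError("plan_from_pilot requires a nonempty estimate batch")
    keep = sd_p > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.warning("excluding %d degenerate pilots with SD_p = 0", n_excluded)
    sd_used = sd_p[keep]
    if inflate:
        sd_used = sd_used * inflation_factor(df, inflation_confidence)
    a = 2.0 * _squared_z_sum(alpha, target_power) / effect_size**2
    n = np.maximum(2, np.ceil(a * sd_used**2).astype(int))
    return SampleSizePlans(
        effect_size=effect_size,
        alpha=alpha,
        target_power=target_power,
        inflated=inflate,
        sd_used=sd_used,
        n_per_group=n,
        true_power=np.asarray(true_power(n, effect_size, true_sd, alpha)),
        n_excluded=n_excluded,
    )


def _floor_n(effect_size: float, true_sd: float, alpha: float, power_floor: float) -> int:
    """Smallest per-group n whose true power reaches the floor."""
    return required_sample_size(effect_size, true_sd, alpha, power_floor)


def assurance(
    pilot_n_per_group: int,
    effect_size: float,
    alpha: float = 0.05,
    target_power: float = 0.90,
    power_floor: float = 0.80,
    *,
    inflate: bool = False,
    inflation_confidence: float = 0.80,
    true_sd: float = 1.0,
    method: str = "exact",
    n_reps: int = 100_000,
    seed: int = 0,
) -> float:
    """Probability that a pilot-planned trial attains at least ``power_floor``.

    ``method="exact"`` uses the chi-square sampling distribution of SD_p²:
    the plan reaches the floor iff its per-group n reaches the smallest n
    meeting the floor, which translates (through the ceiling rule) into a
    threshold on SD_p².  ``method="simulation"`` draws ``n_reps`` pilots and
    reports the empirical fraction; the two agree within Monte-Carlo error.
    """
    if pilot_n_per_group < 2:
        raise InvalidParameterError(
            f"pilot_n_per_group must be >= 2, got {pilot_n_per_group}"
        )
    if not 0.0 <= power_floor < 1.0:
        raise InvalidParameterError(f"power_floor must lie in [0,1), got {power_floor}")
    if power_floor == 0.0:
        return 1.0
    df = 2 * (pilot_n_per_group - 1)
    factor = inflation_factor(df, inflation_confidence) if inflate else 1.0
    if method == "exact":
        n_floor = _floor_n(effect_size, true_sd, alpha, power_floor)
        if n_floor <= 2:
            return 1.0
        # ceil(a * sd^2) >= n_floor  <=>  sd^2 > (n_floor - 1) / a
        a = 2.0 * _squared_z_sum(alpha, target_power) * factor**2 / effect_size**2
        threshold = (n_floor - 1) / a
        # SD_p^2 ~ sigma^2 * chi2_df / df
        return float(stats.chi2.sf(df * threshold / true_sd**2, df))
    if method == "simulation":
        reps = simulate_normal_pilot(
            pilot_n_per_group, n_reps, true_mean=0.0, true_sd=true_sd, seed=seed
        )
        plans = plan_from_pilot(
            pooled_sd(reps.s1_sq, reps.s2_sq),
            df,
            effect_size,
            alpha,
            target_power,
            inflate=inflate,
            inflation_confidence=inflation_confidence,
            true_sd=true_sd,
        )
        return float(np.mean(plans.true_power >= power_floor))
    raise InvalidParameterError(f"unknown method {method!r}")


def summarize_plans(
    plans: SampleSizePlans, pilot_total: int, power_floor: float = 0.80
) -> PlanningSummary:
    """Percentile summary of a plan batch (the data behind box-and-whisker plots)."""
    if len(plans) == 0:
        raise InvalidParameterError("no plans left to summarize after exclusions")
    qs = np.asarray(PERCENTILES)

    def pct(x: np.ndarray) -> tuple[float, ...]:
        return tuple(float(v) for v in np.percentile(x, qs))

    return PlanningSummary(
        pilot_total=int(pilot_total),
        percentiles=PERCENTILES,
        true_power=pct(plans.true_power),
        n_total=pct(plans.n_total),
        n_grand=pct(plans.n_total + pilot_total),
        assurance_at_floor=float(np.mean(plans.true_power >= power_floor)),
        power_floor=power_floor,
        n_plans=len(plans),
        n_excluded=plans.n_excluded,
    )
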