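"""Single-arm event-rate estimation with Wilson score intervals.

The Wilson score interval for an observed proportion ``theta_hat = y/n`` at
level ``1 - a`` has centre ``(theta_hat + z^2/2n) / (1 + z^2/n)`` and
half-width ``z * sqrt(theta_hat*(1-theta_hat)/n + z^2/4n^2) / (1 + z^2/n)``
with ``z`` the ``1 - a/2`` standard-normal quantile; it never leaves [0,1].
The normal quantile is used at full double precision rather than a rounded
1.96 so enumeration and Monte-Carlo summaries stay mutually consistent.

Because the outcome is a bounded count, every Monte-Carlo summary (mean
observed rate, mean interval width, bias, coverage) has an exact twin: a
pmf-weighted sum over y = 0..n.  Enumeration is the default and the oracle;
simulation mode mirrors the replicate-based study procedure and is retained
for seed-reproducible regression tests.

Coverage uses the closed-interval convention: an endpoint exactly equal to
the true rate counts as covering (this matters only at discreteness
boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidParameterError
from .sd_estimation import precision_gain
from .simulate import required_reps_binary, simulate_binomial_pilot

__all__ = [
    "ProportionEstimate",
    "BinomialPilotSummary",
    "wilson_interval",
    "wilson_bounds",
    "enumerate_binomial_expectation",
    "summarize_binomial_cell",
    "precision_gain_binary",
]


@dataclass(frozen=True)
class ProportionEstimate:
    """An observed proportion with its Wilson score interval."""

    n: int
    y: int
    theta_hat: float
    level: float
    wilson_lower: float
    wilson_upper: float

    @property
    def width(self) -> float:
        return self.wilson_upper - self.wilson_lower


@dataclass(frozen=True)
class BinomialPilotSummary:
    """Summaries for one (true rate, pilot size) cell.

    ``n_reps`` is the replicate count for simulation mode and 0 for exact
    enumeration (which has no Monte-Carlo error).
    """

    theta_true: float
    n: int
    n_reps: int
    level: float
    mean_theta_hat: float
    mean_width: float
    bias: float
    coverage: float
    method: str


def wilson_bounds(y, n: int, level: float = 0.95):
    """Vectorized Wilson score bounds; returns ``(lower, upper)`` arrays."""
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    if not 0.0 < level < 1.0:
        raise InvalidParameterError(f"level must lie in (0,1), got {level}")
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y > n):
        raise InvalidParameterError("y must lie in [0, n]")
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    th = y / n
    denom = 1.0 + z * z / n
    centre = (th + z * z / (2.0 * n)) / denom
    half = z * np.sqrt(th * (1.0 - th) / n + z * z / (4.0 * n * n)) / denom
    # clamping is a no-op for the score interval analytically, but guards
    # floating-point residue at y=0 and y=n; the interval always contains
    # the point estimate, so snap to it as well
    lower = np.minimum(np.clip(centre - half, 0.0, 1.0), th)
    upper = np.maximum(np.clip(centre + half, 0.0, 1.0), th)
    return lower, upper


def wilson_interval(y: int, n: int, level: float = 0.95) -> ProportionEstimate:
    """Wilson score interval for ``y`` successes out of ``n``."""
    lo, hi = wilson_bounds(float(y), n, level)
    return ProportionEstimate(
        n=int(n),
        y=int(y),
        theta_hat=y / n,
        level=level,
        wilson_lower=float(lo),
        wilson_upper=float(hi),
    )


def _per_outcome(n: int, theta: float, level: float):
    ys = np.arange(n + 1)
    lo, hi = wilson_bounds(ys, n, level)
    widths = hi - lo
    covers = (lo <= theta) & (theta <= hi)
    return ys, widths, covers


def enumerate_binomial_expectation(
    theta: float, n: int, quantity: str, level: float = 0.95
) -> float:
    """Exact expectation of a per-outcome quantity under Binomial(n, theta).

    ``quantity`` is one of ``"theta_hat"``, ``"width"``, ``"coverage"``; the
    result is the pmf-weighted sum over all n+1 outcomes.
    """
    if not 0.0 < theta < 1.0:
        raise InvalidParameterError(f"theta must lie strictly in (0,1), got {theta}")
    ys, widths, covers = _per_outcome(n, theta, level)
    pmf = stats.binom.pmf(ys, n, theta)
    if quantity == "theta_hat":
        values = ys / n
    elif quantity == "width":
        values = widths
    elif quantity == "coverage":
        values = covers.astype(float)
    else:
        raise InvalidParameterError(
            f"quantity must be 'theta_hat', 'width' or 'coverage', got {quantity!r}"
        )
    return float(np.sum(pmf * values))


def summarize_binomial_cell(
    theta: float,
    n: int,
    n_reps: int | None = None,
    level: float = 0.95,
    seed: int = 0,
    *,
    method: str = "enumeration",
    se_target: float = 0.001,
    min_reps: int = 10_000,
) -> BinomialPilotSummary:
    """Mean rate, mean Wilson width, bias and coverage for one grid cell.

    Enumeration (default) computes the exact binomial expectations.
    Simulation draws ``n_reps`` pilots (default: the standard-error rule
    ``ceil(theta(1-theta)/se_target^2)`` floored at ``min_reps``) and reports
    empirical means; it converges to the enumeration values.
    """
    if method == "enumeration":
        mean_th = enumerate_binomial_expectation(theta, n, "theta_hat", level)
        return BinomialPilotSummary(
            theta_true=theta,
            n=n,
            n_reps=0,
            level=level,
            mean_theta_hat=mean_th,
            mean_width=enumerate_binomial_expectation(theta, n, "width", level),
            bias=mean_th - theta,
            coverage=enumerate_binomial_expectation(theta, n, "coverage", level),
            method=method,
        )
    if method != "simulation":
        raise InvalidParameterError(f"unknown method {method!r}")
    if n_reps is None:
        n_reps = max(min_reps, required_reps_binary(theta, se_target))
    reps = simulate_binomial_pilot(n, theta, n_reps, seed)
    _, widths, covers = _per_outcome(n, theta, level)
    mean_th = float(np.mean(reps.theta_hat))
    return BinomialPilotSummary(
        theta_true=theta,
        n=n,
        n_reps=n_reps,
        level=level,
        mean_theta_hat=mean_th,
        mean_width=float(np.mean(widths[reps.y])),
        bias=mean_th - theta,
        coverage=float(np.mean(covers[reps.y])),
        method=method,
    )


def precision_gain_binary(width_at_n: float, width_at_n_plus_5: float) -> float:
    """Percentage reduction in mean Wilson width per five added subjects."""
    return precision_gain(width_at_n, width_at_n_plus_5)
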