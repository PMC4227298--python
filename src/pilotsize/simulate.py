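"""Synthetic pilot-trial generators.

Two kinds of pilot are simulated, matching the statistical structure the
downstream analysis assumes:

* balanced two-arm pilots with a normally distributed outcome (true mean 0,
  true SD 1 by default), reduced to the two per-arm unbiased sample variances
  — the sufficient statistics for everything downstream;
* single-arm pilots with a binary outcome, reduced to the success count
  ``Y ~ Binomial(n, theta)``.

Reproducibility: a master seed plus a tuple of string/number tokens is hashed
into a :class:`numpy.random.SeedSequence`, so every grid cell owns an
independent substream and cells can be computed in any order with identical
results.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidDesignError, InvalidParameterError

__all__ = [
    "NormalPilotReplicates",
    "BinomialPilotReplicates",
    "substream",
    "simulate_normal_pilot",
    "simulate_binomial_pilot",
    "required_reps_binary",
]

# Cap on elements drawn per chunk so large replicate counts stay in ~128 MB.
_CHUNK_ELEMENTS = 16_000_000


def substream(seed: int, *tokens: object) -> np.random.Generator:
    """Derive an independent, order-free random substream from a master seed.

    The tokens (cell identifiers such as ``("normal", n)`` or
    ``("binary", n, theta)``) are hashed with SHA-256 into extra entropy words,
    so distinct cells get statistically independent streams and the same cell
    always gets the same stream regardless of evaluation order.
    """
    digest = hashlib.sha256(repr(tokens).encode()).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *words]))


@dataclass(frozen=True)
class NormalPilotReplicates:
    """A batch of simulated two-arm normal pilots, stored as variance summaries.

    ``s1_sq``/``s2_sq`` are the unbiased (n−1 denominator) sample variances of
    the two arms, one entry per replicate.
    """

    n_per_group: int
    s1_sq: np.ndarray
    s2_sq: np.ndarray
    true_mean: float = 0.0
    true_sd: float = 1.0
    raw: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return self.s1_sq.shape[0]

    @property
    def df(self) -> int:
        """Degrees of freedom of the pooled variance: 2(n−1)."""
        return 2 * (self.n_per_group - 1)


@dataclass(frozen=True)
class BinomialPilotReplicates:
    """A batch of simulated single-arm binomial pilots (success counts)."""

    n: int
    theta_true: float
    y: np.ndarray

    def __len__(self) -> int:
        return self.y.shape[0]

    @property
    def theta_hat(self) -> np.ndarray:
        return self.y / self.n


def simulate_normal_pilot(
    n_per_group: int,
    n_reps: int,
    true_mean: float = 0.0,
    true_sd: float = 1.0,
    seed: int = 0,
    *,
    rng: np.random.Generator | None = None,
    keep_raw: bool = False,
) -> NormalPilotReplicates:
    """Simulate balanced two-arm normal pilots and return per-arm variances.

    Parameters
    ----------
    n_per_group : subjects per arm (>= 2, one variance df per arm required).
    n_reps : number of independent replicate pilot trials.
    true_mean, true_sd : common population mean and SD of both arms.
    seed : master seed; ignored when an explicit ``rng`` is supplied.
    keep_raw : also retain the raw outcome vectors (debugging only; memory
        scales with ``n_reps * n_per_group``).
    """
    if n_per_group < 2:
        raise InvalidDesignError(
            f"n_per_group must be >= 2 for a pooled variance, got {n_per_group}"
        )
    if n_reps < 1:
        raise InvalidParameterError(f"n_reps must be >= 1, got {n_reps}")
    if not true_sd > 0:
        raise InvalidParameterError(f"true_sd must be positive, got {true_sd}")
    if rng is None:
        rng = substream(seed, "normal", int(n_per_group))

    s1 = np.empty(n_reps)
    s2 = np.empty(n_reps)
    raw_chunks: list[np.ndarray] = []
    chunk = max(1, _CHUNK_ELEMENTS // (2 * n_per_group))
    start = 0
    while start < n_reps:
        stop = min(start + chunk, n_reps)
        draws = rng.normal(true_mean, true_sd, size=(stop - start, 2, n_per_group))
        v = draws.var(axis=2, ddof=1)
        s1[start:stop] = v[:, 0]
        s2[start:stop] = v[:, 1]
        if keep_raw:
            raw_chunks.append(draws)
        start = stop
    raw = None
    if keep_raw:
        stacked = np.concatenate(raw_chunks, axis=0)
        raw = (stacked[:, 0, :], stacked[:, 1, :])
    return NormalPilotReplicates(
        n_per_group=int(n_per_group),
        s1_sq=s1,
        s2_sq=s2,
        true_mean=float(true_mean),
        true_sd=float(true_sd),
        raw=raw,
    )


def simulate_binomial_pilot(
    n: int,
    theta: float,
    n_reps: int,
    seed: int = 0,
    *,
    rng: np.random.Generator | None = None,
) -> BinomialPilotReplicates:
    """Simulate single-arm binomial pilots: i.i.d. success counts Bin(n, theta)."""
    if n < 1:
        raise InvalidDesignError(f"n must be >= 1, got {n}")
    if not 0.0 < theta < 1.0:
        raise InvalidParameterError(f"theta must lie strictly in (0,1), got {theta}")
    if n_reps < 1:
        raise InvalidParameterError(f"n_reps must be >= 1, got {n_reps}")
    if rng is None:
        rng = substream(seed, "binary", int(n), float(theta))
    y = rng.binomial(int(n), float(theta), size=int(n_reps))
    return BinomialPilotReplicates(n=int(n), theta_true=float(theta), y=y)


def required_reps_binary(theta: float, se_target: float) -> int:
    """Smallest replicate count estimating ``theta`` to within ``se_target``.

    Returns the least integer N with ``sqrt(theta*(1-theta)/N) <= se_target``,
    i.e. the ceiling of ``theta*(1-theta)/se_target**2`` (a tiny relative
    tolerance absorbs floating-point noise at exact ceilings).
    """
    if not 0.0 < theta < 1.0:
        raise InvalidParameterError(f"theta must lie strictly in (0,1), got {theta}")
    if not se_target > 0:
        raise InvalidParameterError(f"se_target must be positive, got {se_target}")
    var = theta * (1.0 - theta)
    n = max(1, math.floor(var / se_target**2))
    if var / n > se_target**2 * (1.0 + 1e-12):
        n += 1
    return n
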