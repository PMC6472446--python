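"""Dirichlet-process prior over divergence models and parameter priors.

The number of divergence events and the assignment of population pairs to
those events are treated as random under a Dirichlet process (DP) with
concentration parameter ``alpha`` and base distribution ``H`` on event
times.  Marginalizing the DP over event times induces the Chinese
restaurant process (CRP) on set partitions of the pairs.

Partitions are encoded as restricted-growth strings (RGS): pair 0 is
always assigned event 0, and each subsequent pair is assigned either an
event index already in use or the smallest unused index.  This gives a
unique canonical label for every divergence model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import special, stats

__all__ = [
    "GammaPrior",
    "BetaPrior",
    "PriorConfig",
    "stirling2",
    "bell_number",
    "canonical_partition",
    "crp_partition_log_prob",
    "expected_num_events",
    "sample_partition",
    "dp_prior_k_probs",
    "log_prior_density",
]


# ---------------------------------------------------------------------------
# Prior distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaPrior:
    """Gamma distribution parameterized by (shape, mean), as priors are
    reported in this field; mean = shape * scale.

    An exponential prior with a given mean is ``GammaPrior(1.0, mean)``.
    """

    shape: float
    mean: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.mean <= 0:
            raise ValueError("gamma prior requires shape > 0 and mean > 0")

    @property
    def scale(self) -> float:
        return self.mean / self.shape

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -math.inf
        a, s = self.shape, self.scale
        return (a - 1.0) * math.log(x) - x / s - math.lgamma(a) - a * math.log(s)

    def draw(self, rng: np.random.Generator, size=None):
        return rng.gamma(self.shape, self.scale, size=size)


@dataclass(frozen=True)
class BetaPrior:
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("beta prior requires positive parameters")

    def logpdf(self, x: float) -> float:
        if not 0.0 < x < 1.0:
            return -math.inf
        return stats.beta.logpdf(x, self.alpha, self.beta)

    def draw(self, rng: np.random.Generator, size=None):
        return rng.beta(self.alpha, self.beta, size=size)


@dataclass(frozen=True)
class PriorConfig:
    """Priors for the divergence-model and nuisance parameters.

    ``tau_prior`` is the DP base distribution H (gamma on event times,
    shape 1 for the exponential priors used throughout the simulation
    studies).  Descendant effective sizes (``N_e * mu``) get a gamma
    prior or a fixed value; the root size is parameterized *relative* to
    the mean of the two descendant sizes.  ``pi`` (stationary frequency
    of the "green" state) is fixed (recommended 0.5 for recoded SNPs) or
    beta-distributed.  ``alpha`` is fixed or gamma-distributed.
    """

    tau_prior: GammaPrior = GammaPrior(1.0, 0.01)
    descendant_size_prior: Union[GammaPrior, float] = GammaPrior(5.0, 0.002)
    relative_root_size_prior: Union[GammaPrior, float] = GammaPrior(100.0, 1.0)
    pi_prior: Union[BetaPrior, float] = 0.5
    alpha: Union[GammaPrior, float] = 1.414216

    @property
    def alpha_is_fixed(self) -> bool:
        return not isinstance(self.alpha, GammaPrior)

    @property
    def pi_is_fixed(self) -> bool:
        return not isinstance(self.pi_prior, BetaPrior)

    @property
    def sizes_are_fixed(self) -> bool:
        return not isinstance(self.descendant_size_prior, GammaPrior)

    @property
    def root_size_is_fixed(self) -> bool:
        return not isinstance(self.relative_root_size_prior, GammaPrior)


# ---------------------------------------------------------------------------
# Partition combinatorics
# ---------------------------------------------------------------------------

def stirling2(n: int, k: int) -> int:
    """Number of ways to partition ``n`` pairs into exactly ``k``
    non-empty divergence events (Stirling number of the second kind)."""
    if k < 1 or k > n:
        raise ValueError(f"require 1 <= k <= n, got n={n}, k={k}")
    total = 0
    for i in range(k + 1):
        total += (-1) ** i * math.comb(k, i) * (k - i) ** n
    return total // math.factorial(k)


def bell_number(n: int) -> int:
    """Total number of divergence models for ``n`` pairs."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return sum(stirling2(n, k) for k in range(1, n + 1))


def canonical_partition(assignment: Sequence[int]) -> tuple[int, ...]:
    """Relabel event indices into restricted-growth (first-appearance) order."""
    mapping: dict[int, int] = {}
    out = []
    for a in assignment:
        if a not in mapping:
            mapping[a] = len(mapping)
        out.append(mapping[a])
    return tuple(out)


def partition_sizes(assignment: Sequence[int]) -> list[int]:
    canon = canonical_partition(assignment)
    k = max(canon) + 1
    sizes = [0] * k
    for a in canon:
        sizes[a] += 1
    return sizes


def crp_partition_log_prob(assignment: Sequence[int], alpha: float) -> float:
    """Log CRP probability of an unordered set partition of the pairs.

    p(partition) = alpha^k * prod_c (|c| - 1)! / prod_{i=0}^{N-1} (alpha + i)
    which for two pairs sharing one event reduces to 1 / (1 + alpha).
    """
    if len(assignment) == 0:
        raise ValueError("empty partition")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    sizes = partition_sizes(assignment)
    n = len(assignment)
    k = len(sizes)
    lp = k * math.log(alpha)
    for s in sizes:
        lp += math.lgamma(s)
    lp += math.lgamma(alpha) - math.lgamma(alpha + n)
    return lp


def expected_num_events(n: int, alpha: float) -> float:
    """Prior mean of k under the CRP: sum_{i=1..n} alpha / (alpha + i - 1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return float(sum(alpha / (alpha + i) for i in range(n)))


def sample_partition(n: int, alpha: float, rng: np.random.Generator) -> tuple[int, ...]:
    """Draw a partition of ``n`` pairs by sequential CRP seating."""
    assignment = [0]
    counts = [1]
    for i in range(1, n):
        probs = np.array(counts + [alpha], dtype=float)
        choice = rng.choice(len(probs), p=probs / probs.sum())
        if choice == len(counts):
            counts.append(1)
        else:
            counts[choice] += 1
        assignment.append(int(choice))
    return canonical_partition(assignment)


def dp_prior_k_probs(
    n: int,
    alpha: Union[float, GammaPrior],
    n_sims: int = 100_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Monte-Carlo prior probabilities of k = 1..n divergence events.

    When ``alpha`` carries a gamma hyperprior, a fresh concentration is
    drawn for every simulated partition, marginalizing over it.
    Returns an array ``p`` with ``p[k-1] = Pr(k events)``.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    hyper = isinstance(alpha, GammaPrior)
    counts = np.zeros(n, dtype=np.int64)
    # Vectorized sequential CRP seating over all simulations at once.
    k_now = np.ones(n_sims, dtype=np.int64)
    if hyper:
        alphas = alpha.draw(rng, size=n_sims)
    else:
        alphas = np.full(n_sims, float(alpha))
    for i in range(1, n):
        # a new event is opened with probability alpha / (alpha + i)
        p_new = alphas / (alphas + i)
        k_now += rng.random(n_sims) < p_new
    np.add.at(counts, k_now - 1, 1)
    return counts / n_sims


# ---------------------------------------------------------------------------
# Joint prior density
# ---------------------------------------------------------------------------

def log_prior_density(
    config: PriorConfig,
    partition: Sequence[int],
    event_times: Sequence[float],
    descendant_sizes: Sequence[Sequence[float]],
    relative_root_sizes: Sequence[float],
    pis: Optional[Sequence[float]] = None,
    alpha: Optional[float] = None,
) -> float:
    """Joint log prior: CRP partition term, gamma densities of the event
    times, descendant sizes and relative root sizes, plus beta / gamma
    terms for pi and alpha when they are free.  Returns -inf out of
    support."""
    if alpha is None:
        if not config.alpha_is_fixed:
            raise ValueError("alpha value required when alpha has a hyperprior")
        alpha_val = float(config.alpha)
    else:
        alpha_val = float(alpha)

    k = max(canonical_partition(partition)) + 1
    if len(event_times) != k:
        raise ValueError("event_times length does not match partition")

    lp = crp_partition_log_prob(partition, alpha_val)
    for tau in event_times:
        lp += config.tau_prior.logpdf(tau)
    if not config.sizes_are_fixed:
        for pair_sizes in descendant_sizes:
            for s in pair_sizes:
                lp += config.descendant_size_prior.logpdf(s)
    if not config.root_size_is_fixed:
        for r in relative_root_sizes:
            lp += config.relative_root_size_prior.logpdf(r)
    if not config.pi_is_fixed:
        if pis is None:
            raise ValueError("pi values required when pi is free")
        for p in pis:
            lp += config.pi_prior.logpdf(p)
    if not config.alpha_is_fixed:
        lp += config.alpha.logpdf(alpha_val)
    return lp
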