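"""Coalescent simulation of biallelic characters for pairs of populations.

For each gene tree, lineages sampled from the two descendant populations
coalesce within their own population (pairwise rate 1/(2N)) until the
divergence time, after which the survivors coalesce freely in the root
population.  Characters evolve along the tree under the two-state
mutation model, with the root lineage drawn from the stationary state
distribution.  ``sites_per_tree > 1`` produces linked characters that
share a gene tree, mimicking multi-site loci.

A vectorized numba path does the heavy lifting for large datasets; a
plain-Python gene-tree API mirrors it for inspection and testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .data import AllelePattern, ComparisonData, ComparisonCollection
from .likelihood import MutationModel, PairDemography
from .priors import PriorConfig, GammaPrior, BetaPrior, sample_partition

__all__ = [
    "GeneTree",
    "simulate_gene_tree",
    "mutate_on_tree",
    "simulate_locus",
    "simulate_pair_sites",
    "apply_missingness",
    "apply_singleton_filter",
    "counts_to_comparison",
    "SimulationTruth",
    "draw_truth_from_prior",
    "simulate_collection",
    "write_nexus",
]


# ---------------------------------------------------------------------------
# Python gene-tree reference implementation
# ---------------------------------------------------------------------------

@dataclass
class GeneTree:
    """A coalescent gene tree for one pair.

    Tips are nodes ``0 .. n1-1`` (population 1) and ``n1 .. n1+n2-1``
    (population 2); internal nodes are appended in coalescence order, so
    every parent index exceeds its children's and the root is the last
    node.  ``branch_lengths[i]`` is the time from node ``i`` up to its
    parent (undefined for the root).
    """

    n1: int
    n2: int
    parent: np.ndarray
    node_times: np.ndarray

    @property
    def n_tips(self) -> int:
        return self.n1 + self.n2

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def branch_lengths(self) -> np.ndarray:
        b = np.zeros(self.n_nodes)
        idx = np.arange(self.n_nodes - 1)
        b[idx] = self.node_times[self.parent[idx]] - self.node_times[idx]
        return b

    def total_length(self) -> float:
        return float(self.branch_lengths[:-1].sum())


def _coalesce_phase(
    active: list[int],
    node_times: list[float],
    parent: list[int],
    N: float,
    start: float,
    end: float,
    rng: np.random.Generator,
) -> None:
    """Coalesce the active lineages at pairwise rate 1/(2N) from
    ``start`` until ``end`` (or until one lineage remains)."""
    t = start
    while len(active) > 1:
        k = len(active)
        rate = k * (k - 1) / 2.0 / (2.0 * N)
        t = t + rng.exponential(1.0 / rate)
        if t > end:
            return
        a, b = rng.choice(k, size=2, replace=False)
        new = len(parent)
        parent.append(-1)
        node_times.append(t)
        parent[active[a]] = new
        parent[active[b]] = new
        hi, lo = max(a, b), min(a, b)
        active[lo] = new
        active.pop(hi)


def simulate_gene_tree(
    n1: int, n2: int, demog: PairDemography, rng: np.random.Generator
) -> GeneTree:
    """Draw one gene tree under the pair's species tree."""
    if n1 + n2 < 1:
        raise ValueError("need at least one sampled copy")
    n_tips = n1 + n2
    parent = [-1] * n_tips
    node_times = [0.0] * n_tips
    survivors: list[int] = []
    for tips, N in (
        (list(range(n1)), demog.N_d1),
        (list(range(n1, n_tips)), demog.N_d2),
    ):
        if not tips:
            continue
        _coalesce_phase(tips, node_times, parent, N, 0.0, demog.div_time, rng)
        survivors.extend(tips)
    _coalesce_phase(
        survivors, node_times, parent, demog.N_root, demog.div_time, math.inf, rng
    )
    return GeneTree(n1, n2, np.array(parent), np.array(node_times))


def mutate_on_tree(
    tree: GeneTree, model: MutationModel, rng: np.random.Generator
) -> np.ndarray:
    """Evolve one character down the tree; returns tip states
    (1 = red, 0 = green).  The root lineage is stationary."""
    rate = model.u + model.v
    p_red = model.stationary_red
    states = np.empty(tree.n_nodes, dtype=np.int8)
    states[tree.root] = 1 if rng.random() < p_red else 0
    blen = tree.branch_lengths
    for i in range(tree.n_nodes - 2, -1, -1):
        e = math.exp(-rate * blen[i])
        if states[tree.parent[i]] == 1:
            p = p_red + (1.0 - p_red) * e
        else:
            p = p_red * (1.0 - e)
        states[i] = 1 if rng.random() < p else 0
    return states[: tree.n_tips]


def simulate_locus(
    tree: GeneTree, length: int, model: MutationModel, rng: np.random.Generator
) -> np.ndarray:
    """Evolve ``length`` linked characters along one gene tree; returns
    a (length, n_tips) matrix of tip states."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return np.stack([mutate_on_tree(tree, model, rng) for _ in range(length)])


# ---------------------------------------------------------------------------
# Numba bulk path
# ---------------------------------------------------------------------------

@njit(cache=True)
def _build_tree_kernel(n1, n2, t, Nr, N1, N2, parent, node_time, active, local):  # pragma: no cover
    ntips = n1 + n2
    n_surv = 0
    nxt = ntips
    for which in range(2):
        if which == 0:
            k0, k = 0, n1
            N = N1
        else:
            k0, k = n1, n2
            N = N2
        if k == 0:
            continue
        for i in range(k):
            local[i] = k0 + i
            node_time[k0 + i] = 0.0
        cur = 0.0
        while k > 1:
            rate = k * (k - 1) / 2.0 / (2.0 * N)
            cur += np.random.exponential(1.0 / rate)
            if cur > t:
                break
            a = np.random.randint(k)
            b = np.random.randint(k - 1)
            if b >= a:
                b += 1
            parent[local[a]] = nxt
            parent[local[b]] = nxt
            node_time[nxt] = cur
            lo = a if a < b else b
            hi = b if a < b else a
            local[lo] = nxt
            local[hi] = local[k - 1]
            k -= 1
            nxt += 1
        for i in range(k):
            active[n_surv] = local[i]
            n_surv += 1
    cur = t
    k = n_surv
    while k > 1:
        rate = k * (k - 1) / 2.0 / (2.0 * Nr)
        cur += np.random.exponential(1.0 / rate)
        a = np.random.randint(k)
        b = np.random.randint(k - 1)
        if b >= a:
            b += 1
        parent[active[a]] = nxt
        parent[active[b]] = nxt
        node_time[nxt] = cur
        lo = a if a < b else b
        hi = b if a < b else a
        active[lo] = nxt
        active[hi] = active[k - 1]
        k -= 1
        nxt += 1
    parent[nxt - 1] = -1
    return nxt


@njit(cache=True)
def _simulate_pair_kernel(
    n1, n2, t, Nr, N1, N2, u, v, n_trees, sites_per_tree, seed
):  # pragma: no cover
    np.random.seed(seed)
    ntips = n1 + n2
    rate = u + v
    p_red = v / (u + v)
    out = np.empty((n_trees * sites_per_tree, ntips), np.int8)
    parent = np.empty(2 * ntips - 1 if ntips > 1 else 1, np.int64)
    node_time = np.empty(parent.shape[0], np.float64)
    states = np.empty(parent.shape[0], np.int8)
    e_branch = np.empty(parent.shape[0], np.float64)
    active = np.empty(ntips, np.int64)
    local = np.empty(ntips, np.int64)
    row = 0
    for _ in range(n_trees):
        n_nodes = _build_tree_kernel(
            n1, n2, t, Nr, N1, N2, parent, node_time, active, local
        )
        for i in range(n_nodes - 1):
            e_branch[i] = np.exp(-rate * (node_time[parent[i]] - node_time[i]))
        for _ in range(sites_per_tree):
            states[n_nodes - 1] = 1 if np.random.random() < p_red else 0
            for i in range(n_nodes - 2, -1, -1):
                e = e_branch[i]
                if states[parent[i]] == 1:
                    p = p_red + (1.0 - p_red) * e
                else:
                    p = p_red * (1.0 - e)
                states[i] = 1 if np.random.random() < p else 0
            for j in range(ntips):
                out[row, j] = states[j]
            row += 1
    return out


def simulate_pair_sites(
    n1: int,
    n2: int,
    demog: PairDemography,
    model: MutationModel,
    n_trees: int,
    sites_per_tree: int = 1,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Simulate ``n_trees * sites_per_tree`` characters; rows are sites
    (consecutive blocks of ``sites_per_tree`` share a gene tree), columns
    the ``n1 + n2`` sampled copies, entries 1 = red / 0 = green."""
    if n1 < 0 or n2 < 0 or n1 + n2 < 1:
        raise ValueError("need at least one sampled copy")
    if n_trees < 1 or sites_per_tree < 1:
        raise ValueError("n_trees and sites_per_tree must be >= 1")
    if rng is not None:
        seed = int(rng.integers(0, 2**31 - 1))
    elif seed is None:
        seed = int(np.random.default_rng().integers(0, 2**31 - 1))
    return _simulate_pair_kernel(
        n1, n2, demog.div_time, demog.N_root, demog.N_d1, demog.N_d2,
        model.u, model.v, n_trees, sites_per_tree, seed,
    )


# ---------------------------------------------------------------------------
# Post-processing: missingness, singleton filtering, aggregation
# ---------------------------------------------------------------------------

def apply_missingness(
    n1: np.ndarray, r1: np.ndarray, n2: np.ndarray, r2: np.ndarray,
    p_sample: float, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Each sampled copy is independently observed with probability
    ``p_sample``; red counts follow by hypergeometric subsampling."""
    if not 0.0 < p_sample <= 1.0:
        raise ValueError("p_sample must be in (0, 1]")
    if p_sample == 1.0:
        return n1, r1, n2, r2
    n1o = rng.binomial(n1, p_sample)
    n2o = rng.binomial(n2, p_sample)
    r1o = rng.hypergeometric(r1, n1 - r1, np.maximum(n1o, 1))
    r2o = rng.hypergeometric(r2, n2 - r2, np.maximum(n2o, 1))
    r1o = np.where(n1o > 0, r1o, 0)
    r2o = np.where(n2o > 0, r2o, 0)
    return n1o, r1o, n2o, r2o


def apply_singleton_filter(
    n1: np.ndarray, r1: np.ndarray, n2: np.ndarray, r2: np.ndarray,
    p_retain: float, rng: np.random.Generator,
) -> np.ndarray:
    """Boolean keep-mask: characters whose rarer allele occurs in exactly
    one copy (pooled across both populations) are retained with
    probability ``p_retain``; all others are kept.  Models acquisition
    bias against singleton polymorphisms."""
    if not 0.0 <= p_retain <= 1.0:
        raise ValueError("p_retain must be in [0, 1]")
    n = n1 + n2
    r = r1 + r2
    singleton = (r == 1) | (n - r == 1)
    keep = np.ones(len(n), dtype=bool)
    if p_retain < 1.0:
        keep[singleton] = rng.random(int(singleton.sum())) < p_retain
    return keep


def counts_to_comparison(
    n1: np.ndarray, r1: np.ndarray, n2: np.ndarray, r2: np.ndarray,
    label: str,
    drop_constant: bool = False,
) -> ComparisonData:
    """Aggregate per-site counts into weighted allele patterns."""
    ok = (n1 + n2) > 0
    arr = np.stack([n1[ok], r1[ok], n2[ok], r2[ok]], axis=1)
    uniq, counts = np.unique(arr, axis=0, return_counts=True)
    patterns = []
    for (a, b, c, d), w in zip(uniq, counts):
        p = AllelePattern(int(a), int(b), int(c), int(d), int(w))
        if drop_constant and p.is_constant:
            continue
        patterns.append(p)
    return ComparisonData(
        label=label,
        patterns=patterns,
        constant_removed=drop_constant,
        polyallelic_policy_applied="none",
    )


# ---------------------------------------------------------------------------
# Drawing full models from the prior and simulating collections
# ---------------------------------------------------------------------------

@dataclass
class SimulationTruth:
    """The generating model of a simulated dataset."""

    partition: tuple[int, ...]
    event_times: tuple[float, ...]
    demographies: tuple[PairDemography, ...]
    models: tuple[MutationModel, ...]
    alpha: Optional[float] = None

    @property
    def n_events(self) -> int:
        return max(self.partition) + 1

    @property
    def pair_times(self) -> tuple[float, ...]:
        return tuple(self.event_times[a] for a in self.partition)

    def to_dict(self) -> dict:
        return {
            "partition": list(self.partition),
            "event_times": [float(t) for t in self.event_times],
            "alpha": self.alpha,
            "pairs": [
                {
                    "div_time": d.div_time,
                    "N_root": d.N_root,
                    "N_d1": d.N_d1,
                    "N_d2": d.N_d2,
                    "freq_1": m.pi,
                }
                for d, m in zip(self.demographies, self.models)
            ],
        }


def draw_truth_from_prior(
    priors: PriorConfig, n_pairs: int, rng: np.random.Generator
) -> SimulationTruth:
    """Draw a divergence model and all pair parameters from the prior."""
    if isinstance(priors.alpha, GammaPrior):
        alpha = float(priors.alpha.draw(rng))
    else:
        alpha = float(priors.alpha)
    partition = sample_partition(n_pairs, alpha, rng)
    k = max(partition) + 1
    times = tuple(float(priors.tau_prior.draw(rng)) for _ in range(k))
    demogs = []
    models = []
    for a in partition:
        if isinstance(priors.descendant_size_prior, GammaPrior):
            nd1 = float(priors.descendant_size_prior.draw(rng))
            nd2 = float(priors.descendant_size_prior.draw(rng))
        else:
            nd1 = nd2 = float(priors.descendant_size_prior)
        if isinstance(priors.relative_root_size_prior, GammaPrior):
            rel = float(priors.relative_root_size_prior.draw(rng))
        else:
            rel = float(priors.relative_root_size_prior)
        demogs.append(PairDemography.from_relative_root(times[a], rel, nd1, nd2))
        if isinstance(priors.pi_prior, BetaPrior):
            pi = float(priors.pi_prior.draw(rng))
        else:
            pi = float(priors.pi_prior)
        models.append(MutationModel(pi=pi))
    return SimulationTruth(
        partition=partition,
        event_times=times,
        demographies=tuple(demogs),
        models=tuple(models),
        alpha=alpha,
    )


def simulate_collection(
    truth: SimulationTruth,
    samples_per_population: int | Sequence[tuple[int, int]],
    n_trees: int,
    sites_per_tree: int = 1,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    p_sample: float = 1.0,
    singleton_retain: float = 1.0,
    drop_constant: bool = False,
    labels: Optional[Sequence[str]] = None,
) -> ComparisonCollection:
    """Simulate a full multi-pair dataset under a known truth.

    ``n_trees`` gene trees per pair, each carrying ``sites_per_tree``
    linked characters.  Missingness and singleton filtering are applied
    per character before patterns are aggregated.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n_pairs = len(truth.demographies)
    if isinstance(samples_per_population, int):
        sizes = [(samples_per_population, samples_per_population)] * n_pairs
    else:
        sizes = list(samples_per_population)
    if labels is None:
        labels = [f"pair{i}" for i in range(n_pairs)]
    comparisons = []
    for i, (demog, model) in enumerate(zip(truth.demographies, truth.models)):
        s1, s2 = sizes[i]
        sites = simulate_pair_sites(
            s1, s2, demog, model, n_trees, sites_per_tree, rng=rng
        )
        n1 = np.full(len(sites), s1, dtype=np.int64)
        n2 = np.full(len(sites), s2, dtype=np.int64)
        r1 = sites[:, :s1].sum(axis=1).astype(np.int64)
        r2 = sites[:, s1:].sum(axis=1).astype(np.int64)
        n1, r1, n2, r2 = apply_missingness(n1, r1, n2, r2, p_sample, rng)
        keep = apply_singleton_filter(n1, r1, n2, r2, singleton_retain, rng)
        comparisons.append(
            counts_to_comparison(
                n1[keep], r1[keep], n2[keep], r2[keep],
                label=labels[i],
                drop_constant=drop_constant,
            )
        )
    return ComparisonCollection(comparisons)


# ---------------------------------------------------------------------------
# Character-matrix export
# ---------------------------------------------------------------------------

def write_nexus(
    path: str,
    sites: np.ndarray,
    n1: int,
    pair_label: str = "pair0",
) -> None:
    """Write simulated tip states as a NEXUS standard (01) matrix with
    population labels encoded in the taxon names."""
    n_sites, n_tips = sites.shape
    names = [
        f"{pair_label}_pop{1 if j < n1 else 2}_{j if j < n1 else j - n1}"
        for j in range(n_tips)
    ]
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"    DIMENSIONS NTAX={n_tips} NCHAR={n_sites};\n")
        fh.write('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n')
        fh.write("    MATRIX\n")
        for j, name in enumerate(names):
            row = "".join(str(int(x)) if x >= 0 else "?" for x in sites[:, j])
            fh.write(f"        '{name}'  {row}\n")
        fh.write("    ;\nEND;\n")
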