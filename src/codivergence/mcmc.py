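"""Markov chain Monte Carlo over divergence models and parameters.

The sampler explores the joint posterior of

* the partition of population pairs into divergence events (a Dirichlet
  process prior, updated with Neal's Algorithm 8 using auxiliary event
  times drawn from the base distribution),
* the event times,
* per-pair descendant effective sizes and the root size (parameterized
  relative to the mean of the descendant sizes),
* optionally the stationary frequency ``pi`` per pair and the
  concentration parameter ``alpha`` (conjugate-style auxiliary-variable
  Gibbs update).

Continuous parameters use multiplicative scale moves; a joint move
rescales an event time while inversely rescaling the relative root
sizes of its pairs, decorrelating the time / root-size ridge.

``prior_only=True`` replaces the likelihood with a constant, so the
chain samples the prior exactly — the standard correctness check that
the operators target the intended distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import ComparisonCollection
from .likelihood import MutationModel, PairLikelihoodEngine
from .priors import (
    BetaPrior,
    GammaPrior,
    PriorConfig,
    canonical_partition,
    crp_partition_log_prob,
)

__all__ = [
    "ChainState",
    "initial_state_from_prior",
    "run_chain",
    "run_chains",
    "write_trace",
    "read_trace",
    "partition_string",
]


def partition_string(assignment: Sequence[int]) -> str:
    return ".".join(str(a) for a in canonical_partition(assignment))


@dataclass
class ChainState:
    """Current position of the chain; event labels are kept compact
    (0 .. k-1) but not necessarily in first-appearance order between
    sweeps."""

    assignment: list[int]
    times: list[float]
    nd1: np.ndarray
    nd2: np.ndarray
    rel_root: np.ndarray
    pis: np.ndarray
    alpha: float
    pair_ll: np.ndarray = field(default=None)

    @property
    def n_pairs(self) -> int:
        return len(self.assignment)

    @property
    def n_events(self) -> int:
        return len(self.times)

    def root_size(self, i: int) -> float:
        return self.rel_root[i] * (self.nd1[i] + self.nd2[i]) / 2.0

    def pair_time(self, i: int) -> float:
        return self.times[self.assignment[i]]


def initial_state_from_prior(
    priors: PriorConfig, n_pairs: int, rng: np.random.Generator
) -> ChainState:
    from .simulate import draw_truth_from_prior

    truth = draw_truth_from_prior(priors, n_pairs, rng)
    return ChainState(
        assignment=list(truth.partition),
        times=list(truth.event_times),
        nd1=np.array([d.N_d1 for d in truth.demographies]),
        nd2=np.array([d.N_d2 for d in truth.demographies]),
        rel_root=np.array(
            [d.N_root / ((d.N_d1 + d.N_d2) / 2.0) for d in truth.demographies]
        ),
        pis=np.array([m.pi for m in truth.models]),
        alpha=truth.alpha,
    )


class _Sampler:
    def __init__(
        self,
        collection: Optional[ComparisonCollection],
        priors: PriorConfig,
        rng: np.random.Generator,
        correction: str = "none",
        prior_only: bool = False,
        n_aux: int = 2,
        size_window: float = 0.5,
        time_window: float = 0.5,
        mixer_window: float = 0.3,
        pi_window: float = 0.1,
    ):
        if collection is None and not prior_only:
            raise ValueError("data required unless prior_only=True")
        self.collection = collection
        self.priors = priors
        self.rng = rng
        self.correction = correction
        self.prior_only = prior_only
        self.n_aux = max(1, int(n_aux))
        self.size_window = size_window
        self.time_window = time_window
        self.mixer_window = mixer_window
        self.pi_window = pi_window
        self.n_pairs = len(collection) if collection is not None else None
        self.engines: list[Optional[PairLikelihoodEngine]] = []
        self.accepts: dict[str, list[int]] = {}

    def _count(self, name: str, accepted: bool) -> None:
        c = self.accepts.setdefault(name, [0, 0])
        c[0] += int(accepted)
        c[1] += 1

    # -- likelihood ------------------------------------------------------

    def _build_engines(self, state: ChainState) -> None:
        if self.prior_only:
            self.engines = [None] * state.n_pairs
            state.pair_ll = np.zeros(state.n_pairs)
            return
        self.engines = [
            PairLikelihoodEngine(
                c, MutationModel(pi=state.pis[i]), correction=self.correction
            )
            for i, c in enumerate(self.collection)
        ]
        state.pair_ll = np.array(
            [self._ll(state, i, state.pair_time(i)) for i in range(state.n_pairs)]
        )

    def _ll(
        self,
        state: ChainState,
        i: int,
        t: float,
        nd1: Optional[float] = None,
        nd2: Optional[float] = None,
        rel: Optional[float] = None,
        engine: Optional[PairLikelihoodEngine] = None,
    ) -> float:
        if self.prior_only:
            return 0.0
        nd1 = state.nd1[i] if nd1 is None else nd1
        nd2 = state.nd2[i] if nd2 is None else nd2
        rel = state.rel_root[i] if rel is None else rel
        eng = self.engines[i] if engine is None else engine
        return eng.log_likelihood(t, nd1, nd2, rel * (nd1 + nd2) / 2.0)

    # -- operators -------------------------------------------------------

    def _scale_factor(self, window: float) -> tuple[float, float]:
        ln_s = window * (self.rng.random() - 0.5)
        return math.exp(ln_s), ln_s

    def _metropolis(self, log_ratio: float) -> bool:
        return log_ratio >= 0.0 or self.rng.random() < math.exp(log_ratio)

    def move_size(self, state: ChainState, i: int, which: int) -> None:
        prior = self.priors.descendant_size_prior
        arr = state.nd1 if which == 0 else state.nd2
        x = arr[i]
        s, ln_s = self._scale_factor(self.size_window)
        xp = x * s
        t = state.pair_time(i)
        llp = self._ll(
            state, i, t,
            nd1=xp if which == 0 else None,
            nd2=xp if which == 1 else None,
        )
        log_ratio = (
            llp - state.pair_ll[i] + prior.logpdf(xp) - prior.logpdf(x) + ln_s
        )
        ok = self._metropolis(log_ratio)
        if ok:
            arr[i] = xp
            state.pair_ll[i] = llp
        self._count("size", ok)

    def move_root_size(self, state: ChainState, i: int) -> None:
        prior = self.priors.relative_root_size_prior
        x = state.rel_root[i]
        s, ln_s = self._scale_factor(self.size_window)
        xp = x * s
        t = state.pair_time(i)
        llp = self._ll(state, i, t, rel=xp)
        log_ratio = (
            llp - state.pair_ll[i] + prior.logpdf(xp) - prior.logpdf(x) + ln_s
        )
        ok = self._metropolis(log_ratio)
        if ok:
            state.rel_root[i] = xp
            state.pair_ll[i] = llp
        self._count("root_size", ok)

    def move_pi(self, state: ChainState, i: int) -> None:
        prior = self.priors.pi_prior
        x = state.pis[i]
        xp = x + self.pi_window * (self.rng.random() - 0.5)
        # reflect into (0, 1)
        while xp <= 0.0 or xp >= 1.0:
            if xp <= 0.0:
                xp = -xp
            if xp >= 1.0:
                xp = 2.0 - xp
        if self.prior_only:
            new_engine = None
            llp = 0.0
        else:
            new_engine = PairLikelihoodEngine(
                self.collection[i], MutationModel(pi=xp), correction=self.correction
            )
            llp = self._ll(state, i, state.pair_time(i), engine=new_engine)
        log_ratio = llp - state.pair_ll[i] + prior.logpdf(xp) - prior.logpdf(x)
        ok = self._metropolis(log_ratio)
        if ok:
            state.pis[i] = xp
            state.pair_ll[i] = llp
            if new_engine is not None:
                self.engines[i] = new_engine
        self._count("pi", ok)

    def move_time(self, state: ChainState, e: int) -> None:
        prior = self.priors.tau_prior
        t = state.times[e]
        s, ln_s = self._scale_factor(self.time_window)
        tp = t * s
        members = [i for i in range(state.n_pairs) if state.assignment[i] == e]
        llp = np.array([self._ll(state, i, tp) for i in members])
        log_ratio = (
            float(llp.sum()) - float(state.pair_ll[members].sum())
            + prior.logpdf(tp) - prior.logpdf(t) + ln_s
        )
        ok = self._metropolis(log_ratio)
        if ok:
            state.times[e] = tp
            state.pair_ll[members] = llp
        self._count("time", ok)

    def move_time_root_mixer(self, state: ChainState, e: int) -> None:
        """Jointly rescale an event time and inversely rescale the
        relative root sizes of its pairs."""
        tau_prior = self.priors.tau_prior
        rel_prior = self.priors.relative_root_size_prior
        t = state.times[e]
        s, ln_s = self._scale_factor(self.mixer_window)
        tp = t * s
        members = [i for i in range(state.n_pairs) if state.assignment[i] == e]
        rels = state.rel_root[members]
        relp = rels / s
        llp = np.array(
            [self._ll(state, i, tp, rel=r) for i, r in zip(members, relp)]
        )
        log_ratio = (
            float(llp.sum()) - float(state.pair_ll[members].sum())
            + tau_prior.logpdf(tp) - tau_prior.logpdf(t)
            + sum(rel_prior.logpdf(r) for r in relp)
            - sum(rel_prior.logpdf(r) for r in rels)
            + (1 - len(members)) * ln_s
        )
        ok = self._metropolis(log_ratio)
        if ok:
            state.times[e] = tp
            state.rel_root[members] = relp
            state.pair_ll[members] = llp
        self._count("mixer", ok)

    def move_partition(self, state: ChainState) -> None:
        """One Algorithm-8 sweep reassigning each pair to an existing or
        auxiliary divergence event."""
        prior = self.priors.tau_prior
        for i in range(state.n_pairs):
            c = state.assignment[i]
            counts = [0] * state.n_events
            for j, a in enumerate(state.assignment):
                if j != i:
                    counts[a] += 1
            singleton = counts[c] == 0
            aux_times = [state.times[c]] if singleton else []
            while len(aux_times) < self.n_aux:
                aux_times.append(float(prior.draw(self.rng)))
            cand_events = [e for e in range(state.n_events) if counts[e] > 0]
            log_w = []
            lls = []
            for e in cand_events:
                ll = (
                    state.pair_ll[i]
                    if e == c and not singleton
                    else self._ll(state, i, state.times[e])
                )
                lls.append(ll)
                log_w.append(math.log(counts[e]) + ll)
            for h, th in enumerate(aux_times):
                ll = (
                    state.pair_ll[i]
                    if singleton and h == 0
                    else self._ll(state, i, th)
                )
                lls.append(ll)
                log_w.append(math.log(state.alpha / self.n_aux) + ll)
            log_w = np.array(log_w)
            w = np.exp(log_w - log_w.max())
            choice = int(self.rng.choice(len(w), p=w / w.sum()))
            if choice < len(cand_events):
                new_e = cand_events[choice]
                new_time = None
            else:
                new_e = None
                new_time = aux_times[choice - len(cand_events)]
            state.pair_ll[i] = lls[choice]
            if new_e is not None:
                state.assignment[i] = new_e
            else:
                if singleton:
                    state.times[c] = new_time
                    state.assignment[i] = c
                    continue
                state.times.append(new_time)
                state.assignment[i] = len(state.times) - 1
            if singleton:
                # event c lost its last member: drop it and compact labels
                state.times.pop(c)
                state.assignment = [
                    a - 1 if a > c else a for a in state.assignment
                ]

    def move_alpha(self, state: ChainState) -> None:
        """Auxiliary-variable Gibbs update of the DP concentration under
        its gamma hyperprior."""
        hyper: GammaPrior = self.priors.alpha
        a = hyper.shape
        b = 1.0 / hyper.scale  # rate
        n = state.n_pairs
        k = state.n_events
        eta = self.rng.beta(state.alpha + 1.0, n)
        odds = (a + k - 1.0) / (n * (b - math.log(eta)))
        shape = a + k if self.rng.random() < odds / (1.0 + odds) else a + k - 1.0
        state.alpha = float(self.rng.gamma(shape, 1.0 / (b - math.log(eta))))

    # -- one generation ---------------------------------------------------

    def step(self, state: ChainState) -> None:
        p = self.priors
        for i in range(state.n_pairs):
            if not p.sizes_are_fixed:
                self.move_size(state, i, 0)
                self.move_size(state, i, 1)
            if not p.root_size_is_fixed:
                self.move_root_size(state, i)
            if not p.pi_is_fixed:
                self.move_pi(state, i)
        self.move_partition(state)
        for e in range(state.n_events):
            self.move_time(state, e)
        if not p.root_size_is_fixed:
            for e in range(state.n_events):
                self.move_time_root_mixer(state, e)
        if not p.alpha_is_fixed:
            self.move_alpha(state)

    # -- recording ---------------------------------------------------------

    def log_prior(self, state: ChainState) -> float:
        p = self.priors
        lp = crp_partition_log_prob(state.assignment, state.alpha)
        lp += sum(p.tau_prior.logpdf(t) for t in state.times)
        if not p.sizes_are_fixed:
            lp += sum(p.descendant_size_prior.logpdf(x) for x in state.nd1)
            lp += sum(p.descendant_size_prior.logpdf(x) for x in state.nd2)
        if not p.root_size_is_fixed:
            lp += sum(p.relative_root_size_prior.logpdf(x) for x in state.rel_root)
        if not p.pi_is_fixed:
            lp += sum(p.pi_prior.logpdf(x) for x in state.pis)
        if not p.alpha_is_fixed:
            lp += p.alpha.logpdf(state.alpha)
        return lp

    def record(self, state: ChainState, gen: int, labels: Sequence[str]) -> dict:
        row = {
            "generation": gen,
            "ln_likelihood": float(state.pair_ll.sum()),
            "ln_prior": self.log_prior(state),
            "n_events": state.n_events,
            "model": partition_string(state.assignment),
            "alpha": state.alpha,
        }
        for i, lab in enumerate(labels):
            row[f"time_{lab}"] = state.pair_time(i)
            row[f"size1_{lab}"] = float(state.nd1[i])
            row[f"size2_{lab}"] = float(state.nd2[i])
            row[f"root_rel_{lab}"] = float(state.rel_root[i])
            row[f"root_size_{lab}"] = state.root_size(i)
            row[f"freq1_{lab}"] = float(state.pis[i])
        return row


def run_chain(
    collection: Optional[ComparisonCollection],
    priors: PriorConfig,
    generations: int,
    sample_interval: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    prior_only: bool = False,
    correction: str = "none",
    n_pairs: Optional[int] = None,
    initial_state: Optional[ChainState] = None,
    n_aux: int = 2,
    size_window: float = 0.5,
    time_window: float = 0.5,
    mixer_window: float = 0.3,
    pi_window: float = 0.1,
    return_acceptance: bool = False,
):
    """Run one chain and return the posterior trace as a DataFrame with
    one row per recorded sample (generation 0 plus every
    ``sample_interval`` generations)."""
    if generations < 1 or sample_interval < 1 or generations % sample_interval:
        raise ValueError("sample_interval must divide generations")
    if rng is None:
        rng = np.random.default_rng(seed)
    if collection is not None:
        n_pairs = len(collection)
        labels = [c.label for c in collection]
    else:
        if n_pairs is None:
            raise ValueError("n_pairs required when no data are given")
        labels = [f"pair{i}" for i in range(n_pairs)]
    sampler = _Sampler(
        collection, priors, rng,
        correction=correction, prior_only=prior_only, n_aux=n_aux,
        size_window=size_window, time_window=time_window,
        mixer_window=mixer_window, pi_window=pi_window,
    )
    state = initial_state or initial_state_from_prior(priors, n_pairs, rng)
    sampler._build_engines(state)
    rows = [sampler.record(state, 0, labels)]
    for gen in range(1, generations + 1):
        sampler.step(state)
        if gen % sample_interval == 0:
            rows.append(sampler.record(state, gen, labels))
    trace = pd.DataFrame(rows)
    if return_acceptance:
        rates = {
            k: (c[0] / c[1] if c[1] else float("nan"))
            for k, c in sampler.accepts.items()
        }
        return trace, rates
    return trace


def run_chains(
    collection: Optional[ComparisonCollection],
    priors: PriorConfig,
    generations: int,
    sample_interval: int,
    n_chains: int,
    seed: Optional[int] = None,
    **kwargs,
) -> list[pd.DataFrame]:
    """Run independent chains with seeds derived from one root seed."""
    ss = np.random.SeedSequence(seed)
    return [
        run_chain(
            collection, priors, generations, sample_interval,
            rng=np.random.default_rng(child), **kwargs,
        )
        for child in ss.spawn(n_chains)
    ]


def write_trace(trace: pd.DataFrame, path: str) -> None:
    trace.to_csv(path, sep="\t", index=False)


def read_trace(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"model": str})
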