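"""Exact pattern probabilities under the two-population coalescent with
two-state mutation.

For one pair of populations the "species tree" S has a root population
of effective size ``N_root`` that split, a time ``t`` ago, into two
descendant populations of sizes ``N_d1`` and ``N_d2`` (sizes are the
product ``N_e * mu``; with the overall mutation rate mu = 1 all times
are in expected substitutions per site).  Each pair of gene-copy
lineages coalesces at rate 1/(2N), and each lineage mutates between the
red and green states at relative rates u (red->green) and v
(green->red), normalized so the stationary substitution flux equals mu.

The probability of an allele-count pattern (n1, r1), (n2, r2), summed
over gene-tree topologies and integrated over branch lengths, is
computed through the exactly equivalent Wright-Fisher diffusion dual:

* the population frequency x of the red allele follows a diffusion with
  variance x(1-x)/(2N) and drift v - (u+v)x, whose moment system on the
  monomials x^j (1-x)^(m-j), m <= n, is finite and closed.  Propagating
  a monomial along a branch is therefore a matrix exponential acting on
  a table indexed by (m, j) -- the branch's partial-likelihood table;
* at the divergence the two descendant frequencies share the root
  frequency, so the two branch tables combine by multiplying monomials
  (lineage sets merge and red counts add);
* the root population is at stationarity, where the frequency is
  Beta(4*N_root*v, 4*N_root*u) distributed, so the root integration has
  closed-form Beta moments.

Observed counts are binomial draws of the tip frequencies, giving

    p(n, r) = C(n1,r1) C(n2,r2) E[ X1^r1 (1-X1)^(n1-r1) X2^r2 (1-X2)^(n2-r2) ].

All pattern probabilities for fixed sample sizes sum to one by the
binomial theorem, which the test suite uses as the arbiter of
correctness together with Monte-Carlo simulation of gene trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from numba import njit
from scipy.linalg import expm
from scipy.special import betaln

from .data import AllelePattern, ComparisonData, ComparisonCollection

__all__ = [
    "MutationModel",
    "PairDemography",
    "PartialLikelihoodTable",
    "leaf_partials",
    "branch_propagate",
    "dual_generator",
    "pattern_table",
    "pattern_probability",
    "constant_probability",
    "pair_log_likelihood",
    "collection_log_likelihood",
    "PairLikelihoodEngine",
]

_PROB_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationModel:
    """Two-state mutation model.

    ``pi`` is the stationary frequency of the green state and ``mu`` the
    overall rate.  The relative rates are normalized so the stationary
    flux equals mu:  u = mu/(2(1-pi)) (red->green) and v = mu/(2 pi)
    (green->red), hence stationary green = u/(u+v) = pi, and pi = 0.5
    gives the symmetric two-state model with u = v = mu.
    """

    pi: float = 0.5
    mu: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError("pi must lie strictly between 0 and 1")
        if self.mu <= 0:
            raise ValueError("mu must be positive")

    @property
    def u(self) -> float:
        return self.mu / (2.0 * (1.0 - self.pi))

    @property
    def v(self) -> float:
        return self.mu / (2.0 * self.pi)

    @property
    def stationary_red(self) -> float:
        return self.v / (self.u + self.v)


@dataclass(frozen=True)
class PairDemography:
    """Species tree for one pair: divergence time and three effective
    sizes, each the product N_e * mu, in expected-substitution units."""

    div_time: float
    N_root: float
    N_d1: float
    N_d2: float

    def __post_init__(self) -> None:
        if self.div_time < 0:
            raise ValueError("divergence time must be >= 0")
        if min(self.N_root, self.N_d1, self.N_d2) <= 0:
            raise ValueError("effective sizes must be positive")

    @property
    def relative_root_size(self) -> float:
        return self.N_root / ((self.N_d1 + self.N_d2) / 2.0)

    @classmethod
    def from_relative_root(
        cls, div_time: float, rel_root: float, N_d1: float, N_d2: float
    ) -> "PairDemography":
        return cls(div_time, rel_root * (N_d1 + N_d2) / 2.0, N_d1, N_d2)


# ---------------------------------------------------------------------------
# State space:  (m, j) with 0 <= j <= m <= n_max, ordered by m ascending
# and j descending, which makes the moment generator upper triangular.
# ---------------------------------------------------------------------------

def _states(n_max: int) -> list[tuple[int, int]]:
    return [(m, j) for m in range(n_max + 1) for j in range(m, -1, -1)]


def _state_index(n_max: int) -> dict[tuple[int, int], int]:
    return {s: i for i, s in enumerate(_states(n_max))}


def _generator_parts(n_max: int, u: float, v: float) -> tuple[np.ndarray, np.ndarray]:
    """The transfer generator M = Mc / (4N) + Mm on coefficient vectors.

    Coefficients c of psi = sum c(m,j) x^j (1-x)^(m-j) evolve as
    dc/dt = M c, the transpose action of the diffusion generator on the
    monomial basis.
    """
    idx = _state_index(n_max)
    S = len(idx)
    Mc = np.zeros((S, S))
    Mm = np.zeros((S, S))
    for (m, j), a in idx.items():
        i = m - j
        Mc[a, a] = -m * (m - 1)
        Mm[a, a] = -(u + v) * j
        if j >= 1:
            b = idx[(m - 1, j - 1)]
            Mc[b, a] += j * (j - 1)
            Mm[b, a] += v * j
        if i >= 1:
            b = idx[(m - 1, j)]
            Mc[b, a] += i * (i - 1)
            Mm[b, a] += -v * i
            b = idx[(m, j + 1)]
            Mm[b, a] += (u + v) * i
    return Mc, Mm


def dual_generator(n_max: int, N: float, model: MutationModel) -> np.ndarray:
    """Dense transfer generator for a branch of size parameter N."""
    Mc, Mm = _get_parts(n_max, model.u, model.v)
    return Mc / (4.0 * N) + Mm


_PARTS_CACHE: dict[tuple[int, float, float], tuple[np.ndarray, np.ndarray]] = {}


def _get_parts(n_max: int, u: float, v: float) -> tuple[np.ndarray, np.ndarray]:
    key = (n_max, u, v)
    if key not in _PARTS_CACHE:
        if len(_PARTS_CACHE) > 64:
            _PARTS_CACHE.clear()
        _PARTS_CACHE[key] = _generator_parts(n_max, u, v)
    return _PARTS_CACHE[key]


# ---------------------------------------------------------------------------
# Partial-likelihood tables
# ---------------------------------------------------------------------------

@dataclass
class PartialLikelihoodTable:
    """Coefficients over lineage-count / red-count states (m, j) at one
    point on a branch; the entry at (m, j) weights the monomial
    x^j (1-x)^(m-j) of the local allele frequency."""

    n_max: int
    values: np.ndarray

    def __post_init__(self) -> None:
        S = (self.n_max + 1) * (self.n_max + 2) // 2
        if self.values.shape != (S,):
            raise ValueError("table shape does not match n_max")

    def __getitem__(self, state: tuple[int, int]) -> float:
        return float(self.values[_state_index(self.n_max)[state]])


def leaf_partials(n: int, r: int, n_max: Optional[int] = None) -> PartialLikelihoodTable:
    """Table at a branch bottom for an observed sample of ``n`` copies,
    ``r`` of them red: unit mass at state (n, r)."""
    if not 0 <= r <= n:
        raise ValueError(f"require 0 <= r <= n, got n={n}, r={r}")
    n_max = n if n_max is None else n_max
    if n_max < n:
        raise ValueError("n_max must be >= n")
    S = (n_max + 1) * (n_max + 2) // 2
    vals = np.zeros(S)
    vals[_state_index(n_max)[(n, r)]] = 1.0
    return PartialLikelihoodTable(n_max, vals)


def branch_propagate(
    partials: PartialLikelihoodTable,
    N: float,
    model: MutationModel,
    duration: float,
) -> PartialLikelihoodTable:
    """Propagate a table from the bottom to the top of a branch of the
    given duration: the action of exp(M * duration) on the table."""
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if N <= 0:
        raise ValueError("N must be positive")
    if duration == 0:
        return PartialLikelihoodTable(partials.n_max, partials.values.copy())
    M = dual_generator(partials.n_max, N, model)
    return PartialLikelihoodTable(partials.n_max, expm(M * duration) @ partials.values)


# ---------------------------------------------------------------------------
# Fast eigen path for repeated branch exponentials (MCMC hot loop)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _decompose_kernel(M, tol):  # pragma: no cover - numba
    """Eigendecomposition of an upper-triangular matrix by
    back-substitution: M = E diag(lam) Einv with E unit upper
    triangular.  Returns (E, Einv, lam, resid, cond, ok).

    A repeated eigenvalue is tolerated when the corresponding 0/0
    resolves (semisimple case, e.g. the duplicated zero eigenvalue
    shared by the empty and single-lineage states); otherwise ok is
    False.  ``resid`` is the max-norm residual of M E = E diag(lam) and
    ``cond`` a 1-norm condition estimate of E, for the caller's
    stability guard.  Inner loops run on transposed (row-contiguous)
    copies for cache locality.
    """
    S = M.shape[0]
    lam = np.empty(S)
    for i in range(S):
        lam[i] = M[i, i]
    # ER[i, jj] = E[jj, i] (eigenvector i stored as a row)
    ER = np.zeros((S, S))
    ok = True
    for i in range(S):
        ER[i, i] = 1.0
        li = lam[i]
        for jj in range(i - 1, -1, -1):
            s = 0.0
            for k in range(jj + 1, i + 1):
                s += M[jj, k] * ER[i, k]
            denom = li - lam[jj]
            if abs(denom) < tol:
                if abs(s) >= tol:
                    ok = False
                ER[i, jj] = 0.0
            else:
                ER[i, jj] = s / denom
    E = ER.T.copy()
    # XR[i, k] = Einv[k, i]; solve E (column i of Einv) = e_i
    XR = np.zeros((S, S))
    for i in range(S):
        XR[i, i] = 1.0
        for jj in range(i - 1, -1, -1):
            s = 0.0
            for k in range(jj + 1, i + 1):
                s += E[jj, k] * XR[i, k]
            XR[i, jj] = -s
    Einv = XR.T.copy()
    # residual of M E = E diag(lam), and cond_1(E) * cond-ish of Einv
    resid = 0.0
    for i in range(S):
        li = lam[i]
        for jj in range(i + 1):
            s = 0.0
            for k in range(jj, i + 1):
                s += M[jj, k] * ER[i, k]
            r = abs(s - ER[i, jj] * li)
            if r > resid:
                resid = r
    ne = 0.0
    ni = 0.0
    for i in range(S):
        se = 0.0
        si = 0.0
        for k in range(S):
            se += abs(ER[i, k])
            si += abs(XR[i, k])
        if se > ne:
            ne = se
        if si > ni:
            ni = si
    return E, Einv, lam, resid, ne * ni, ok


class _Decomposition:
    """Cached eigendecomposition of one branch generator; falls back to
    scipy's expm when the spectrum is too close to degenerate."""

    __slots__ = ("M", "ok", "E", "Einv", "lam", "_ucols")

    def __init__(self, M: np.ndarray):
        self.M = M
        self._ucols: dict[int, np.ndarray] = {}
        scale = 1.0 + np.max(np.abs(np.diag(M)))
        E, Einv, lam, resid, cond, ok = _decompose_kernel(
            np.ascontiguousarray(M), 1e-10 * scale
        )
        self.lam = lam
        # the error of the eigen-based exponential is ~ cond(E) * eps
        self.ok = bool(
            ok and np.isfinite(resid) and resid <= 1e-9 * scale and cond <= 1e9
        )
        if self.ok:
            self.E = E
            self.Einv = Einv
        else:
            self.E = self.Einv = None

    def transfer_cols(
        self, t: float, cols: np.ndarray, cols_key: tuple
    ) -> np.ndarray:
        """Columns of exp(M t) at the given state indices."""
        if self.ok:
            U = self._ucols.get(cols_key)
            if U is None:
                U = np.ascontiguousarray(self.Einv[:, cols])
                self._ucols[cols_key] = U
            return self.E @ (np.exp(self.lam * t)[:, None] * U)
        return expm(self.M * t)[:, cols]


class BranchPropagator:
    """Shared per-(n_max, mutation) branch propagator with per-N
    decomposition caching."""

    def __init__(self, n_max: int, u: float, v: float):
        self.n_max = n_max
        self.Mc, self.Mm = _get_parts(n_max, u, v)
        self._decomps: dict[float, _Decomposition] = {}

    def decomposition(self, N: float) -> _Decomposition:
        d = self._decomps.get(N)
        if d is None:
            if len(self._decomps) > 128:
                self._decomps.clear()
            d = _Decomposition(self.Mc / (4.0 * N) + self.Mm)
            self._decomps[N] = d
        return d


_PROPAGATORS: dict[tuple[int, float, float], BranchPropagator] = {}


def get_propagator(n_max: int, u: float, v: float) -> BranchPropagator:
    key = (n_max, u, v)
    if key not in _PROPAGATORS:
        if len(_PROPAGATORS) > 64:
            _PROPAGATORS.clear()
        _PROPAGATORS[key] = BranchPropagator(n_max, u, v)
    return _PROPAGATORS[key]


# ---------------------------------------------------------------------------
# Root integration
# ---------------------------------------------------------------------------

def _beta_moment_table(
    N_root: float, u: float, v: float, j_max: int, i_max: int
) -> np.ndarray:
    """T[J, I] = E[X^J (1-X)^I] for X ~ Beta(4*N_root*v, 4*N_root*u),
    the stationary red-allele frequency of the root population."""
    a = 4.0 * N_root * v
    b = 4.0 * N_root * u
    J = np.arange(j_max + 1)[:, None]
    I = np.arange(i_max + 1)[None, :]
    return np.exp(betaln(a + J, b + I) - betaln(a, b))


_GRID_MAPS_CACHE: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _grid_maps(n_max: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map each state (m, j) to its (j, i) grid position; returns
    (flat grid index per state, j per grid cell, i per grid cell)."""
    cached = _GRID_MAPS_CACHE.get(n_max)
    if cached is not None:
        return cached
    states = _states(n_max)
    g = n_max + 1
    flat = np.array([j * g + (m - j) for (m, j) in states])
    jj = np.repeat(np.arange(g), g)
    ii = np.tile(np.arange(g), g)
    if len(_GRID_MAPS_CACHE) > 64:
        _GRID_MAPS_CACHE.clear()
    _GRID_MAPS_CACHE[n_max] = (flat, jj, ii)
    return flat, jj, ii


@njit(cache=True)
def _root_pair_kernel(a, b, g1, g2):  # pragma: no cover - numba
    """Mroot[(j1,i1),(j2,i2)] = E[X^(j1+j2) (1-X)^(i1+i2)] for
    X ~ Beta(a, b), built from the Beta-moment recurrences."""
    jmax = g1 + g2 - 2
    T = np.empty((jmax + 1, jmax + 1))
    T[0, 0] = 1.0
    for I in range(jmax):
        T[0, I + 1] = T[0, I] * (b + I) / (a + b + I)
    for J in range(jmax):
        for I in range(jmax + 1):
            T[J + 1, I] = T[J, I] * (a + J) / (a + b + J + I)
    M = np.empty((g1 * g1, g2 * g2))
    for j1 in range(g1):
        for i1 in range(g1):
            row = j1 * g1 + i1
            for j2 in range(g2):
                for i2 in range(g2):
                    M[row, j2 * g2 + i2] = T[j1 + j2, i1 + i2]
    return M


def _root_pair_matrix(
    N_root: float, u: float, v: float, n1_max: int, n2_max: int
) -> np.ndarray:
    a = 4.0 * N_root * v
    b = 4.0 * N_root * u
    return _root_pair_kernel(a, b, n1_max + 1, n2_max + 1)


# ---------------------------------------------------------------------------
# One-shot pattern probabilities (exact expm path)
# ---------------------------------------------------------------------------

def _branch_coefficient_grid(
    n: int, demog_N: float, t: float, model: MutationModel
) -> np.ndarray:
    """Evolved coefficient vectors for all (n, r), scattered onto the
    (j, i) grid; shape ((n+1)^2, n+1) with column r for observed r."""
    g = n + 1
    grid = np.zeros((g * g, g))
    if n == 0:
        grid[0, 0] = 1.0  # empty sample: psi == 1
        return grid
    idx = _state_index(n)
    W = expm(dual_generator(n, demog_N, model) * t)
    flat, _, _ = _grid_maps(n)
    cols = np.array([idx[(n, r)] for r in range(n + 1)])
    grid[flat, :] = W[:, cols]
    return grid


def pattern_table(
    n1: int, n2: int, demog: PairDemography, model: MutationModel
) -> np.ndarray:
    """All pattern probabilities for sample sizes (n1, n2): the entry at
    [r1, r2] is p((n1, r1), (n2, r2) | S, mu, pi).  Rows/columns sum to
    one over the full table."""
    if n1 + n2 < 1:
        raise ValueError("need at least one sampled copy")
    B1 = _branch_coefficient_grid(n1, demog.N_d1, demog.div_time, model)
    B2 = _branch_coefficient_grid(n2, demog.N_d2, demog.div_time, model)
    Mroot = _root_pair_matrix(demog.N_root, model.u, model.v, n1, n2)
    P = B1.T @ Mroot @ B2
    bin1 = np.array([math.comb(n1, r) for r in range(n1 + 1)], dtype=float)
    bin2 = np.array([math.comb(n2, r) for r in range(n2 + 1)], dtype=float)
    return bin1[:, None] * bin2[None, :] * P


def pattern_probability(
    pattern: AllelePattern, demog: PairDemography, model: MutationModel
) -> float:
    """Exact probability of one unordered allele-count pattern."""
    table = pattern_table(pattern.n1, pattern.n2, demog, model)
    return float(table[pattern.r1, pattern.r2])


def constant_probability(
    n1: int, n2: int, demog: PairDemography, model: MutationModel
) -> tuple[float, float]:
    """(p_all_red, p_all_green) for the given sample sizes."""
    table = pattern_table(n1, n2, demog, model)
    return float(table[n1, n2]), float(table[0, 0])


# ---------------------------------------------------------------------------
# Pair / collection log likelihoods
# ---------------------------------------------------------------------------

class PairLikelihoodEngine:
    """Per-pair likelihood evaluator with caching for MCMC.

    Patterns are grouped by sample sizes (n1, n2); one branch matrix
    exponential per distinct (size parameter, duration) serves every
    pattern of the pair.  ``method='eig'`` reuses a cached triangular
    eigendecomposition per branch size parameter so repeated divergence
    time evaluations cost only small matrix products.
    """

    def __init__(
        self,
        data: ComparisonData,
        model: MutationModel,
        correction: str = "none",
        method: str = "eig",
    ):
        if correction not in ("none", "per_site", "max_copies"):
            raise ValueError(f"unknown correction {correction!r}")
        if correction != "none" and data.has_constant_patterns:
            raise ValueError(
                "constant-character correction requested but the data still "
                "contain constant patterns"
            )
        if method not in ("eig", "expm"):
            raise ValueError(f"unknown method {method!r}")
        self.data = data
        self.model = model
        self.correction = correction
        self.method = method
        self._memo: dict[tuple, float] = {}

        groups: dict[tuple[int, int], list[AllelePattern]] = {}
        for p in data.patterns:
            groups.setdefault((p.n1, p.n2), []).append(p)
        self.n1_max, self.n2_max = data.max_copies
        if correction == "max_copies" and (self.n1_max, self.n2_max) not in groups:
            groups[(self.n1_max, self.n2_max)] = []
        self.group_keys = sorted(groups)
        self.groups = {
            key: (
                np.array([p.r1 for p in pats], dtype=np.int64),
                np.array([p.r2 for p in pats], dtype=np.int64),
                np.array([p.weight for p in pats], dtype=float),
            )
            for key, pats in groups.items()
        }

        u, v = model.u, model.v
        self._setup_branch(1, self.n1_max, {k[0] for k in self.group_keys}, u, v)
        self._setup_branch(2, self.n2_max, {k[1] for k in self.group_keys}, u, v)
        self._root_cache: dict[float, np.ndarray] = {}

        def lchoose(n, r):
            return (
                math.lgamma(n + 1) - math.lgamma(r + 1) - math.lgamma(n - r + 1)
            )

        # Precomputed per group: probability-matrix indices for each
        # pattern and for the two constant patterns, plus log binomials.
        self._group_calc = {}
        for key in self.group_keys:
            n1, n2 = key
            r1s, r2s, ws = self.groups[key]
            self._group_calc[key] = (
                np.array([self._col(1, n1, r) for r in r1s], dtype=np.int64),
                np.array([self._col(2, n2, r) for r in r2s], dtype=np.int64),
                ws,
                np.array([lchoose(n1, r1) + lchoose(n2, r2)
                          for r1, r2 in zip(r1s, r2s)]),
                (self._col(1, n1, n1), self._col(2, n2, n2)),
                (self._col(1, n1, 0), self._col(2, n2, 0)),
            )

    def _setup_branch(self, which: int, n_max: int, n_values: set, u: float, v: float):
        """Precompute state columns and grid scatter for one branch."""
        cols = []
        col_of: dict[tuple[int, int], int] = {}
        if n_max > 0:
            idx = _state_index(n_max)
            for n in sorted(n_values):
                if n == 0:
                    continue
                for r in range(n + 1):
                    col_of[(n, r)] = len(cols)
                    cols.append(idx[(n, r)])
            flat, _, _ = _grid_maps(n_max)
            prop = get_propagator(n_max, u, v)
        else:
            flat = np.array([0])
            prop = None
        setattr(self, f"_prop{which}", prop)
        setattr(self, f"_cols{which}", np.array(cols, dtype=np.int64))
        setattr(self, f"_col_of{which}", col_of)
        setattr(self, f"_flat{which}", flat)
        # the key must identify the column set: decompositions are shared
        # between engines whose patterns may need different columns
        setattr(self, f"_colskey{which}", tuple(cols))

    def _col(self, which: int, n: int, r: int) -> int:
        """Column of the assembled probability matrix holding the
        evolved coefficients for an observed sample (n, r); column 0 is
        the empty sample."""
        if n == 0:
            return 0
        return getattr(self, f"_col_of{which}")[(n, r)] + 1

    def _branch_grid(self, which: int, N: float, t: float) -> np.ndarray:
        prop: BranchPropagator = getattr(self, f"_prop{which}")
        n_max = self.n1_max if which == 1 else self.n2_max
        g = n_max + 1
        cols = getattr(self, f"_cols{which}")
        grid = np.zeros((g * g, max(len(cols), 1) + 1))
        grid[0, 0] = 1.0  # column 0: the empty sample (n = 0)
        if prop is None or len(cols) == 0:
            return grid[:, :1]
        if self.method == "eig":
            C = prop.decomposition(N).transfer_cols(t, cols, getattr(self, f"_colskey{which}"))
        else:
            M = prop.Mc / (4.0 * N) + prop.Mm
            C = expm(M * t)[:, cols]
        flat = getattr(self, f"_flat{which}")
        grid[flat, 1:] = C
        return grid

    def _root_matrix(self, N_root: float) -> np.ndarray:
        Mr = self._root_cache.get(N_root)
        if Mr is None:
            if len(self._root_cache) > 64:
                self._root_cache.clear()
            Mr = _root_pair_matrix(
                N_root, self.model.u, self.model.v, self.n1_max, self.n2_max
            )
            self._root_cache[N_root] = Mr
        return Mr

    def log_likelihood(
        self, t: float, N_d1: float, N_d2: float, N_root: float
    ) -> float:
        """Sum over weighted patterns of log pattern probability, with
        the configured constant-character correction."""
        if not self.data.patterns and self.correction != "max_copies":
            return 0.0
        key = (t, N_d1, N_d2, N_root)
        val = self._memo.get(key)
        if val is not None:
            return val
        if len(self._memo) > 512:
            self._memo.clear()

        B1 = self._branch_grid(1, N_d1, t)
        B2 = self._branch_grid(2, N_d2, t)
        Mr = self._root_matrix(N_root)
        # P[c1, c2] = raw moment for branch coefficient columns c1, c2
        P = B1.T @ (Mr @ B2)

        ll = 0.0
        for group_key in self.group_keys:
            c1, c2, ws, lb, all_red, all_green = self._group_calc[group_key]
            if len(ws):
                probs = np.clip(P[c1, c2], _PROB_FLOOR, None)
                ll += float(np.sum(ws * (np.log(probs) + lb)))
            if self.correction == "per_site":
                p_var = max(
                    1.0 - P[all_red] - P[all_green], _PROB_FLOOR
                )
                ll -= float(np.sum(ws)) * math.log(p_var)
        if self.correction == "max_copies":
            _, _, _, _, all_red, all_green = self._group_calc[
                (self.n1_max, self.n2_max)
            ]
            p_var = max(1.0 - P[all_red] - P[all_green], _PROB_FLOOR)
            ll -= self.data.total_weight * math.log(p_var)
        self._memo[key] = ll
        return ll


def pair_log_likelihood(
    data: ComparisonData,
    demog: PairDemography,
    model: MutationModel,
    correction: str = "none",
) -> float:
    """Log probability of one pair's patterns given its species tree.

    ``correction='per_site'`` divides each pattern's probability by the
    probability that a character with that pattern's sample sizes is
    variable; ``'max_copies'`` applies one overall factor at the maximum
    sample sizes (the SNAPP-style correction).  The two agree exactly
    when every site has complete sampling.
    """
    engine = PairLikelihoodEngine(data, model, correction=correction, method="expm")
    return engine.log_likelihood(demog.div_time, demog.N_d1, demog.N_d2, demog.N_root)


def collection_log_likelihood(
    collection: ComparisonCollection,
    demographies: Sequence[PairDemography],
    model: MutationModel | Sequence[MutationModel],
    correction: str = "none",
) -> float:
    """Sum of pair log likelihoods; pairs are independent."""
    if len(demographies) != len(collection):
        raise ValueError("one demography required per pair")
    if isinstance(model, MutationModel):
        models: Sequence[MutationModel] = [model] * len(collection)
    else:
        models = list(model)
        if len(models) != len(collection):
            raise ValueError("one mutation model required per pair")
    return sum(
        pair_log_likelihood(c, d, m, correction=correction)
        for c, d, m in zip(collection, demographies, models)
    )
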