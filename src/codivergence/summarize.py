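"""Posterior summaries, model comparison, and convergence diagnostics."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .priors import GammaPrior, dp_prior_k_probs

__all__ = [
    "equal_tailed_interval",
    "credible_set",
    "potential_scale_reduction",
    "effective_sample_size",
    "bayes_factor",
    "bayes_factors_k",
    "calibration_bins",
    "PosteriorSummary",
    "summarize_traces",
]


def equal_tailed_interval(samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval from posterior samples."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    samples = np.asarray(samples, dtype=float)
    lo = (1.0 - level) / 2.0
    return (float(np.quantile(samples, lo)), float(np.quantile(samples, 1.0 - lo)))


def credible_set(probs: dict, level: float = 0.95) -> list:
    """Smallest set of values whose probabilities sum to at least
    ``level``, filled in descending probability order."""
    if not 0.0 < level <= 1.0:
        raise ValueError("level must be in (0, 1]")
    out = []
    total = 0.0
    for key, p in sorted(probs.items(), key=lambda kv: (-kv[1], str(kv[0]))):
        out.append(key)
        total += p
        if total >= level - 1e-12:
            break
    return out


def potential_scale_reduction(chains: Sequence[np.ndarray]) -> float:
    """Potential scale reduction factor across chains (the classic
    between/within-variance form, reported as the square-root R-hat).
    Values near 1 indicate convergence; requires >= 2 chains of equal
    length."""
    arrs = [np.asarray(c, dtype=float) for c in chains]
    m = len(arrs)
    if m < 2:
        raise ValueError("need at least two chains")
    n = len(arrs[0])
    if any(len(a) != n for a in arrs) or n < 2:
        raise ValueError("chains must share a length of at least 2")
    means = np.array([a.mean() for a in arrs])
    variances = np.array([a.var(ddof=1) for a in arrs])
    W = variances.mean()
    B = n * means.var(ddof=1)
    if W <= 0.0:
        return 1.0 if B <= 0.0 else math.inf
    sigma2 = (n - 1.0) / n * W + B / n
    var_hat = sigma2 + B / (m * n)
    return float(math.sqrt(var_hat / W))


def effective_sample_size(samples: Union[np.ndarray, Sequence[np.ndarray]]) -> float:
    """Autocorrelation-adjusted effective sample size (one or more
    chains).  Constant samples give 0."""
    import arviz as az

    if isinstance(samples, np.ndarray) and samples.ndim == 1:
        chains = samples[None, :]
    else:
        chains = np.asarray([np.asarray(c, dtype=float) for c in samples])
        if chains.ndim == 1:
            chains = chains[None, :]
    if chains.shape[1] < 10:
        raise ValueError("need at least 10 samples per chain")
    if np.allclose(chains, chains.flat[0]):
        return 0.0
    return float(az.ess(az.convert_to_dataset(chains))["x"].values)


def bayes_factor(
    posterior_prob: float, prior_prob: float, eps: float = 1e-12
) -> float:
    """Bayes factor for a hypothesis versus its complement from
    posterior and prior probabilities (ratio of odds)."""
    if not 0.0 <= posterior_prob <= 1.0 or not 0.0 < prior_prob < 1.0:
        raise ValueError("probabilities must be valid and prior non-degenerate")
    post = min(max(posterior_prob, eps), 1.0 - eps)
    return (post / (1.0 - post)) / (prior_prob / (1.0 - prior_prob))


def bayes_factors_k(
    posterior_k: dict[int, float],
    n_pairs: int,
    alpha: Union[float, GammaPrior],
    n_prior_sims: int = 200_000,
    seed: Optional[int] = 0,
) -> dict[int, float]:
    """Bayes factor for each number of divergence events versus all
    other numbers; prior probabilities are computed under the chain's
    own Dirichlet-process prior (Monte Carlo when alpha carries a
    hyperprior)."""
    prior = dp_prior_k_probs(n_pairs, alpha, n_sims=n_prior_sims, seed=seed)
    out = {}
    for k in range(1, n_pairs + 1):
        if not 0.0 < prior[k - 1] < 1.0:
            continue
        out[k] = bayes_factor(posterior_k.get(k, 0.0), float(prior[k - 1]))
    return out


def calibration_bins(
    posterior_probs: np.ndarray,
    truth_indicators: np.ndarray,
    bin_width: float = 0.1,
) -> list[dict]:
    """Calibration table for inferred posterior probabilities.

    Datasets are binned by their inferred posterior probability of some
    hypothesis; within each bin the mean inferred probability is paired
    with the empirical frequency at which the hypothesis was true.  For
    a well-calibrated method the two agree.
    """
    if not 0.0 < bin_width <= 1.0:
        raise ValueError("bin_width must be in (0, 1]")
    p = np.asarray(posterior_probs, dtype=float)
    t = np.asarray(truth_indicators, dtype=bool)
    if p.shape != t.shape:
        raise ValueError("posterior_probs and truth_indicators must align")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("posterior probabilities must lie in [0, 1]")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (p >= lo) & (p < hi if hi < 1.0 else p <= hi)
        if not mask.any():
            continue
        out.append(
            {
                "bin_lower": float(lo),
                "bin_upper": float(hi),
                "mean_posterior": float(p[mask].mean()),
                "empirical_frequency": float(t[mask].mean()),
                "count": int(mask.sum()),
            }
        )
    return out


# ---------------------------------------------------------------------------
# Whole-trace summaries
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    n_samples: int
    n_chains: int
    burn_in: int
    prob_k: dict[int, float]
    prob_model: dict[str, float]
    map_model: str
    credible_set_models: list[str]
    parameters: dict[str, dict]
    bayes_factors: Optional[dict[int, float]] = None

    def to_dict(self) -> dict:
        d = {
            "n_samples": self.n_samples,
            "n_chains": self.n_chains,
            "burn_in": self.burn_in,
            "prob_num_events": {int(k): float(v) for k, v in self.prob_k.items()},
            "prob_model": {k: float(v) for k, v in self.prob_model.items()},
            "map_model": self.map_model,
            "credible_set_models": list(self.credible_set_models),
            "parameters": self.parameters,
        }
        if self.bayes_factors is not None:
            d["bayes_factors_num_events"] = {
                int(k): float(v) for k, v in self.bayes_factors.items()
            }
        return d


def summarize_traces(
    traces: Union[pd.DataFrame, Sequence[pd.DataFrame]],
    burn_in: int = 0,
    level: float = 0.95,
    n_pairs: Optional[int] = None,
    alpha: Optional[Union[float, GammaPrior]] = None,
) -> PosteriorSummary:
    """Summarize one or more chains: divergence-model probabilities, the
    MAP model and its credible set, per-parameter posterior means with
    equal-tailed intervals, effective sample sizes and (for multiple
    chains) potential scale reduction factors.

    ``burn_in`` is the number of leading samples discarded per chain.
    When ``n_pairs`` and ``alpha`` are given, Bayes factors for the
    number of events are included.
    """
    if isinstance(traces, pd.DataFrame):
        traces = [traces]
    chains = [t.iloc[burn_in:].reset_index(drop=True) for t in traces]
    if any(len(c) == 0 for c in chains):
        raise ValueError("burn_in leaves no samples in at least one chain")
    pooled = pd.concat(chains, ignore_index=True)
    n = len(pooled)

    prob_k = pooled["n_events"].value_counts(normalize=True).sort_index()
    prob_k = {int(k): float(v) for k, v in prob_k.items()}
    prob_model = pooled["model"].astype(str).value_counts(normalize=True)
    prob_model = {str(k): float(v) for k, v in prob_model.items()}
    map_model = max(prob_model.items(), key=lambda kv: kv[1])[0]
    cs = credible_set(prob_model, level)

    numeric = [
        c for c in pooled.columns
        if c not in ("generation", "model") and np.issubdtype(pooled[c].dtype, np.number)
    ]
    same_len = len({len(c) for c in chains}) == 1
    params: dict[str, dict] = {}
    for c in numeric:
        x = pooled[c].to_numpy(dtype=float)
        lo, hi = equal_tailed_interval(x, level)
        entry = {
            "mean": float(x.mean()),
            "median": float(np.median(x)),
            "ci_lower": lo,
            "ci_upper": hi,
        }
        try:
            entry["ess"] = effective_sample_size(
                [ch[c].to_numpy(dtype=float) for ch in chains] if same_len else x
            )
        except ValueError:
            entry["ess"] = float("nan")
        if len(chains) >= 2 and same_len and len(chains[0]) >= 2:
            entry["psrf"] = potential_scale_reduction(
                [ch[c].to_numpy(dtype=float) for ch in chains]
            )
        params[c] = entry

    bfs = None
    if n_pairs is not None and alpha is not None:
        bfs = bayes_factors_k(prob_k, n_pairs, alpha)

    return PosteriorSummary(
        n_samples=n,
        n_chains=len(chains),
        burn_in=burn_in,
        prob_k=prob_k,
        prob_model=prob_model,
        map_model=map_model,
        credible_set_models=cs,
        parameters=params,
        bayes_factors=bfs,
    )
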