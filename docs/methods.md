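# Methods

This note documents the mathematics and algorithms implemented in
`codivergence`: the data model, the exact pair likelihood, the priors,
the MCMC machinery, the simulator, and the posterior summaries.

## Data

A *character* is a biallelic site with states called red and green.
For one pair of populations a site is reduced to the allele-count
pattern `(n1, r1), (n2, r2)`: the numbers of sampled gene copies and of
red copies in populations 1 and 2. Identical patterns are aggregated
with multiplicity weights (`data.AllelePattern`, `data.ComparisonData`).
Missing data simply reduce the per-site `n`. Nucleotide alignments are
recoded to binary per site, treating the first-seen allele as green;
sites with more than two alleles are recoded against the first allele
or removed, by policy. Several pairs analyzed jointly form a
`ComparisonCollection`.

## The pair model

Each pair `i` has a two-population species tree: a divergence time
`t_i` and three effective population sizes (root and two descendants).
The mutation rate is fixed at 1, so times are expected substitutions
per site and sizes are scaled as `N = N_e * mu`. The mutation model is
a two-state CTMC with rates `u` (red to green) and `v` (green to red),
normalized from the stationary green frequency `pi` as
`u = 1/(2(1-pi))`, `v = 1/(2 pi)`; this makes the stationary flux equal
to the mutation rate and gives `u = v = 1` at `pi = 0.5`. Conditional
on a gene tree, lineages within a population coalesce at pairwise rate
`1/(2N)`.

## Exact likelihood by diffusion moment duality

The probability of a pattern requires integrating over all gene trees
and allele histories. We do this with the moment dual of the
Wright–Fisher diffusion rather than gene-tree enumeration.

Consider the (backward-in-time) state of a branch: a partial
likelihood table indexed by `(m, j)` — `m` ancestral lineages of which
`j` carry red. Equivalently, expand the conditional pattern
probability in the monomial basis `x^j (1-x)^(m-j)` of the allele
frequency `x`. Under the diffusion with pairwise coalescence `1/(2N)`
and mutation `(u, v)`, this basis is closed: the generator maps each
monomial to monomials with equal or smaller `m`. Ordering states by
`m` ascending and `j` descending makes the transfer generator

```
M = Mc / (4N) + Mm
```

**upper triangular**, where `Mc` holds the coalescent terms (diagonal
`-m(m-1)`, flows from `(m, j)` to `(m-1, j-1)` and `(m-1, j)`) and `Mm`
the mutation terms (diagonal `-(u+v) j` plus off-diagonal flows); see
`likelihood.dual_generator`. Propagating a table up a branch of
duration `t` is then the matrix exponential `exp(M t)` applied to the
table. A sample of `n` copies with `r` red enters at the branch bottom
as unit mass at state `(n, r)`; the binomial coefficient `C(n, r)` for
unordered samples is applied once at the end.

At the root the two propagated tables meet. The root population is
stationary, so each monomial integrates in closed form against the
Beta law `Beta(a, b)` with `a = 4 N_root v`, `b = 4 N_root u`:

```
E[x^J (1-x)^I]  via the recurrence  T[J+1, I] = T[J, I] (a + J)/(a + b + J + I).
```

Lineages from the two descendants may also coalesce with each other in
the root; this is captured by pairing the two monomial tables through
the root generator, implemented as a single root-pairing matrix
(`likelihood._root_pair_matrix`). The final pattern probability is

```
p(n, r) = C(n1, r1) C(n2, r2) * [B1' Mroot B2](r1, r2)
```

where `B1`, `B2` are the branch coefficient grids. Normalization over
all patterns to 1 is automatic by the binomial theorem and is used as a
test invariant.

This formulation is mathematically equivalent to the standard
partial-likelihood recursion for biallelic characters on a species
tree; we chose it because it reduces a pair likelihood to two
triangular matrix exponentials plus one bilinear form.

### Fast repeated evaluation

MCMC evaluates the same branch generator at many durations. Because
`M` is upper triangular its eigenvalues are its diagonal, and a
triangular eigendecomposition `M = E diag(lam) E^{-1}` gives
`exp(Mt) = E diag(e^{lam t}) E^{-1}` at the cost of two small matrix
products. The spectrum has one systematic degeneracy — eigenvalue 0 is
shared by states `(0,0)` and `(1,0)` because the coalescent term
`m(m-1)` vanishes for `m <= 1` — but it is semisimple (the constant
function supplies the second eigenvector), so the 0/0 encountered in
back-substitution resolves benignly. The decomposition is computed by
a fused numba kernel that also returns the residual of `M E = E Λ` and
a condition estimate of `E`; if either guard fails, evaluation falls
back to `scipy.linalg.expm`. Engines cache decompositions per
population-size value and the one-shot public functions
(`pattern_table`, `pair_log_likelihood`) always use exact `expm`.
Eigendecomposition caches shared between likelihood engines are keyed
by the exact column set they serve.

### Constant-character corrections

When constant characters have been removed from the data, the
likelihood conditions on variability. Two variants are implemented:

* `per_site` — each pattern probability is divided by
  `1 - p_all_red - p_all_green` evaluated at that pattern's own sample
  sizes;
* `max_copies` — a single correction factor evaluated at the pair's
  maximum sample sizes.

The two are identical under complete sampling (no missing data) and
differ otherwise; both require `constant_removed` data, and no
correction (`none`) is used when constant characters are retained.

## Priors

The partition of `N` pairs into `k` divergence events follows a
Dirichlet process with concentration `alpha`, i.e. the Chinese
restaurant process:

```
p(partition) = alpha^k * prod_c (n_c - 1)! * Gamma(alpha) / Gamma(alpha + N),
E[k] = sum_{i=1..N} alpha / (alpha + i - 1).
```

Event times are i.i.d. gamma (exponential as shape 1) — the base
distribution of the process. Descendant sizes are gamma or fixed; the
root size is parameterized as the *relative root size* `R` (root size
divided by the mean descendant size) with a gamma or fixed prior, which
decorrelates it from the descendant sizes. `pi` is fixed or beta.
`alpha` is fixed or gamma-hyperpriored. Prior probabilities of `k`
are computed by Monte Carlo CRP simulation (`priors.dp_prior_k_probs`)
and exactly in tests via unsigned Stirling numbers.

## MCMC

One generation (`mcmc._Sampler.step`) applies:

* multiplicative scale moves (Hastings `ln s` per scaled variable) to
  each free descendant and relative root size and to each event time
  (shared by all its member pairs); a window move with reflection for
  each free `pi`;
* a joint *time–root-size mixer*: an event time is scaled by `s` and
  the relative root sizes of its member pairs by `1/s`, traversing the
  time/root-size posterior ridge; Hastings `(1 - n_members) ln s`;
* a Gibbs sweep over the partition using the auxiliary-variable method
  (Neal's algorithm 8) with `n_aux = 2` auxiliary events: for each
  pair, the pair is reassigned among the occupied events (weight
  `count * L`) and fresh events with times drawn from the base
  distribution (weight `(alpha / n_aux) * L`); a pair currently alone
  keeps its own time as the first auxiliary;
* when `alpha` is free, the standard two-step beta/gamma Gibbs update
  conditional on `k` and `N`.

Chains record tab-separated traces (generation, log likelihood, log
prior, number of events, the partition as a canonical string such as
`0.0.1`, `alpha`, and per-pair times, sizes, root sizes, and `pi`).
Multiple chains are run from seeds spawned off one root seed.

*Validation*: running the sampler with the likelihood disabled must
reproduce the prior exactly; the test suite checks the event-count
distribution against closed-form CRP probabilities and
Kolmogorov–Smirnov statistics of every continuous marginal, which
exercises every proposal and acceptance computation at once.

## Simulation

The simulator is an independent implementation (used to cross-validate
the likelihood): explicit coalescent gene trees are drawn per pair
(two descendant phases truncated at `t`, then the root phase), and
characters evolve down each tree under the two-state CTMC, the root
state drawn from stationarity. Loci of linked sites share one gene
tree. A numba kernel generates large datasets quickly; a pure-Python
path (`simulate_gene_tree`, `mutate_on_tree`, `simulate_locus`) serves
as its oracle. Post-processing can subsample gene copies per site
(missingness), drop singleton patterns with a retention probability
(modeling acquisition bias), and drop constant sites. Chi-square
agreement between simulated pattern frequencies and `pattern_table` at
10^6 characters is an acceptance check. `draw_truth_from_prior` plus
`simulate_collection` generate full simulation-study replicates;
`write_nexus` exports alignments.

## Summaries and diagnostics

From one or more traces: posterior probabilities of each number of
events and each divergence model, the MAP model, the 95% credible set
(smallest set of models reaching the level, filled in descending
probability), per-parameter means/medians and equal-tailed credible
intervals, effective sample sizes (autocorrelation-adjusted, via
arviz), and the classic between/within-chain potential scale reduction
factor. Bayes factors for each number of events compare posterior odds
with Dirichlet-process prior odds obtained by simulation. Calibration
tables bin replicate posterior probabilities against empirical
frequencies.

## Acceptance testing

Five end-to-end checks mirror the levels of the design:

1. exact combinatorics of divergence models and CRP moments;
2. likelihood correctness — normalization, simulator agreement at 10^6
   characters, equality of the two corrections under complete
   sampling, the pooled-population limit at `t = 0`, and prior-only
   MCMC;
3. simulator output means (variable characters per locus/dataset)
   against published values, with runtime-computed Monte Carlo
   tolerances;
4. three scaled-down simulate-and-reinfer studies (50 replicates each)
   checking credible-interval calibration, recovery of the number of
   events, and robustness to singleton bias and linked loci; replicate
   counts and chain lengths were fixed in advance by runtime budget and
   all tolerances are 3-sigma binomial/bootstrap Monte Carlo errors;
5. the CLI running the empirical configuration shape (four pairs, both
   concentration values, five divergence-time priors, constants
   retained).

`scripts/acceptance.py` recomputes the stochastic quantities to JSON.
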