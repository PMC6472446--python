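import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from codivergence.data import AllelePattern, ComparisonCollection, ComparisonData
from codivergence.likelihood import (
    MutationModel,
    PairDemography,
    PairLikelihoodEngine,
    branch_propagate,
    collection_log_likelihood,
    constant_probability,
    dual_generator,
    leaf_partials,
    pair_log_likelihood,
    pattern_probability,
    pattern_table,
)


class TestMutationModel:
    def test_rates(self):
        m = MutationModel(pi=0.5)
        assert m.u == pytest.approx(1.0)
        assert m.v == pytest.approx(1.0)
        assert m.stationary_red == pytest.approx(0.5)

    def test_skewed(self):
        m = MutationModel(pi=0.3)
        # pi is the stationary green frequency, so red is 1 - pi
        assert m.stationary_red == pytest.approx(0.7)
        assert m.u / (m.u + m.v) == pytest.approx(0.3)
        # detailed balance: u * pi_red == v * pi_green at stationarity
        assert m.u * m.stationary_red == pytest.approx(m.v * (1 - m.stationary_red))

    def test_invalid(self):
        with pytest.raises(ValueError):
            MutationModel(pi=0.0)
        with pytest.raises(ValueError):
            MutationModel(pi=1.0)


class TestPairDemography:
    def test_relative_root(self):
        d = PairDemography(0.01, 0.004, 0.002, 0.002)
        assert d.relative_root_size == pytest.approx(2.0)
        d2 = PairDemography.from_relative_root(0.01, 2.0, 0.002, 0.002)
        assert d2.N_root == pytest.approx(0.004)

    def test_invalid(self):
        with pytest.raises(ValueError):
            PairDemography(-0.01, 0.002, 0.002, 0.002)
        with pytest.raises(ValueError):
            PairDemography(0.01, 0.0, 0.002, 0.002)


class TestPatternTable:
    def test_normalization(self, demog, model):
        for n1, n2 in [(1, 1), (3, 4), (10, 10)]:
            table = pattern_table(n1, n2, demog, model)
            assert table.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all(table > 0)

    def test_single_lineage_is_stationary(self, demog, skewed_model):
        # one sampled copy carries no coalescent information: the red
        # probability is exactly the stationary frequency
        table = pattern_table(1, 0, demog, skewed_model)
        assert table[1, 0] == pytest.approx(skewed_model.stationary_red, abs=1e-12)
        assert table[0, 0] == pytest.approx(1 - skewed_model.stationary_red, abs=1e-12)

    def test_zero_divergence_pools_populations(self, model):
        # at div_time == 0 all lineages coalesce in the root population,
        # so (n1, n2) splits of a pooled sample follow the hypergeometric
        # partition of the single-population table
        N = 0.003
        d0 = PairDemography(0.0, N, N, N)
        n1, n2 = 3, 2
        pair = pattern_table(n1, n2, d0, model)
        pooled = pattern_table(n1 + n2, 0, PairDemography(0.0, N, N, N), model)
        for r in range(n1 + n2 + 1):
            split = sum(
                pair[r1, r - r1]
                for r1 in range(max(0, r - n2), min(n1, r) + 1)
            )
            assert split == pytest.approx(pooled[r, 0], abs=1e-12)
            # and each split term carries the hypergeometric weight
            for r1 in range(max(0, r - n2), min(n1, r) + 1):
                w = (
                    math.comb(n1, r1) * math.comb(n2, r - r1)
                    / math.comb(n1 + n2, r)
                )
                assert pair[r1, r - r1] == pytest.approx(
                    w * pooled[r, 0], abs=1e-12
                )

    def test_color_symmetry_at_half(self, demog):
        # with pi = 0.5 swapping red and green leaves probabilities alone
        model = MutationModel(pi=0.5)
        table = pattern_table(4, 3, demog, model)
        assert np.allclose(table, table[::-1, ::-1], atol=1e-13)

    def test_population_swap_symmetry(self, model):
        d = PairDemography(0.01, 0.002, 0.0025, 0.0015)
        swapped = PairDemography(0.01, 0.002, 0.0015, 0.0025)
        t1 = pattern_table(4, 3, d, model)
        t2 = pattern_table(3, 4, swapped, model)
        assert np.allclose(t1, t2.T, atol=1e-13)

    def test_beta_binomial_root_limit(self, skewed_model):
        # a sample taken directly from the root population (div_time = 0,
        # tiny descendant time) follows the beta-binomial with
        # a = 4*N*v, b = 4*N*u
        N = 0.005
        m = skewed_model
        d = PairDemography(0.0, N, N, N)
        n = 6
        table = pattern_table(n, 0, d, m)
        a, b = 4 * N * m.v, 4 * N * m.u
        for r in range(n + 1):
            exact = math.comb(n, r) * math.exp(
                _lbeta(a + r, b + n - r) - _lbeta(a, b)
            )
            assert table[r, 0] == pytest.approx(exact, rel=1e-9)


def _lbeta(a, b):
    return math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)


class TestBranchPropagation:
    def test_identity_at_zero_duration(self, model):
        partials = leaf_partials(4, 2)
        out = branch_propagate(partials, 0.002, model, 0.0)
        assert np.allclose(out.values, partials.values)

    def test_negative_duration_raises(self, model):
        with pytest.raises(ValueError):
            branch_propagate(leaf_partials(2, 1), 0.002, model, -0.1)

    def test_matches_direct_expm(self, skewed_model):
        partials = leaf_partials(5, 3)
        N, t = 0.004, 0.02
        out = branch_propagate(partials, N, skewed_model, t)
        M = dual_generator(5, N, skewed_model)
        direct = expm(M * t) @ partials.values
        assert np.allclose(out.values, direct, atol=1e-12)

    def test_matches_ode_integration(self, model):
        # independent oracle: integrate dy/dt = M y with an ODE solver
        partials = leaf_partials(4, 1)
        N, t = 0.003, 0.015
        M = dual_generator(4, N, model)
        sol = solve_ivp(
            lambda _, y: M @ y, (0.0, t), partials.values,
            rtol=1e-12, atol=1e-14, method="DOP853",
        )
        out = branch_propagate(partials, N, model, t)
        assert np.allclose(out.values, sol.y[:, -1], atol=1e-9)

    def test_leaf_partials_indexing(self):
        p = leaf_partials(3, 2)
        assert p[(3, 2)] == pytest.approx(1.0)  # unit mass at the sample
        assert p[(3, 1)] == 0.0
        assert p[(2, 1)] == 0.0


class TestEngine:
    def test_engine_matches_one_shot(self, small_data, model, demog):
        engine = PairLikelihoodEngine(small_data, model)
        ll = engine.log_likelihood(
            demog.div_time, demog.N_d1, demog.N_d2, demog.N_root
        )
        direct = pair_log_likelihood(small_data, demog, model)
        assert ll == pytest.approx(direct, abs=1e-9)

    def test_eig_equals_expm(self, small_data, skewed_model, demog):
        e_eig = PairLikelihoodEngine(small_data, skewed_model, method="eig")
        e_expm = PairLikelihoodEngine(small_data, skewed_model, method="expm")
        args = (demog.div_time, demog.N_d1, demog.N_d2, demog.N_root)
        assert e_eig.log_likelihood(*args) == pytest.approx(
            e_expm.log_likelihood(*args), abs=1e-9
        )

    def test_manual_log_likelihood(self, demog, model):
        data = ComparisonData(
            label="x",
            patterns=[AllelePattern(3, 1, 2, 0, 4), AllelePattern(3, 0, 2, 2, 2)],
        )
        expected = 4 * math.log(
            pattern_probability(AllelePattern(3, 1, 2, 0), demog, model)
        ) + 2 * math.log(
            pattern_probability(AllelePattern(3, 0, 2, 2), demog, model)
        )
        assert pair_log_likelihood(data, demog, model) == pytest.approx(expected)

    def test_corrections_agree_under_complete_sampling(self, demog, model):
        data = ComparisonData(
            label="x",
            patterns=[
                AllelePattern(4, 1, 4, 0, 3),
                AllelePattern(4, 2, 4, 3, 2),
                AllelePattern(4, 3, 4, 1, 1),
            ],
            constant_removed=True,
        )
        ll_site = pair_log_likelihood(data, demog, model, correction="per_site")
        ll_max = pair_log_likelihood(data, demog, model, correction="max_copies")
        assert ll_site == pytest.approx(ll_max, abs=1e-10)
        # and both equal the manual renormalization
        p_red, p_green = constant_probability(4, 4, demog, model)
        manual = sum(
            p.weight
            * math.log(
                pattern_probability(p, demog, model) / (1 - p_red - p_green)
            )
            for p in data.patterns
        )
        assert ll_site == pytest.approx(manual, abs=1e-10)

    def test_correction_with_constants_raises(self, small_data, model):
        with pytest.raises(ValueError):
            PairLikelihoodEngine(small_data, model, correction="per_site")

    def test_collection_additivity(self, small_collection, model, demog):
        demogs = [demog, PairDemography(0.02, 0.003, 0.002, 0.002)]
        total = collection_log_likelihood(
            small_collection, demogs, [model, model]
        )
        parts = sum(
            pair_log_likelihood(c, d, model)
            for c, d in zip(small_collection, demogs)
        )
        assert total == pytest.approx(parts, abs=1e-9)

    def test_shared_decomposition_cache_isolation(self, model, demog):
        # engines share branch decompositions through a module cache;
        # engines needing different column sets must not collide
        d1 = ComparisonData(
            label="a", patterns=[AllelePattern(4, 1, 4, 0, 2)]
        )
        d2 = ComparisonData(
            label="b",
            patterns=[AllelePattern(4, 2, 4, 1, 1), AllelePattern(3, 1, 2, 1, 1)],
        )
        args = (demog.div_time, demog.N_d1, demog.N_d2, demog.N_root)
        e1 = PairLikelihoodEngine(d1, model)
        ll1_first = e1.log_likelihood(*args)
        e2 = PairLikelihoodEngine(d2, model)
        ll2 = e2.log_likelihood(*args)
        assert ll2 == pytest.approx(
            pair_log_likelihood(d2, demog, model), abs=1e-9
        )
        assert e1.log_likelihood(*args) == pytest.approx(ll1_first, abs=1e-12)

    def test_likelihood_responds_to_time(self, small_data, model):
        lls = [
            pair_log_likelihood(
                small_data, PairDemography(t, 0.002, 0.002, 0.002), model
            )
            for t in (0.001, 0.01, 0.1)
        ]
        assert len(set(round(x, 6) for x in lls)) == 3
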