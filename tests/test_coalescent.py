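"""Coalescent engine: population functions, intensities, waiting times."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import ks_2samp

import reactree as rt
from reactree.coalescent import (
    CoalescenceError,
    draw_next_event_time,
    pair_coalescent_intensity,
    population_size,
)


def pair_model(pf, n=2, t_leaves=0.0, types=("L",)):
    return rt.CoalescentModel(
        types, tuple(rt.CoalescentReaction(t, pf) for t in types),
        leaves=(rt.LeafSchedule(t_leaves, types[0], n),),
    )


class TestPopulationFunctions:
    def test_constant(self):
        assert population_size(rt.ConstantPopulation(2.0), -3.7) == 2.0

    def test_exponential_closed_form(self):
        pf = rt.ExponentialGrowth(1.0, 1.0, t_ref=0.0)
        assert population_size(pf, -1.0) == pytest.approx(math.exp(-1.0))

    def test_piecewise(self):
        pf = rt.PiecewiseConstantPopulation((1.0, 2.0), (5.0,))
        assert population_size(pf, 7.0) == 2.0
        assert population_size(pf, 4.9) == 1.0

    @pytest.mark.parametrize("pf", [
        rt.ConstantPopulation(3.0),
        rt.ExponentialGrowth(2.0, 0.7, t_ref=1.0),
        rt.ExponentialGrowth(2.0, -0.4, t_ref=0.0),
        rt.PiecewiseConstantPopulation((1.0, 3.0, 0.5), (2.0, 4.0)),
    ])
    def test_pair_rate_integral_matches_quadrature(self, pf):
        """Analytic cumulative intensity agrees with numerical quadrature."""
        for a, b in [(-2.0, 1.0), (0.5, 6.0), (-5.0, 7.3)]:
            num, _ = quad(pf.pair_rate, a, b, limit=200,
                          points=list(getattr(pf, "change_times", ())))
            assert pf.integral_pair_rate(a, b) == pytest.approx(num, abs=1e-8)


class TestIntensity:
    def test_one_pair_unit_population(self):
        m = pair_model(rt.ConstantPopulation(1.0), n=2)
        assert pair_coalescent_intensity(m, {"L": 2}, 0.0) == pytest.approx(1.0)

    def test_ten_lineages_choose_two(self):
        m = pair_model(rt.ConstantPopulation(1.0), n=10)
        assert pair_coalescent_intensity(m, {"L": 10}, 0.0) == pytest.approx(45.0)

    def test_migration_adds_linear_term(self):
        m = rt.CoalescentModel(
            ("a", "b"),
            (rt.CoalescentReaction("a", rt.ConstantPopulation(1.0)),
             rt.CoalescentReaction("b", rt.ConstantPopulation(1.0))),
            migrations=(rt.Migration("a", "b", rt.RateFunction.constant(0.3)),),
            leaves=(rt.LeafSchedule(0.0, "a", 2), rt.LeafSchedule(0.0, "b", 1)),
        )
        # C(2,2)/1 + C(1,2)/1 + 2*0.3
        assert pair_coalescent_intensity(m, {"a": 2, "b": 1}, 0.0) == \
            pytest.approx(1.0 + 0.0 + 0.6)


class TestWaitingTimes:
    def test_exponential_unit_mean_for_one_pair(self, rng):
        m = pair_model(rt.ConstantPopulation(1.0))
        waits = []
        for _ in range(4000):
            t, comp = draw_next_event_time(m, {"L": 2}, 0.0, -math.inf, rng)
            assert comp is not None
            waits.append(-t)
        mean, se = np.mean(waits), np.std(waits) / np.sqrt(len(waits))
        assert abs(mean - 1.0) < 3 * se

    def test_inversion_consistent_with_quadrature(self, rng):
        """The drawn time solves  integral of intensity = Exp(1) deviate,
        checked by re-integrating the intensity numerically."""
        pf = rt.PiecewiseConstantPopulation((2.0, 0.5, 1.5), (-3.0, -1.0))
        m = pair_model(pf, n=4)
        k = {"L": 4}
        for _ in range(200):
            state = rng.bit_generator.state
            t, comp = draw_next_event_time(m, k, 0.0, -math.inf, rng)
            rng.bit_generator.state = state
            target = rng.exponential(1.0)
            rng.bit_generator.state = state  # consume identically
            draw_next_event_time(m, k, 0.0, -math.inf, rng)
            num, _ = quad(lambda u: 6.0 * pf.pair_rate(u), t, 0.0,
                          points=[-3.0, -1.0], limit=200)
            assert num == pytest.approx(target, rel=1e-8, abs=1e-8)

    def test_zero_lineages_returns_floor(self, rng):
        m = pair_model(rt.ConstantPopulation(1.0))
        t, comp = draw_next_event_time(m, {"L": 0}, 0.0, -2.5, rng)
        assert t == -2.5 and comp is None

    def test_shrinking_population_may_never_coalesce(self, rng):
        # Backward in time the population explodes (r < 0 forward), so the
        # cumulative intensity converges and coalescence can fail.
        pf = rt.ExponentialGrowth(1.0, -5.0, t_ref=0.0)
        m = pair_model(pf)
        with pytest.raises(CoalescenceError):
            for _ in range(200):
                draw_next_event_time(m, {"L": 2}, 0.0, -math.inf, rng)


class TestSimulate:
    def test_single_leaf_zero_height(self):
        m = pair_model(rt.ConstantPopulation(1.0), n=1)
        root = rt.simulate_coalescent(m, 1)
        assert root.is_leaf and rt.tree_height(root) == 0.0

    def test_pair_tmrca_mean_equals_ne(self):
        m = pair_model(rt.ConstantPopulation(1.0), n=2)
        h = [rt.tree_height(rt.simulate_coalescent(m, rt.replicate_rng(90, i)))
             for i in range(4000)]
        mean, se = np.mean(h), np.std(h) / np.sqrt(len(h))
        assert abs(mean - 1.0) < 3 * se

    def test_kingman_levels_n10(self):
        """E[T_k] = 2 Ne / (k(k-1)) for each level k, and the TMRCA mean
        2 Ne (1 - 1/n); checked per level at 3 standard errors."""
        n = 10
        m = pair_model(rt.ConstantPopulation(1.0), n=n)
        level_waits = {k: [] for k in range(2, n + 1)}
        heights = []
        for i in range(3000):
            root = rt.simulate_coalescent(m, rt.replicate_rng(91, i))
            depths = sorted(-nd.time for nd in root.walk() if nd.children)
            heights.append(depths[-1])
            prev = 0.0
            for k, d in zip(range(n, 1, -1), depths):
                level_waits[k].append(d - prev)
                prev = d
        mean, se = np.mean(heights), np.std(heights) / np.sqrt(len(heights))
        assert abs(mean - 2 * (1 - 1 / n)) < 3 * se
        for k, waits in level_waits.items():
            mean = np.mean(waits)
            se = np.std(waits) / np.sqrt(len(waits))
            assert abs(mean - 2 / (k * (k - 1))) < 3.5 * se, f"level {k}"

    def test_exponential_growth_matches_inverse_transform_oracle(self):
        """Pair TMRCA under exponential growth vs direct inverse-transform
        sampling from the analytic cumulative intensity."""
        N0, r, t_leaf = 5.0, 0.8, 0.0
        pf = rt.ExponentialGrowth(N0, r, t_ref=t_leaf)
        m = pair_model(pf, n=2, t_leaves=t_leaf)
        sim = np.array([
            rt.tree_height(rt.simulate_coalescent(m, rt.replicate_rng(92, i)))
            for i in range(3000)
        ])
        # Lambda(h) = (exp(r h) - 1) / (r N0) for a pair looking back h
        rng = np.random.default_rng(555)
        e = rng.exponential(1.0, size=3000)
        oracle = np.log1p(r * N0 * e) / r
        assert ks_2samp(sim, oracle).pvalue > 0.01

    def test_two_deme_exchangeability(self):
        """Symmetric migration, equal deme sizes: the tree-height law must
        be invariant under relabelling the demes."""
        def heights(flip, seed):
            a, b = ("a", "b") if not flip else ("b", "a")
            m = rt.CoalescentModel(
                ("a", "b"),
                (rt.CoalescentReaction("a", rt.ConstantPopulation(1.0)),
                 rt.CoalescentReaction("b", rt.ConstantPopulation(1.0))),
                migrations=(rt.Migration("a", "b", rt.RateFunction.constant(1.0)),
                            rt.Migration("b", "a", rt.RateFunction.constant(1.0))),
                leaves=(rt.LeafSchedule(0.0, a, 3), rt.LeafSchedule(0.0, b, 2)),
            )
            return [rt.tree_height(rt.simulate_coalescent(m, rt.replicate_rng(seed, i)))
                    for i in range(1500)]

        assert ks_2samp(heights(False, 93), heights(True, 94)).pvalue > 0.01

    def test_mean_field_logistic_pair_rate(self):
        """At carrying capacity the birth-death coalescent approximation's
        per-pair rate is 2 lambda / K on the mean-field trajectory."""
        from reactree.oracles import logistic_fixture
        K, lam = 80.0, 1.0
        m = logistic_fixture(K, birth_rate=lam, t_end=40.0, n_samples=10,
                             x0=int(K))
        pf = rt.MeanFieldPopulation(m, "X", bd_approx=True)
        assert pf.size(20.0) == pytest.approx(K, rel=1e-6)
        assert pf.pair_rate(20.0) == pytest.approx(2 * lam / K, rel=1e-6)
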