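"""CIWP-PSO: pyramid layering, complementary weights, opposition learning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kapurseg import (
    KapurObjective,
    SwarmConfig,
    WeightParams,
    ciwp_step,
    complementary_weights,
    compute_histogram,
    exhaustive_optimal_thresholds,
    generate_synthetic_image,
    init_swarm,
    inverse_sigmoid,
    partition_layers,
    random_mixture_spec,
    rebin_histogram,
    rol_update,
    run_ciwp_pso,
)


class TestPartitionLayers:
    def test_standard_swarm_split(self):
        rng = np.random.default_rng(0)
        part = partition_layers(rng.random(30), rate=0.9)
        assert part.worst.size == 3 and part.middle.size == 26
        assert part.n_total == 30

    def test_four_particle_example(self):
        part = partition_layers(np.array([5.0, 3.0, 1.0, 9.0]), rate=0.75)
        assert part.elite == 3
        assert part.worst.tolist() == [2]
        assert sorted(part.middle.tolist()) == [0, 1]

    def test_all_equal_tie_rule(self):
        part = partition_layers(np.ones(10), rate=0.8)
        assert part.elite == 0  # lower index ranks better on ties
        assert part.worst.tolist() == [8, 9]

    def test_too_few_particles(self):
        with pytest.raises(ValueError):
            partition_layers(np.array([1.0, 2.0]), rate=0.9)

    def test_rate_one_disables_worst_layer(self):
        part = partition_layers(np.arange(10.0), rate=1.0)
        assert part.worst.size == 0
        assert part.middle.size == 9

    def test_layer_fitness_ordering(self):
        rng = np.random.default_rng(1)
        f = rng.random(30)
        part = partition_layers(f, rate=0.9)
        assert f[part.elite] == f.max()
        assert f[part.worst].max() <= f[part.middle].min()


class TestInverseSigmoid:
    def test_zero_maps_to_zero(self):
        assert inverse_sigmoid(0.0) == 0.0

    def test_endpoint_value(self):
        # ln(0.98 / 0.02) / 7.8 = ln(49) / 7.8
        assert inverse_sigmoid(0.5) == pytest.approx(np.log(49) / 7.8, abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=0.5))
    def test_odd_function(self, x):
        assert inverse_sigmoid(-x) == pytest.approx(-inverse_sigmoid(x), abs=1e-12)

    def test_strictly_increasing(self):
        xs = np.linspace(-0.5, 0.5, 201)
        ys = inverse_sigmoid(xs)
        assert np.all(np.diff(ys) > 0)


class TestComplementaryWeights:
    def test_median_fitness_gives_midpoint(self):
        w, wr = complementary_weights(5.0, 10.0, 0.0)
        assert w == wr == pytest.approx(0.7)

    def test_endpoint_weights(self):
        w_best, wr_best = complementary_weights(1.0, 1.0, 0.0)
        assert w_best == pytest.approx(0.7 + 0.4 * np.log(49) / 7.8, abs=1e-12)
        assert wr_best == pytest.approx(0.7 - 0.4 * np.log(49) / 7.8, abs=1e-12)

    def test_complementarity_exact(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            lo, hi = np.sort(rng.uniform(0, 100, 2))
            if lo == hi:
                continue
            f = rng.uniform(lo, hi)
            w, wr = complementary_weights(f, hi, lo)
            assert w + wr == 0.5 + 0.9

    def test_degenerate_swarm_maps_to_midpoint(self):
        w, wr = complementary_weights(3.0, 3.0, 3.0)
        assert w == wr == pytest.approx(0.7)

    def test_monotone_and_bounded(self):
        f = np.linspace(0.0, 1.0, 101)
        w, wr = complementary_weights(f, 1.0, 0.0)
        assert np.all(np.diff(w) > 0) and np.all(np.diff(wr) < 0)
        assert np.all((w >= 0.5) & (w <= 0.9))


class TestRolUpdate:
    @pytest.mark.parametrize(
        "pos,lo,hi,r,expected",
        [
            (10.0, 0.0, 10.0, 1.0, 0.0),  # exact opposition of the boundary
            (5.0, 0.0, 10.0, 1.0, 5.0),  # midpoint is a fixed point
            (100.0, 0.0, 4095.0, 0.01, 4094.0),
        ],
    )
    def test_forced_draws(self, forced_rng, pos, lo, hi, r, expected):
        out = rol_update(np.array([[pos]]), lo, hi, forced_rng(r))
        assert out[0, 0] == pytest.approx(expected)

    def test_output_in_bounds_and_covers_opposition_range(self):
        rng = np.random.default_rng(21)
        p = 300.0
        outs = rol_update(np.full((20_000, 1), p), 1.0, 4095.0, rng).ravel()
        assert outs.min() >= 1.0 and outs.max() <= 4095.0
        # pre-clamp support is [LB+UB-P, LB+UB]; here entirely inside the box
        assert outs.min() < (1 + 4095 - p) + 30
        assert outs.max() > 4095.0 - 30


class TestCiwpStep:
    def _swarm(self, cfg, seed=0):
        swarm = init_swarm(cfg, np.random.default_rng(seed))
        swarm.fitness = np.random.default_rng(seed + 1).random(cfg.n_particles)
        return swarm

    def test_elite_position_unchanged(self):
        cfg = SwarmConfig.for_levels(256, 3, n_particles=10)
        swarm = self._swarm(cfg)
        part = partition_layers(swarm.fitness, cfg.rate)
        before = swarm.positions[part.elite].copy()
        ciwp_step(swarm, part, swarm.positions[part.elite], cfg, np.random.default_rng(2))
        assert np.array_equal(swarm.positions[part.elite], before)

    def test_zero_learning_factors_reduce_to_weighted_inertia(self, forced_rng):
        cfg = SwarmConfig.for_levels(256, 2, n_particles=6, c1=0.0, c2=0.0, rate=1.0)
        swarm = self._swarm(cfg)
        part = partition_layers(swarm.fitness, cfg.rate)
        x0 = swarm.positions.copy()
        v0 = swarm.velocities.copy()
        w, _ = complementary_weights(
            swarm.fitness, swarm.fitness.max(), swarm.fitness.min(),
            WeightParams.from_config(cfg),
        )
        ciwp_step(swarm, part, x0[part.elite], cfg, forced_rng())
        mid = part.middle
        expected = np.clip(x0[mid] + w[mid, None] * v0[mid], cfg.lower, cfg.upper)
        assert np.allclose(swarm.positions[mid], expected)

    def test_all_positions_stay_in_bounds(self):
        cfg = SwarmConfig.for_levels(4096, 4, n_particles=12)
        swarm = self._swarm(cfg, seed=5)
        rng = np.random.default_rng(6)
        for _ in range(200):
            swarm.fitness = rng.random(cfg.n_particles)
            part = partition_layers(swarm.fitness, cfg.rate)
            ciwp_step(swarm, part, swarm.positions[part.elite], cfg, rng)
            assert np.all(
                (swarm.positions >= cfg.lower) & (swarm.positions <= cfg.upper)
            )


class TestRunCiwpPso:
    def test_reaches_two_threshold_optimum(self):
        spec = random_mixture_spec(77, n_modes=2)
        hist = rebin_histogram(compute_histogram(generate_synthetic_image(spec)), 256)
        _, optimum = exhaustive_optimal_thresholds(hist, 2)
        res = run_ciwp_pso(KapurObjective(hist), SwarmConfig.for_levels(256, 2, seed=3))
        assert optimum - res.best_fitness <= 1e-6
        assert res.best_fitness <= optimum + 1e-12  # never beats the certificate

    def test_convergence_monotone_and_improving(self):
        spec = random_mixture_spec(78, n_modes=3)
        hist = rebin_histogram(compute_histogram(generate_synthetic_image(spec)), 256)
        for seed in (0, 1, 2):
            res = run_ciwp_pso(
                KapurObjective(hist),
                SwarmConfig.for_levels(256, 3, n_iterations=40, seed=seed),
            )
            assert np.all(np.diff(res.convergence) >= 0)
            assert res.best_fitness >= res.convergence[0]
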