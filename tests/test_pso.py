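"""Swarm optimizer: update algebra, monotone global best, convergence on
analytic landscapes, determinism and hyperparameter decoding."""

import numpy as np
import pytest

from usqrate import backbone as bb
from usqrate import pso


def sphere(x):
    return -float(np.sum(x**2))


class TestStepAlgebra:
    def test_pure_inertia_shifts_position_by_velocity(self):
        """w=1, c1=c2=0: velocity unchanged, x moves by exactly v."""
        state = pso.init_swarm(sphere, [(-5, 5), (-5, 5)], n_particles=3, seed=0, w=1.0, c1=0.0, c2=0.0)
        for p in state.particles:
            p.velocity = np.array([0.3, -0.2])
        before = [p.position.copy() for p in state.particles]
        pso.step(state, sphere)
        for p, x0 in zip(state.particles, before):
            assert np.allclose(p.velocity, [0.3, -0.2])
            assert np.allclose(p.position, np.clip(x0 + p.velocity, -5, 5))

    def test_converged_particle_velocity_reduces_to_inertia(self):
        """x = pbest = gbest: both attraction terms vanish, v' = w*v."""
        state = pso.init_swarm(sphere, [(-5, 5)], n_particles=2, seed=1, w=0.5)
        p = state.particles[0]
        p.position = state.gbest.copy()
        p.pbest = state.gbest.copy()
        p.velocity = np.array([0.8])
        pso.step(state, sphere)
        assert np.allclose(state.particles[0].velocity, 0.5 * 0.8)

    def test_positions_respect_bounds(self):
        state = pso.init_swarm(sphere, [(-1, 1)] * 3, n_particles=10, seed=2)
        for _ in range(20):
            pso.step(state, sphere)
            for p in state.particles:
                assert np.all(p.position >= -1) and np.all(p.position <= 1)

    def test_gbest_is_max_of_pbests(self):
        state = pso.init_swarm(sphere, [(-5, 5)] * 2, n_particles=8, seed=3)
        for _ in range(10):
            pso.step(state, sphere)
            assert state.gbest_fitness == max(p.pbest_fitness for p in state.particles)

    def test_nonfinite_fitness_recorded_as_neg_inf(self, caplog):
        def bad(x):
            return float("nan")

        with caplog.at_level("WARNING"):
            state = pso.init_swarm(bad, [(0, 1)], n_particles=2, seed=0)
        assert all(p.pbest_fitness == -np.inf for p in state.particles)
        assert "non-finite" in caplog.text
        pso.step(state, bad)  # must not crash


class TestOptimize:
    def test_sphere_convergence(self):
        _, best, _ = pso.optimize(
            sphere, [(-5, 5), (-5, 5)], n_particles=20, n_iterations=100, seed=0, w=0.7, c1=1.5, c2=1.5
        )
        assert best > -1e-3

    def test_shifted_parabola_locates_optimum(self):
        best_x, _, _ = pso.optimize(
            lambda x: -((x[0] - 2.0) ** 2), [(0, 5)], n_particles=10, n_iterations=50, seed=0
        )
        assert abs(best_x[0] - 2.0) < 0.01

    def test_rastrigin_basin(self):
        """2-D Rastrigin restricted to the central basin around the optimum."""

        def rastrigin(x):
            return -float(20 + np.sum(x**2 - 10 * np.cos(2 * np.pi * x)))

        best_x, best, _ = pso.optimize(rastrigin, [(-0.45, 0.45)] * 2, n_particles=20, n_iterations=80, seed=1)
        assert best > -1e-4
        assert np.all(np.abs(best_x) < 0.01)

    def test_constant_fitness(self):
        _, best, _ = pso.optimize(lambda x: 3.5, [(0, 1)], n_particles=5, n_iterations=5, seed=0)
        assert best == 3.5

    def test_identical_seed_identical_trace(self):
        r1 = pso.optimize(sphere, [(-5, 5)] * 2, n_particles=8, n_iterations=30, seed=42)
        r2 = pso.optimize(sphere, [(-5, 5)] * 2, n_particles=8, n_iterations=30, seed=42)
        assert r1[2] == r2[2]
        assert np.array_equal(r1[0], r2[0])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_gbest_trace_monotone_nondecreasing(self, seed):
        rng = np.random.default_rng(seed)
        shift = rng.uniform(-2, 2, size=3)

        def f(x):
            return -float(np.sum((x - shift) ** 2))

        _, _, trace = pso.optimize(f, [(-3, 3)] * 3, n_particles=10, n_iterations=40, seed=seed)
        assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_empty_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            pso.optimize(sphere, [], n_particles=5, n_iterations=5)

    def test_too_few_particles_rejected(self):
        with pytest.raises(ValueError, match="particles"):
            pso.optimize(sphere, [(0, 1)], n_particles=1, n_iterations=5)


class TestHyperparameterTuning:
    def test_decoding_rounds_and_scales(self):
        cfg = pso._decode(
            np.array([-2.0, 7.6, 0.001, 0.25]),
            ["log10_learning_rate", "batch_size", "weight_decay", "dropout"],
            bb.TrainConfig(),
        )
        assert cfg.learning_rate == pytest.approx(0.01)
        assert cfg.batch_size == 8
        assert cfg.weight_decay == pytest.approx(0.001)
        assert cfg.dropout == pytest.approx(0.25)

    def test_unknown_dimension_rejected(self):
        with pytest.raises(ValueError, match="unknown search dimension"):
            pso.tune_hyperparameters(bb.smallnet(), [], [], {"momentum": (0, 1)})

    def test_tunes_learning_rate_on_toy_problem(self, rng):
        size = (16, 16)
        imgs = [np.clip(np.full(size, 0.2) + rng.normal(0, 0.01, size), 0, 1) for _ in range(6)]
        imgs += [np.clip(np.full(size, 0.8) + rng.normal(0, 0.01, size), 0, 1) for _ in range(6)]
        labels = ["dark"] * 6 + ["bright"] * 6
        spec = bb.smallnet(input_size=size)
        cfg, fitness, trace = pso.tune_hyperparameters(
            spec,
            imgs,
            labels,
            {"log10_learning_rate": (-3.0, -0.5)},
            n_particles=3,
            n_iterations=2,
            seed=0,
            base_config=bb.TrainConfig(epochs=8, batch_size=4, seed=0),
        )
        assert 10**-3 <= cfg.learning_rate <= 10**-0.5
        assert fitness == 1.0
        assert all(b >= a for a, b in zip(trace, trace[1:]))
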