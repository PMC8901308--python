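"""Swarm primitives: schedules, transfer function, mutation/recombination,
and the full optimizers' convergence and reproducibility contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpsokit.swarm import (
    ParticleState,
    SwarmConfig,
    SwarmState,
    combine_bits,
    decay_schedule,
    inertia_weight,
    modified_bpso_step,
    mutate_bits,
    position_update_continuous,
    run_levy_optimizer,
    run_optimizer,
    sample_binary_position,
    sigmoid,
    velocity_update,
)


def make_config(**kw):
    kw.setdefault("n_particles", 5)
    kw.setdefault("dims", 6)
    kw.setdefault("n_iterations", 100)
    return SwarmConfig(**kw)


class TestInertiaWeight:
    @pytest.mark.parametrize(
        "t, expected",
        [(0, 0.9), (100, 0.4), (50, 0.65)],
    )
    def test_linear_schedule(self, t, expected):
        cfg = make_config(w_max=0.9, w_min=0.4, n_iterations=100)
        assert inertia_weight(t, cfg) == pytest.approx(expected)

    def test_out_of_range_iteration_rejected(self):
        cfg = make_config()
        with pytest.raises(ValueError):
            inertia_weight(101, cfg)
        with pytest.raises(ValueError):
            inertia_weight(-1, cfg)

    def test_bounded_and_monotone(self):
        cfg = make_config(w_max=1.2, w_min=0.3, n_iterations=40)
        ws = [inertia_weight(t, cfg) for t in range(41)]
        assert all(0.3 <= w <= 1.2 for w in ws)
        assert all(a >= b for a, b in zip(ws, ws[1:]))


class TestVelocityUpdate:
    def test_stationary_at_consensus(self, rng):
        x = np.array([1.0, 2.0])
        p = ParticleState(x.copy(), np.zeros(2), x.copy(), 0.0)
        v = velocity_update(p, x, w=0.7, config=make_config(dims=2), rng=rng)
        assert np.allclose(v, 0)

    def test_pure_inertia(self, rng):
        p = ParticleState(np.zeros(2), np.array([2.0, -1.0]), np.zeros(2), 0.0)
        cfg = make_config(dims=2, d1=0.0, d2=0.0, v_clamp=None)
        v = velocity_update(p, np.zeros(2), w=1.0, config=cfg, rng=rng)
        assert np.allclose(v, [2.0, -1.0])

    def test_cognitive_pull_toward_pbest(self):
        # r1 == 1 forced by a degenerate generator stub
        class OnesRng:
            def random(self, n):
                return np.ones(n)

        p = ParticleState(np.zeros(2), np.zeros(2), np.ones(2), 0.0)
        cfg = make_config(dims=2, d1=1.0, d2=0.0, v_clamp=None)
        v = velocity_update(p, np.zeros(2), w=0.0, config=cfg, rng=OnesRng())
        assert np.allclose(v, [1.0, 1.0])

    def test_clamped_to_v_clamp(self, rng):
        p = ParticleState(np.zeros(3), np.full(3, 100.0), np.zeros(3), 0.0)
        cfg = make_config(dims=3, v_clamp=6.0, d1=0, d2=0)
        v = velocity_update(p, np.zeros(3), w=1.0, config=cfg, rng=rng)
        assert np.all(np.abs(v) <= 6.0)

    def test_dimension_mismatch(self, rng):
        p = ParticleState(np.zeros(3), np.zeros(3), np.zeros(3), 0.0)
        with pytest.raises(ValueError):
            velocity_update(p, np.zeros(4), 0.5, make_config(dims=3), rng)


def test_position_update_continuous():
    assert np.allclose(position_update_continuous([1, 2], [0, 0]), [1, 2])
    assert np.allclose(position_update_continuous([0.5, 0.5], [0.25, -0.5]), [0.75, 0.0])
    with pytest.raises(ValueError):
        position_update_continuous([1, 2], [1, 2, 3])


class TestSigmoid:
    def test_known_values(self):
        assert sigmoid(0.0) == pytest.approx(0.5)
        assert sigmoid(1.0) == pytest.approx(0.7310585786, abs=1e-9)
        assert sigmoid(40.0) == pytest.approx(1.0, abs=1e-15)

    @given(st.floats(min_value=-20, max_value=20))
    @settings(derandomize=True, max_examples=50)
    def test_symmetry(self, v):
        assert sigmoid(v) + sigmoid(-v) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_increasing(self):
        grid = np.linspace(-20, 20, 201)
        assert np.all(np.diff(sigmoid(grid)) > 0)


class TestSampleBinaryPosition:
    def test_saturated_transfer(self, rng):
        assert not sample_binary_position(np.full(50, -40.0), rng).any()
        assert sample_binary_position(np.full(50, 40.0), rng).all()

    def test_marginal_probability_at_zero_velocity(self, rng):
        draws = np.concatenate(
            [sample_binary_position(np.zeros(100), rng) for _ in range(100)]
        )
        assert draws.mean() == pytest.approx(0.5, abs=0.015)


class TestDecaySchedule:
    @pytest.mark.parametrize("m_base, t, expected", [(5.0, 0, 5.0), (5.0, 100, 0.0), (4.0, 25, 3.0)])
    def test_values(self, m_base, t, expected):
        assert decay_schedule(m_base, t) == pytest.approx(expected)

    def test_clamped_past_horizon_and_monotone(self):
        vals = [decay_schedule(4.0, t) for t in range(0, 160, 5)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert decay_schedule(4.0, 150) == 0.0

    def test_generalized_horizon(self):
        assert decay_schedule(4.0, 25, horizon=50) == pytest.approx(2.0)

    def test_negative_iteration_rejected(self):
        with pytest.raises(ValueError):
            decay_schedule(1.0, -1)


class TestMutateBits:
    def test_zero_count_is_identity(self, rng):
        bits = np.array([0, 1, 1, 0, 1])
        assert np.array_equal(mutate_bits(bits, 0.0, rng), bits)

    def test_hamming_distance_bounded_by_dims(self, rng):
        bits = np.zeros(8, dtype=int)
        for _ in range(200):
            out = mutate_bits(bits, 7.99, rng)
            assert (out != bits).sum() <= 8

    def test_mean_hamming_distance(self, rng):
        bits = np.zeros(10, dtype=int)
        dists = [(mutate_bits(bits, 4.0, rng) != bits).sum() for _ in range(10000)]
        assert np.mean(dists) == pytest.approx(2.0, abs=0.1)

    @given(st.integers(0, 2**31 - 1), st.floats(0, 9.99))
    @settings(derandomize=True, max_examples=30)
    def test_output_stays_binary(self, seed, m_t):
        r = np.random.default_rng(seed)
        out = mutate_bits(r.integers(0, 2, 10), m_t, r)
        assert set(np.unique(out)).issubset({0, 1})


class TestCombineBits:
    @pytest.mark.parametrize("b", [0, 1])
    def test_agreement_is_kept(self, b, rng):
        assert combine_bits(b, b, rng) == b

    def test_disagreement_takes_gbest_with_one_third_probability(self, rng):
        draws = [combine_bits(0, 1, rng) for _ in range(30000)]
        assert np.mean(draws) == pytest.approx(1 / 3, abs=0.01)

    def test_non_bit_rejected(self, rng):
        with pytest.raises(ValueError):
            combine_bits(2, 0, rng)


class TestModifiedStep:
    def test_fixed_point_without_mutation(self, rng):
        cfg = make_config(dims=4, m1_base=0.0, m2_base=0.0)
        pos = np.array([1, 0, 1, 1])
        particles = [
            ParticleState(pos.copy(), np.zeros(4), pos.copy(), 3.0) for _ in range(3)
        ]
        state = SwarmState(particles, pos.copy(), 3.0, t=0)
        modified_bpso_step(state, cfg, lambda b: float(b.sum()), rng)
        assert state.t == 1
        assert state.gbest_fitness == 3.0
        for p in state.particles:
            assert np.array_equal(p.position, pos)

    def test_single_particle_solves_onemax(self):
        cfg = SwarmConfig(n_particles=1, dims=6, n_iterations=200, seed=4)
        res = run_optimizer(lambda b: float(b.sum()), cfg)
        assert res.best_fitness == 6.0

    def test_non_finite_fitness_names_particle(self, rng):
        cfg = make_config(dims=4)
        pos = np.array([1, 0, 1, 1])
        particles = [ParticleState(pos.copy(), np.zeros(4), pos.copy(), 0.0)]
        state = SwarmState(particles, pos.copy(), 0.0)
        with pytest.raises(ValueError, match="particle 0"):
            modified_bpso_step(state, cfg, lambda b: float("nan"), rng)


class TestRunOptimizer:
    @pytest.mark.parametrize("variant", ["continuous", "standard_binary", "modified_binary"])
    def test_same_seed_is_bit_identical(self, variant):
        def fit(x):
            return -float(np.sum(np.asarray(x, float) ** 2))

        cfg = dict(n_particles=8, dims=5, n_iterations=20, variant=variant, seed=11)
        a = run_optimizer(fit, SwarmConfig(**cfg))
        b = run_optimizer(fit, SwarmConfig(**cfg))
        assert np.array_equal(a.best_position, b.best_position)
        assert a.best_fitness == b.best_fitness
        assert np.array_equal(a.fitness_history, b.fitness_history)
        assert a.evaluations == b.evaluations

    @pytest.mark.parametrize("variant", ["standard_binary", "modified_binary"])
    def test_gbest_monotone_and_positions_binary(self, variant):
        seen = []

        def fit(b):
            seen.append(np.asarray(b))
            return float(b.sum()) - 0.5 * b[0]

        cfg = SwarmConfig(n_particles=6, dims=7, n_iterations=30, variant=variant, seed=2)
        res = run_optimizer(fit, cfg)
        assert np.all(np.diff(res.fitness_history) >= 0)
        assert len(res.fitness_history) == 30
        for pos in seen:
            assert set(np.unique(pos)).issubset({0, 1})

    def test_sphere_convergence_continuous(self):
        cfg = SwarmConfig(
            n_particles=30, dims=2, n_iterations=100, variant="continuous", seed=3
        )
        res = run_optimizer(lambda x: -float(np.sum(x**2)), cfg)
        assert np.linalg.norm(res.best_position) < 0.1

    def test_onemax_success_rate_over_seeds(self):
        hits = 0
        for seed in range(50):
            cfg = SwarmConfig(n_particles=20, dims=12, n_iterations=100, seed=seed)
            res = run_optimizer(lambda b: float(b.sum()), cfg)
            hits += res.best_fitness == 12.0
        assert hits >= 45

    def test_evaluation_count(self):
        calls = 0

        def fit(b):
            nonlocal calls
            calls += 1
            return float(b.sum())

        cfg = SwarmConfig(n_particles=4, dims=5, n_iterations=10, seed=0)
        res = run_optimizer(fit, cfg)
        assert res.evaluations == calls == 4 * 11  # init + 10 iterations


class TestLevyOptimizer:
    def test_deterministic(self):
        cfg = SwarmConfig(n_particles=6, dims=8, n_iterations=15, variant="standard_binary", seed=5)
        a = run_levy_optimizer(lambda b: float(b.sum()), cfg)
        b = run_levy_optimizer(lambda b: float(b.sum()), cfg)
        assert np.array_equal(a.best_position, b.best_position)
        assert a.best_fitness == b.best_fitness

    def test_onemax_success_rate(self):
        hits = 0
        for seed in range(20):
            cfg = SwarmConfig(
                n_particles=20, dims=12, n_iterations=100, variant="standard_binary", seed=seed
            )
            hits += run_levy_optimizer(lambda b: float(b.sum()), cfg).best_fitness == 12.0
        assert hits >= 10


class TestSwarmConfig:
    def test_invalid_configs_rejected_before_evaluation(self):
        with pytest.raises(ValueError):
            SwarmConfig(n_particles=0, dims=3)
        with pytest.raises(ValueError):
            SwarmConfig(n_particles=3, dims=3, w_max=0.2, w_min=0.5)
        with pytest.raises(ValueError):
            SwarmConfig(n_particles=3, dims=3, m1_base=3.0)
        with pytest.raises(ValueError):
            SwarmConfig(n_particles=3, dims=3, variant="annealing")

    def test_auto_v_clamp_resolution(self):
        assert SwarmConfig(n_particles=2, dims=2, variant="standard_binary").v_clamp == 6.0
        assert SwarmConfig(n_particles=2, dims=2, variant="modified_binary").v_clamp is None
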