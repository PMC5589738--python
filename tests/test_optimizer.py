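import math

import numpy as np
import pytest

from anfiswo.optimizer import (
    ObjectiveSpec,
    OptimizerResult,
    WOAConfig,
    _State,
    coefficients,
    encircle_update,
    explore_update,
    ga_minimize,
    init_population,
    minimize,
    pso_minimize,
    spiral_update,
    woa_minimize,
    woa_step,
)


def sphere_spec(dim=5, half_width=10.0):
    return ObjectiveSpec(
        fn=lambda x: float(np.sum(np.asarray(x) ** 2)),
        lower=np.full(dim, -half_width),
        upper=np.full(dim, half_width),
    )


class TestObjectiveSpec:
    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            ObjectiveSpec(fn=lambda x: 0.0, lower=np.array([0.0]), upper=np.array([0.0]))

    def test_non_finite_becomes_inf(self):
        spec = ObjectiveSpec(fn=lambda x: float("nan"), lower=np.zeros(1), upper=np.ones(1))
        assert spec.evaluate(np.array([0.5])) == np.inf


class TestInitPopulation:
    def test_within_bounds(self):
        spec = sphere_spec()
        pop = init_population(spec, 1000, seed=0)
        assert np.all(pop >= spec.lower) and np.all(pop <= spec.upper)

    def test_deterministic(self):
        spec = sphere_spec()
        np.testing.assert_array_equal(
            init_population(spec, 50, seed=3), init_population(spec, 50, seed=3)
        )

    def test_uniform_moments(self):
        # Monte-Carlo oracle: mean of U(-10, 10) is 0, se = width/sqrt(12n)
        spec = sphere_spec()
        pop = init_population(spec, 10_000, seed=7)
        se = 20.0 / math.sqrt(12.0 * 10_000)
        assert np.all(np.abs(pop.mean(axis=0)) < 3 * se)


class TestCoefficients:
    @pytest.mark.parametrize(
        "a,r,expect_A,expect_C",
        [(2.0, 0.5, 0.0, 1.0), (0.0, 0.3, 0.0, 0.6), (2.0, 1.0, 2.0, 2.0)],
    )
    def test_hand_values(self, a, r, expect_A, expect_C):
        A, C = coefficients(a, np.array([r]))
        assert A[0] == pytest.approx(expect_A)
        assert C[0] == pytest.approx(expect_C)

    def test_ranges(self, rng):
        for _ in range(50):
            a = float(rng.uniform(0, 2))
            A, C = coefficients(a, rng.random(4))
            assert np.all(np.abs(A) <= a + 1e-12)
            assert np.all((C >= 0) & (C <= 2))


class TestUpdateRules:
    def test_encircle_a_zero_lands_on_best(self, rng):
        x, best = rng.random(3), rng.random(3)
        np.testing.assert_allclose(encircle_update(x, best, 0.0, rng.random(3)), best)

    def test_encircle_fixed_point(self, rng):
        best = rng.random(3)
        np.testing.assert_allclose(
            encircle_update(best, best, rng.random(3), np.ones(3)), best
        )

    def test_encircle_hand_arithmetic(self):
        got = encircle_update(
            np.array([0.0, 0.0]), np.array([1.0, 2.0]),
            np.array([0.5, 0.5]), np.array([1.0, 1.0]),
        )
        np.testing.assert_allclose(got, [0.5, 1.0])

    def test_spiral_zero_distance(self, rng):
        best = rng.random(4)
        for l in (-1.0, -0.3, 0.0, 0.7, 1.0):
            np.testing.assert_allclose(spiral_update(best, best, 1.0, l), best)

    def test_spiral_cosine_zero(self, rng):
        x, best = rng.random(2), rng.random(2)
        np.testing.assert_allclose(spiral_update(x, best, 1.0, 0.25), best, atol=1e-12)

    def test_spiral_hand_arithmetic(self):
        got = spiral_update(np.array([0.0]), np.array([1.0]), 1.0, 0.0)
        assert got[0] == pytest.approx(2.0)

    def test_explore_a_zero_lands_on_rand(self, rng):
        x, x_rand = rng.random(3), rng.random(3)
        np.testing.assert_allclose(explore_update(x, x_rand, 0.0, rng.random(3)), x_rand)

    def test_explore_fixed_point(self, rng):
        x_rand, C = rng.random(3), rng.random(3)
        np.testing.assert_allclose(
            explore_update(C * x_rand, x_rand, rng.random(3), C), x_rand
        )

    def test_explore_hand_arithmetic(self):
        got = explore_update(
            np.array([2.0]), np.array([0.0]), np.array([1.0]), np.array([2.0])
        )
        assert got[0] == pytest.approx(-2.0)


class _ScriptedRng:
    """Replays a fixed stream for random()/uniform()/integers()."""

    def __init__(self, singles, uniforms, vectors, ints):
        self.singles = list(singles)
        self.uniforms = list(uniforms)
        self.vectors = list(vectors)
        self.ints = list(ints)

    def random(self, size=None):
        if size is None:
            return self.singles.pop(0)
        return np.asarray(self.vectors.pop(0), dtype=float)

    def uniform(self, lo, hi, size=None):
        return self.uniforms.pop(0)

    def integers(self, n, size=None):
        return self.ints.pop(0)


def naive_woa_step(positions, fitness, best, best_fit, spec, config, a, stream):
    """Loop-based reimplementation of one iteration, consuming the same
    scripted stream in the same documented order as the production code."""
    n, dim = positions.shape
    new_pos = []
    for i in range(n):
        x = positions[i]
        p = stream.random()
        if p >= 0.5:
            l = stream.uniform(-1.0, 1.0)
            d = np.abs(best - x)
            x_new = d * np.exp(config.b * l) * np.cos(2 * np.pi * l) + best
        else:
            rA = stream.random()
            A = 2 * a * rA - a
            C = 2 * stream.random(dim)
            if abs(A) < config.tau_a:
                x_new = best - A * np.abs(C * best - x)
            else:
                j = stream.integers(n)
                x_new = positions[j] - A * np.abs(C * positions[j] - x)
        new_pos.append(np.clip(x_new, spec.lower, spec.upper))
    new_pos = np.array(new_pos)
    fit = np.array([spec.evaluate(x) for x in new_pos])
    i_best = int(np.argmin(fit))
    if fit[i_best] < best_fit:
        best_fit = float(fit[i_best])
        best = new_pos[i_best].copy()
    return new_pos, fit, best, best_fit


class TestWoaStep:
    def _fixed_instance(self):
        spec = ObjectiveSpec(
            fn=lambda x: float(np.sum((np.asarray(x) - 1.0) ** 2)),
            lower=np.array([-5.0, -5.0]),
            upper=np.array([5.0, 5.0]),
        )
        positions = np.array([[0.5, -0.5], [2.0, 3.0], [-1.0, 0.0]])
        fitness = np.array([spec.evaluate(x) for x in positions])
        i = int(np.argmin(fitness))
        return spec, positions, fitness, positions[i].copy(), float(fitness[i])

    def test_matches_naive_reimplementation_exactly(self):
        # whale 1 spirals, whale 2 encircles, whale 3 explores
        singles = [0.7, 0.3, 0.4, 0.2, 0.9]       # p1, p2, rA2, p3, rA3
        uniforms = [0.15]                          # l1
        vectors = [[0.3, 0.8], [0.6, 0.1]]         # C2, C3
        ints = [1]                                 # random whale for 3
        config = WOAConfig(n=3, max_iter=10, seed=0)
        a = 1.2

        spec, positions, fitness, best, best_fit = self._fixed_instance()
        state = _State(positions.copy(), fitness.copy(), best.copy(), best_fit)
        woa_step(state, spec, config, _ScriptedRng(singles, uniforms, vectors, ints), a)

        spec2, positions2, fitness2, best2, best_fit2 = self._fixed_instance()
        exp_pos, exp_fit, exp_best, exp_best_fit = naive_woa_step(
            positions2, fitness2, best2, best_fit2, spec2, config, a,
            _ScriptedRng(singles, uniforms, vectors, ints),
        )
        np.testing.assert_array_equal(state.positions, exp_pos)
        np.testing.assert_array_equal(state.fitness, exp_fit)
        np.testing.assert_array_equal(state.best_position, exp_best)
        assert state.best_fitness == exp_best_fit

    def test_elitist_best_never_worsens(self):
        spec = sphere_spec(dim=3)
        config = WOAConfig(n=8, max_iter=30, seed=5)
        rng = np.random.default_rng(5)
        positions = init_population(spec, 8, rng)
        fitness = np.array([spec.evaluate(x) for x in positions])
        i = int(np.argmin(fitness))
        state = _State(positions, fitness, positions[i].copy(), float(fitness[i]))
        prev = state.best_fitness
        for t in range(1, 31):
            a = 2.0 * (1.0 - t / 30)
            woa_step(state, spec, config, rng, a)
            assert state.best_fitness <= prev
            prev = state.best_fitness

    def test_forced_encircle_with_zero_a_collapses_to_best(self):
        spec = sphere_spec(dim=2)
        config = WOAConfig(n=3, max_iter=10, seed=0)
        positions = np.array([[1.0, 2.0], [3.0, -1.0], [0.5, 0.5]])
        fitness = np.array([spec.evaluate(x) for x in positions])
        i = int(np.argmin(fitness))
        best = positions[i].copy()
        state = _State(positions, fitness, best.copy(), float(fitness[i]))
        # p < 0.5 for all whales, a = 0 so A = 0 -> everyone lands on best;
        # singles interleave as p1, rA1, p2, rA2, p3, rA3
        stream = _ScriptedRng(
            singles=[0.1, 0.3, 0.1, 0.3, 0.1, 0.3],
            uniforms=[], vectors=[[0.2, 0.9]] * 3, ints=[],
        )
        woa_step(state, spec, config, stream, a=0.0)
        np.testing.assert_allclose(state.positions, np.tile(best, (3, 1)))

    def test_schedule_reaches_zero(self):
        max_iter = 100
        a = 2.0 * (1.0 - max_iter / max_iter)
        assert abs(a) < 1e-12


class TestMinimizers:
    def test_woa_sphere_paper_settings(self):
        # empirical oracle: global minimum is 0
        hits = 0
        for seed in range(10):
            res = woa_minimize(sphere_spec(), WOAConfig(n=25, max_iter=100, seed=seed))
            hits += res.best_fitness < 1e-2
        assert hits >= 9

    def test_woa_1d_absolute(self):
        spec = ObjectiveSpec(
            fn=lambda x: float(abs(x[0] - 3.0)), lower=np.array([0.0]), upper=np.array([10.0])
        )
        res = woa_minimize(spec, WOAConfig(n=25, max_iter=100, seed=0))
        assert abs(res.best_position[0] - 3.0) < 0.05

    def test_trace_contract(self):
        res = woa_minimize(sphere_spec(), WOAConfig(n=10, max_iter=100, seed=1))
        assert len(res.trace) <= 100
        assert np.all(np.diff(res.trace) <= 0)
        assert res.best_fitness == res.trace[-1]

    def test_best_fitness_matches_position(self):
        spec = sphere_spec()
        res = woa_minimize(spec, WOAConfig(n=10, max_iter=50, seed=2))
        assert res.best_fitness == pytest.approx(spec.evaluate(res.best_position))

    def test_stop_tol(self):
        res = woa_minimize(
            sphere_spec(), WOAConfig(n=25, max_iter=100, seed=0, stop_tol=1.0)
        )
        assert len(res.trace) < 100
        assert res.best_fitness <= 1.0

    def test_positions_respect_bounds(self):
        spec = ObjectiveSpec(
            fn=lambda x: float(-np.sum(x)), lower=np.zeros(3), upper=np.ones(3)
        )
        res = woa_minimize(spec, WOAConfig(n=10, max_iter=50, seed=0))
        assert np.all(res.best_position >= 0) and np.all(res.best_position <= 1)

    def test_determinism(self):
        a = woa_minimize(sphere_spec(), WOAConfig(n=10, max_iter=40, seed=11))
        b = woa_minimize(sphere_spec(), WOAConfig(n=10, max_iter=40, seed=11))
        np.testing.assert_array_equal(a.best_position, b.best_position)
        np.testing.assert_array_equal(a.trace, b.trace)
        assert a.n_evaluations == b.n_evaluations

    def test_initial_positions_injected(self):
        spec = sphere_spec()
        warm = np.zeros(5)   # the global optimum
        res = woa_minimize(
            spec, WOAConfig(n=10, max_iter=5, seed=0), initial_positions=[warm]
        )
        assert res.best_fitness == 0.0

    @pytest.mark.parametrize("minimizer", [pso_minimize, ga_minimize])
    def test_baseline_sphere(self, minimizer):
        hits = 0
        for seed in range(10):
            res = minimizer(sphere_spec(), WOAConfig(n=25, max_iter=100, seed=seed))
            hits += res.best_fitness < 1e-1
        assert hits >= 8

    @pytest.mark.parametrize("minimizer", [pso_minimize, ga_minimize])
    def test_baseline_contracts(self, minimizer):
        a = minimizer(sphere_spec(), WOAConfig(n=10, max_iter=40, seed=3))
        b = minimizer(sphere_spec(), WOAConfig(n=10, max_iter=40, seed=3))
        np.testing.assert_array_equal(a.best_position, b.best_position)
        assert np.all(np.diff(a.trace) <= 0)

    def test_dispatch(self):
        res = minimize("woa", sphere_spec(), WOAConfig(n=10, max_iter=10, seed=0))
        assert isinstance(res, OptimizerResult)
        with pytest.raises(ValueError, match="unknown optimizer"):
            minimize("gradient", sphere_spec(), WOAConfig())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            WOAConfig(n=1)
        with pytest.raises(ValueError):
            WOAConfig(max_iter=0)
        with pytest.raises(ValueError):
            WOAConfig(tau_a=0.0)
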