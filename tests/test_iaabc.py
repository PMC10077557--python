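"""Unit and property tests for the bee-colony optimizer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uvbee import iaabc
from uvbee.iaabc import (
    ColonyConfig,
    HoneySource,
    SearchSpace,
    candidate_basic,
    candidate_iaabc,
    fitness_of,
    griewank,
    inertia_weight,
    init_sources,
    levy_step,
    mantegna_sigma,
    optimize,
    selection_probabilities,
)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


# ---------------------------------------------------------------------------
# search space and initialization
# ---------------------------------------------------------------------------

class TestSearchSpace:
    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace(2, np.array([0.0, 1.0]), np.array([1.0, 0.0]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace(3, np.zeros(2), np.ones(2))


class TestInitSources:
    def test_count_shape_and_bounds(self):
        space = SearchSpace.cube(5, -600, 600)
        cfg = ColonyConfig(n_sources=35, seed=0)
        sources = init_sources(sphere, space, cfg, np.random.default_rng(0))
        assert len(sources) == 35
        for s in sources:
            assert s.position.shape == (5,)
            assert np.all(s.position >= -600) and np.all(s.position <= 600)
            assert s.trials == 0
            assert s.fitness == fitness_of(s.objective)

    def test_zero_width_interval_collapses(self):
        space = SearchSpace(3, np.full(3, 2.0), np.full(3, 2.0))
        sources = init_sources(sphere, space, ColonyConfig(n_sources=4),
                               np.random.default_rng(1))
        for s in sources:
            assert np.array_equal(s.position, [2.0, 2.0, 2.0])

    def test_seeded_determinism(self):
        space = SearchSpace.cube(4, -1, 1)
        cfg = ColonyConfig(n_sources=6)
        a = init_sources(sphere, space, cfg, np.random.default_rng(42))
        b = init_sources(sphere, space, cfg, np.random.default_rng(42))
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.position, sb.position)


# ---------------------------------------------------------------------------
# fitness and selection
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("f, expected", [(0.0, 1.0), (1.0, 0.5), (-2.0, 3.0)])
def test_fitness_of_canonical_values(f, expected):
    assert fitness_of(f) == expected


def test_fitness_of_rejects_non_finite():
    for bad in (math.nan, math.inf, -math.inf):
        with pytest.raises(ValueError):
            fitness_of(bad)


@given(st.floats(min_value=-1e12, max_value=1e12))
@settings(max_examples=100, derandomize=True)
def test_fitness_positive_and_decreasing(f):
    fit = fitness_of(f)
    assert fit > 0
    if f >= 0:
        assert fitness_of(f + 1.0) < fit


class TestSelectionProbabilities:
    def test_uniform_for_equal_fitness(self):
        p = selection_probabilities([2.0] * 5)
        assert np.allclose(p, 0.2)

    def test_single_source(self):
        assert np.allclose(selection_probabilities([0.7]), [1.0])

    def test_proportionality(self):
        assert np.allclose(selection_probabilities([1.0, 3.0]), [0.25, 0.75])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            selection_probabilities([])

    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=1,
                    max_size=20))
    @settings(max_examples=100, derandomize=True)
    def test_sums_to_one_order_preserving(self, fits):
        p = selection_probabilities(fits)
        assert abs(p.sum() - 1.0) < 1e-12
        order = np.argsort(fits)
        assert np.all(np.diff(p[order]) >= -1e-15)


# ---------------------------------------------------------------------------
# inertia weight and Levy steps
# ---------------------------------------------------------------------------

class TestInertiaWeight:
    CFG = ColonyConfig(max_cycles=2000, omega_min=0.15, omega_max=1.05)

    def test_boundaries_and_midpoint(self):
        assert inertia_weight(0, self.CFG) == pytest.approx(1.05)
        assert inertia_weight(2000, self.CFG) == pytest.approx(0.15)
        assert inertia_weight(1000, self.CFG) == pytest.approx(0.60)

    def test_monotone_non_increasing(self):
        vals = [inertia_weight(c, self.CFG) for c in range(0, 2001, 50)]
        assert np.all(np.diff(vals) <= 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            inertia_weight(-1, self.CFG)
        with pytest.raises(ValueError):
            inertia_weight(2001, self.CFG)


class TestLevyStep:
    def test_mantegna_sigma_value(self):
        # independent evaluation of the closed form at beta = 1.5
        beta = 1.5
        expected = (math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
                    / (math.gamma((1 + beta) / 2) * beta
                       * 2 ** ((beta - 1) / 2))) ** (1 / beta)
        assert mantegna_sigma(1.5) == pytest.approx(expected, rel=1e-12)
        assert mantegna_sigma(1.5) == pytest.approx(0.6966, abs=1e-4)

    def test_seeded_reproducibility(self):
        a = [levy_step(np.random.default_rng(3), 1.5) for _ in range(10)]
        b = [levy_step(np.random.default_rng(3), 1.5) for _ in range(10)]
        assert a == b

    def test_heavier_tail_than_gaussian(self):
        n = 100_000
        rng = np.random.default_rng(0)
        levy = np.array([levy_step(rng, 1.5) for _ in range(n)])
        gauss = np.random.default_rng(0).normal(size=n)
        frac_levy = np.mean(np.abs(levy) > 5)
        frac_gauss = np.mean(np.abs(gauss) > 5)
        assert frac_levy > 0
        assert frac_levy > frac_gauss

    def test_beta_range_enforced(self):
        rng = np.random.default_rng(0)
        for beta in (1.0, 2.5, 0.5):
            with pytest.raises(ValueError):
                levy_step(rng, beta)


# ---------------------------------------------------------------------------
# candidate moves
# ---------------------------------------------------------------------------

class TestCandidates:
    space = SearchSpace.cube(3, -10, 10)
    cfg = ColonyConfig(levy_scale=0.0)

    def _sources(self):
        a = HoneySource(np.array([1.0, 2.0, 3.0]), 14.0, fitness_of(14.0))
        b = HoneySource(np.array([4.0, 5.0, 6.0]), 77.0, fitness_of(77.0))
        return a, b

    def test_basic_zero_step_keeps_source(self):
        a, b = self._sources()
        pos = candidate_basic(a, b, 1, self.space, r=0.0)
        assert np.array_equal(pos, a.position)

    def test_basic_zero_difference_keeps_source(self):
        a, _ = self._sources()
        b = HoneySource(a.position.copy(), a.objective, a.fitness)
        pos = candidate_basic(a, b, 0, self.space, r=0.77)
        assert np.array_equal(pos, a.position)

    def test_basic_changes_single_dimension_and_clamps(self):
        a, b = self._sources()
        wide = HoneySource(np.array([1.0, 200.0, 3.0]), 0.0, 1.0)
        pos = candidate_basic(wide, b, 1, self.space, r=1.0)
        assert pos[1] == 10.0  # clamped to upper bound
        assert pos[0] == wide.position[0] and pos[2] == wide.position[2]

    def test_self_reference_rejected(self):
        a, _ = self._sources()
        with pytest.raises(ValueError):
            candidate_basic(a, a, 0, self.space, r=0.5)
        with pytest.raises(ValueError):
            candidate_iaabc(a, a, 0, 1.0, self.space,
                            ColonyConfig(omega_max=1.05), r=0.5)

    def test_iaabc_at_omega_one_matches_basic(self):
        a, b = self._sources()
        cfg = ColonyConfig(omega_min=0.15, omega_max=1.05, levy_scale=0.0)
        for r in (-0.9, 0.0, 0.4, 1.0):
            expect = candidate_basic(a, b, 2, self.space, r=r)
            got = candidate_iaabc(a, b, 2, 1.0, self.space, cfg, r=r)
            assert np.allclose(got, expect)

    def test_iaabc_contracts_position_by_omega(self):
        # with zero neighbour difference the move is pure position contraction
        a, _ = self._sources()
        b = HoneySource(a.position.copy(), a.objective, a.fitness)
        cfg = ColonyConfig(omega_min=0.15, omega_max=1.05, levy_scale=0.0)
        pos = candidate_iaabc(a, b, 0, 0.5, self.space, cfg, r=0.3)
        assert pos[0] == pytest.approx(0.5 * a.position[0])
        assert np.array_equal(pos[1:], a.position[1:])

    def test_iaabc_levy_consumes_rng_only_when_enabled(self):
        a, b = self._sources()
        cfg_on = ColonyConfig(levy_scale=0.1)
        cfg_off = ColonyConfig(levy_scale=0.0)
        on = candidate_iaabc(a, b, 0, 1.0, self.space, cfg_on,
                             rng=np.random.default_rng(5))
        off = candidate_iaabc(a, b, 0, 1.0, self.space, cfg_off,
                              rng=np.random.default_rng(5))
        assert not np.array_equal(on, off)  # Levy term actually applied


# ---------------------------------------------------------------------------
# griewank
# ---------------------------------------------------------------------------

class TestGriewank:
    def test_global_optimum_value(self):
        for dim in (1, 2, 5, 30):
            assert griewank(np.zeros(dim)) == 0.0

    def test_hand_computed_point(self):
        # f(pi, 0) = 1 + pi^2/4000 - cos(pi) cos(0) = 2 + pi^2/4000
        assert griewank([math.pi, 0.0]) == pytest.approx(2 + math.pi ** 2 / 4000,
                                                         rel=1e-12)

    def test_non_negative_on_domain(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-600, 600, size=(10_000, 5))
        vals = np.apply_along_axis(griewank, 1, pts)
        assert np.all(vals >= 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            griewank([])


# ---------------------------------------------------------------------------
# full optimizer
# ---------------------------------------------------------------------------

class TestOptimize:
    def test_convex_recovery_2d(self):
        target = np.array([1.5, -2.0])
        space = SearchSpace.cube(2, -10, 10)
        cfg = ColonyConfig(seed=1)
        res = optimize(lambda x: float(np.sum((x - target) ** 2)), space, cfg)
        assert res.best_objective <= 1e-6
        assert res.cycles_run <= 2000

    def test_1d_quadratic_parameter_recovery(self):
        space = SearchSpace.cube(1, -5, 5)
        res = optimize(lambda x: float((x[0] - 0.7) ** 2), space,
                       ColonyConfig(seed=3))
        assert abs(res.best_position[0] - 0.7) <= 1e-4

    def test_trace_monotone_and_consistent(self):
        space = SearchSpace.cube(3, -5, 5)
        res = optimize(sphere, space, ColonyConfig(max_cycles=100, seed=0,
                                                   fitness_tol=0.0))
        assert np.all(np.diff(res.trace) <= 0)
        assert res.best_objective == res.trace[-1]
        assert res.cycles_run == res.trace.size

    def test_positions_stay_in_bounds(self):
        space = SearchSpace.cube(2, -1, 1)
        seen = []

        def recording(x):
            seen.append(x.copy())
            return sphere(x)

        optimize(recording, space, ColonyConfig(max_cycles=30, seed=2,
                                                fitness_tol=0.0))
        arr = np.array(seen)
        assert np.all(arr >= -1) and np.all(arr <= 1)

    def test_variants_identical_with_unit_omega_no_levy(self):
        space = SearchSpace.cube(5, -600, 600)
        results = []
        for variant in ("abc", "iaabc"):
            cfg = ColonyConfig(max_cycles=40, seed=7, omega_min=1.0,
                               omega_max=1.0, levy_scale=0.0, fitness_tol=0.0)
            results.append(optimize(griewank, space, cfg, variant=variant))
        assert np.array_equal(results[0].trace, results[1].trace)
        assert np.array_equal(results[0].best_position, results[1].best_position)

    def test_non_finite_objective_reported_with_context(self):
        space = SearchSpace.cube(1, -1, 1)

        calls = {"n": 0}

        def flaky(x):
            calls["n"] += 1
            return math.nan if calls["n"] > 40 else sphere(x)

        with pytest.raises(ValueError, match="non-finite"):
            optimize(flaky, space, ColonyConfig(max_cycles=50, seed=0,
                                                fitness_tol=0.0))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            optimize(sphere, SearchSpace.cube(1, -1, 1), ColonyConfig(),
                     variant="pso")
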