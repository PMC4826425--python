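import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sbcfw_isorank import testkit
from sbcfw_isorank.isorank_problem import (
    IsoRankProblem,
    compute_q,
    init_x,
    optimal_step,
    solve,
    update_p,
)
from sbcfw_isorank.product_operator import build_product_operator
from sbcfw_isorank.sbcfw_core import BlockScheme


def make_problem(alpha=1.0, sim=None, instance=None, xi=0.1):
    if instance is None:
        target = testkit.random_connected_graph(12, 4.0, seed=5)
        instance = testkit.plant_query(target, 4, rewire_fraction=0.0, seed=6)
        if alpha < 1.0 and sim is None:
            sim = testkit.synth_similarity(instance, signal=1.0, noise_pairs=3, seed=7)
    op = build_product_operator(instance.query, instance.target, sim=sim, alpha=alpha)
    return IsoRankProblem(op=op, xi=xi), op


class TestInitX:
    def test_fixed_partition_block_mass(self):
        scheme = BlockScheme(N=9, n_blocks=3, mode="fixed_partition", seed=0)
        x = init_x(scheme, seed=1)
        assert sorted(np.unique(x).tolist()) == [0.0, pytest.approx(1 / 3)]
        assert np.count_nonzero(x) == 3

    def test_simplex_membership(self):
        for n in (1, 3, 4):
            scheme = BlockScheme(N=10, n_blocks=n, seed=n)
            x = init_x(scheme, seed=n)
            assert x.sum() == pytest.approx(1.0, abs=1e-12)
            assert x.min() >= 0.0

    def test_single_block_gives_uniform(self):
        scheme = BlockScheme(N=8, n_blocks=1, seed=0)
        np.testing.assert_allclose(init_x(scheme, seed=0), np.full(8, 1 / 8))

    def test_uneven_blocks_still_sum_to_one(self):
        scheme = BlockScheme(N=11, n_blocks=3, seed=2)
        for seed in range(5):
            x = init_x(scheme, seed=seed)
            assert x.sum() == pytest.approx(1.0, abs=1e-12)


class TestObjective:
    def test_zero_at_stationary_distribution(self):
        problem, op = make_problem(alpha=1.0)
        x = op.d / op.d.sum()
        assert problem.objective(x) < 1e-24

    def test_matches_dense_residual_on_basis_vector(self, p3xk3_op):
        problem = IsoRankProblem(op=p3xk3_op)
        E = testkit.dense_Bhat(p3xk3_op) - np.eye(9)
        for t in range(9):
            e = np.zeros(9)
            e[t] = 1.0
            expected = 0.5 * float((E @ e) @ (E @ e))
            assert problem.objective(e) == pytest.approx(expected, abs=1e-12)

    def test_nonnegative_for_random_vectors(self, rng):
        problem, op = make_problem(alpha=0.5)
        for _ in range(20):
            assert problem.objective(rng.random(op.N)) >= 0.0

    def test_tracked_equals_direct(self, rng):
        problem, op = make_problem(alpha=0.5)
        x = rng.dirichlet(np.ones(op.N))
        problem.reset(x)
        assert problem.tracked_objective() == pytest.approx(problem.objective(x), abs=1e-10)


class TestPartialGradient:
    def test_zero_at_stationary_point(self):
        problem, op = make_problem(alpha=1.0)
        x = op.d / op.d.sum()
        problem.reset(x)
        g = problem.partial_gradient(np.arange(op.N))
        assert np.abs(g).max() < 1e-12

    def test_full_block_matches_dense_hessian_product(self, rng):
        problem, op = make_problem(alpha=0.5)
        M = testkit.dense_M(op)
        x = rng.dirichlet(np.ones(op.N))
        problem.reset(x)
        g = problem.partial_gradient(np.arange(op.N))
        np.testing.assert_allclose(g, M @ x, atol=1e-10)

    def test_complementary_blocks_sum_to_full_gradient(self, rng):
        problem, op = make_problem(alpha=0.5)
        x = rng.dirichlet(np.ones(op.N))
        problem.reset(x)
        half = op.N // 2
        b1, b2 = np.arange(half), np.arange(half, op.N)
        total = problem.partial_gradient(b1) + problem.partial_gradient(b2)
        np.testing.assert_allclose(total, problem.partial_gradient(np.arange(op.N)), atol=1e-12)


class TestBlockLMO:
    def test_moves_block_mass_to_smallest_gradient(self, rng):
        problem, op = make_problem(alpha=0.5)
        x = rng.dirichlet(np.ones(op.N))
        problem.reset(x)
        block = np.arange(5)
        s = problem.block_lmo(x, block)
        g = problem.partial_gradient(block)
        j = block[int(np.argmin(g[block]))]
        L = x[block].sum()
        assert s[j] == pytest.approx(L)
        assert np.count_nonzero(s[block]) == 1
        np.testing.assert_array_equal(s[5:], x[5:])

    def test_block_mass_conserved_and_simplex_preserved(self, rng):
        problem, op = make_problem(alpha=0.5)
        x = rng.dirichlet(np.ones(op.N))
        problem.reset(x)
        block = np.array([1, 4, 7, 9])
        s = problem.block_lmo(x, block)
        assert s[block].sum() == pytest.approx(x[block].sum(), abs=1e-15)
        assert s.sum() == pytest.approx(1.0, abs=1e-12)
        assert s.min() >= 0.0

    def test_attains_minimum_over_slice_vertices(self, rng):
        # brute force: every vertex of the feasible slice puts mass L on
        # one block coordinate; the LMO must pick the best one
        problem, op = make_problem(alpha=0.5)
        for trial in range(10):
            x = rng.dirichlet(np.ones(op.N))
            problem.reset(x)
            block = np.sort(rng.choice(op.N, size=8, replace=False))
            s = problem.block_lmo(x, block)
            g = problem.partial_gradient(block)
            L = x[block].sum()
            z_star = float(g @ (s - x))
            for j in block:
                v = x.copy()
                v[block] = 0.0
                v[j] = L
                assert z_star <= float(g @ (v - x)) + 1e-12

    def test_zero_mass_block_returns_x(self, rng):
        problem, op = make_problem(alpha=0.5)
        x = np.zeros(op.N)
        x[-1] = 1.0
        problem.reset(x)
        s = problem.block_lmo(x, np.arange(4))
        np.testing.assert_array_equal(s, x)

    def test_empty_block_rejected(self, rng):
        problem, op = make_problem(alpha=0.5)
        x = rng.dirichlet(np.ones(op.N))
        problem.reset(x)
        with pytest.raises(ValueError):
            problem.block_lmo(x, np.array([], dtype=int))


class TestOptimalStep:
    def test_null_direction_gives_zero(self, rng):
        p = rng.random(10)
        assert optimal_step(p, p) == 0.0

    def test_orthogonal_unit_case(self):
        p = np.array([1.0, 0.0])
        q = np.array([0.0, 1.0])
        assert optimal_step(p, q) == pytest.approx(0.5)

    def test_full_step_when_target_residual_zero(self, rng):
        p = rng.random(6)
        assert optimal_step(p, np.zeros(6)) == 1.0

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_beats_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.standard_normal(12)
        q = rng.standard_normal(12)
        gamma = optimal_step(p, q)
        grid = np.linspace(0.0, 1.0, 101)
        vals = 0.5 * np.sum((p[None, :] + grid[:, None] * (q - p)[None, :]) ** 2, axis=1)
        best = 0.5 * float(np.sum((p + gamma * (q - p)) ** 2))
        assert best <= vals.min() + 1e-10


class TestResidualRecurrences:
    def test_update_p_gamma_zero_is_identity(self, rng):
        problem, op = make_problem(alpha=0.5)
        x = rng.dirichlet(np.ones(op.N))
        p = op.apply_E(x)
        np.testing.assert_array_equal(update_p(op, p, 0.0, x, x), p)

    def test_update_p_matches_scratch(self, rng):
        problem, op = make_problem(alpha=0.5)
        x = rng.dirichlet(np.ones(op.N))
        problem.reset(x)
        block = np.arange(6)
        s = problem.block_lmo(x, block)
        for gamma in (0.25, 1.0):
            p_new = update_p(op, problem.p, gamma, s, x)
            np.testing.assert_allclose(p_new, op.apply_E(x + gamma * (s - x)), atol=1e-12)

    def test_compute_q_matches_scratch(self, rng):
        problem, op = make_problem(alpha=0.5)
        x = rng.dirichlet(np.ones(op.N))
        p = op.apply_E(x)
        block = np.array([2, 3, 5, 8])
        L = float(x[block].sum())
        j = 3
        q = compute_q(op, p, x, j, L, block)
        s = x.copy()
        s[block] = 0.0
        s[j] = L
        np.testing.assert_allclose(q, op.apply_E(s), atol=1e-12)
        assert 0.5 * float(q @ q) >= 0.0

    def test_debug_run_keeps_recurrences_tight(self, small_planted):
        x, state = solve(
            small_planted.query,
            small_planted.target,
            sim=small_planted.sim,
            alpha=0.5,
            n_blocks=4,
            xi=1e-12,
            seed=3,
            max_iter=300,
            debug=True,
            engine="python",
        )
        assert state.problem.max_p_err < 1e-10
        assert state.problem.max_q_err < 1e-10


class TestStop:
    def test_zero_residual_stops(self):
        problem, op = make_problem(alpha=1.0)
        x = op.d / op.d.sum()
        problem.reset(x)
        assert problem.stop(x)

    def test_ratio_above_xi_continues(self):
        problem, op = make_problem(alpha=1.0, xi=0.1)
        problem.p = np.zeros(op.N)
        problem.p[0] = 0.2
        x = np.zeros(op.N)
        x[0] = 1.0
        assert not problem.stop(x)


class TestSolve:
    def test_recovers_degree_stationary_distribution(self):
        target = testkit.random_connected_graph(20, 5.0, seed=11)
        inst = testkit.plant_query(target, 4, rewire_fraction=0.0, seed=12)
        x, state = solve(inst.query, inst.target, alpha=1.0, n_blocks=5, xi=1e-6,
                         seed=13, max_iter=2_000_000)
        op = build_product_operator(inst.query, inst.target, alpha=1.0)
        dbar = op.d / op.d.sum()
        assert state.converged
        assert np.abs(x - dbar).sum() < 1e-3

    def test_same_seed_is_bitwise_identical(self, small_planted):
        kwargs = dict(sim=small_planted.sim, alpha=0.5, n_blocks=4, xi=1e-3,
                      seed=99, max_iter=100_000)
        for engine in ("python", "compiled"):
            x1, s1 = solve(small_planted.query, small_planted.target, engine=engine, **kwargs)
            x2, s2 = solve(small_planted.query, small_planted.target, engine=engine, **kwargs)
            np.testing.assert_array_equal(x1, x2)
            assert s1.objective_trace == s2.objective_trace

    def test_engines_reach_equivalent_optima(self, small_planted):
        kwargs = dict(sim=small_planted.sim, alpha=0.5, n_blocks=4, xi=3e-4,
                      seed=5, max_iter=2_000_000)
        x_py, s_py = solve(small_planted.query, small_planted.target, engine="python", **kwargs)
        x_cc, s_cc = solve(small_planted.query, small_planted.target, engine="compiled", **kwargs)
        assert s_py.converged and s_cc.converged
        assert s_py.objective_trace[-1] == pytest.approx(s_cc.objective_trace[-1], rel=1e-3, abs=1e-12)
        assert np.abs(x_py - x_cc).sum() < 1e-2

    def test_simplex_preserved_along_python_run(self, small_planted):
        seen = []
        x, state = solve(small_planted.query, small_planted.target, sim=small_planted.sim,
                         alpha=0.5, n_blocks=4, xi=1e-3, seed=1, max_iter=2000, engine="python")
        assert abs(x.sum() - 1.0) < 1e-9
        assert x.min() >= -1e-12

    def test_single_block_matches_deterministic_frank_wolfe(self, small_planted):
        # n = 1 removes all randomness from the block choice: the python
        # engine must match an independent dense full-FW implementation
        op = build_product_operator(small_planted.query, small_planted.target,
                                    sim=small_planted.sim, alpha=0.5)
        E = testkit.dense_Bhat(op) - np.eye(op.N)
        M = E.T @ E
        x, state = solve(small_planted.query, small_planted.target, sim=small_planted.sim,
                         alpha=0.5, n_blocks=1, xi=1e-12, seed=7, max_iter=40, engine="python")
        x_ref = np.full(op.N, 1.0 / op.N)
        trace_ref = [0.5 * float(x_ref @ M @ x_ref)]
        for _ in range(40):
            g = M @ x_ref
            j = int(np.argmin(g))
            s = np.zeros(op.N)
            s[j] = 1.0
            d = s - x_ref
            denom = float(d @ M @ d)
            gamma = 0.0 if denom < 1e-15 else min(1.0, max(0.0, -float(g @ d) / denom))
            x_ref = x_ref + gamma * d
            trace_ref.append(0.5 * float(x_ref @ M @ x_ref))
        np.testing.assert_allclose(state.objective_trace, trace_ref, atol=1e-10)

    def test_unknown_engine_rejected(self, small_planted):
        with pytest.raises(ValueError, match="engine"):
            solve(small_planted.query, small_planted.target, sim=small_planted.sim,
                  engine="fortran")
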