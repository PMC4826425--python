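"""SBCFW instantiation of the IsoRank eigenvector problem.

IsoRank scores node pairs across two networks as the maximal right
eigenvector of the (similarity-mixed) product-graph transition matrix
Bhat.  Restated as a convex program, that eigenvector is the minimiser of

    f(x) = 1/2 ||Bhat x - x||^2    over the unit simplex {x >= 0, 1^T x = 1}.

Writing E = Bhat - I, the Hessian M = E^T E is positive semi-definite, so
f is convex with gradient M x.  The block-coordinate Frank-Wolfe
machinery then needs only:

* the residual p = E x, tracked by the rank-one recurrence
  p <- p + gamma E (s - x) so no full-size matvec on a dense iterate is
  ever repeated,
* a closed-form block subproblem: within the sampled block, move the
  whole block mass L onto the coordinate with the smallest partial
  gradient [E^T p]_block,
* the analytic exact line search for the quadratic in gamma.

All vectors live in the query-major pair order owned by
:mod:`~sbcfw_isorank.product_operator`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .network_io import Network, SimilarityTable
from .product_operator import ProductOperator, build_product_operator, restrict
from .sbcfw_core import BlockScheme, SolverState, run

__all__ = [
    "IsoRankProblem",
    "init_x",
    "optimal_step",
    "update_p",
    "compute_q",
    "solve",
]

# Feasibility slack for the simplex constraint under accumulated rounding.
SIMPLEX_SUM_TOL = 1e-9
SIMPLEX_NEG_TOL = 1e-12
# Below this, ||p - q||^2 is treated as a null direction.
DENOM_TOL = 1e-15


def init_x(scheme: BlockScheme, seed: Optional[int] = None) -> np.ndarray:
    """Sparse feasible start: one random block carries uniform mass 1/b.

    Keeping the support to a single block makes the first residual and
    partial-gradient computations as cheap as a regular iteration.  The
    mass is 1/b for the chosen block's actual size b, so the simplex
    constraint holds exactly even when N is not divisible by n.
    """
    rng = np.random.default_rng(seed) if seed is not None else scheme.rng
    i = int(rng.integers(scheme.n_blocks))
    if scheme.mode == "fixed_partition":
        block = scheme._fixed[i]
    else:
        block = rng.choice(scheme.N, size=scheme.block_sizes[i], replace=False)
        block.sort()
    x = np.zeros(scheme.N)
    x[block] = 1.0 / block.size
    return x


def optimal_step(p: np.ndarray, q: np.ndarray) -> float:
    """Exact line search for 1/2 ||p + gamma (q - p)||^2 over gamma in [0, 1].

    The unconstrained minimiser is (p.p - p.q) / ||p - q||^2; it is
    clipped to [0, 1], with gamma = 0 for non-descent or null directions.
    """
    pp = float(p @ p)
    pq = float(p @ q)
    qq = float(q @ q)
    denom = pp - 2.0 * pq + qq
    if denom < DENOM_TOL:
        return 0.0
    gamma_hat = (pp - pq) / denom
    if gamma_hat <= 0.0:
        return 0.0
    return min(1.0, gamma_hat)


def update_p(op: ProductOperator, p: np.ndarray, gamma: float, s: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residual recurrence p_{k+1} = p_k + gamma E (s - x).

    (s - x) is nonzero only inside the updated block, so the matvec costs
    one sparse product-operator application, never a dense N x N product.
    """
    delta = s - x
    return p + gamma * (op.apply_Bhat(delta) - delta)


def compute_q(op: ProductOperator, p: np.ndarray, x: np.ndarray, j: int, L: float, block: np.ndarray) -> np.ndarray:
    """q = E s via q = p + E (L e_j - U_i x), the block-sparse difference."""
    delta = np.zeros_like(x)
    delta[block] = -x[block]
    delta[j] += L
    return p + op.apply_Bhat(delta) - delta


@dataclass
class IsoRankProblem:
    """Callbacks wiring the IsoRank objective into the SBCFW loop.

    Tracks p = E x across iterations.  ``debug=True`` additionally
    recomputes p and q from scratch every iteration and records the worst
    deviation, which verifies the recurrences at O(N) extra cost.
    """

    op: ProductOperator
    xi: float = 0.1
    debug: bool = False

    def __post_init__(self) -> None:
        self.p: Optional[np.ndarray] = None
        self._q: Optional[np.ndarray] = None
        self.max_p_err = 0.0
        self.max_q_err = 0.0
        self.n_zero_mass_blocks = 0

    # -- objective ---------------------------------------------------------

    def objective(self, x: np.ndarray) -> float:
        """f(x) = 1/2 ||Bhat x - x||^2, recomputed directly from x."""
        r = self.op.apply_E(np.asarray(x, dtype=np.float64))
        return 0.5 * float(r @ r)

    def tracked_objective(self) -> float:
        """f(x) = 1/2 p^T p from the tracked residual."""
        if self.p is None:
            raise RuntimeError("residual not initialised; call reset(x0) first")
        return 0.5 * float(self.p @ self.p)

    def reset(self, x0: np.ndarray) -> None:
        """(Re)compute the tracked residual from scratch for a new iterate."""
        self.p = self.op.apply_E(x0)
        self._q = None
        self.max_p_err = 0.0
        self.max_q_err = 0.0
        self.n_zero_mass_blocks = 0

    # -- SBCFW callbacks ---------------------------------------------------

    def partial_gradient(self, block: np.ndarray) -> np.ndarray:
        """grad_i f(x) = U_i E^T p, using the tracked residual."""
        if self.p is None:
            raise RuntimeError("residual not initialised; call reset(x0) first")
        return restrict(self.op.apply_ET(self.p), block)

    def block_lmo(self, x: np.ndarray, block: np.ndarray) -> np.ndarray:
        """Solve the simplex-slice linear subproblem in closed form.

        The feasible slice fixes every coordinate outside the block and
        keeps the block mass L = sum(x[block]) constant, so its vertices
        put all of L on one block coordinate; the linear objective is
        minimised at the coordinate j with the smallest partial-gradient
        entry (ties -> smallest index).
        """
        block = np.asarray(block, dtype=np.intp)
        if block.size == 0:
            raise ValueError("empty coordinate block")
        grad_block = self.op.apply_ET(self.p)[block] if self.p is not None else None
        if grad_block is None:
            raise RuntimeError("residual not initialised; call reset(x0) first")
        j = int(block[int(np.argmin(grad_block))])
        L = float(np.sum(x[block]))
        s = x.copy()
        s[block] = 0.0
        s[j] = L
        if L == 0.0:
            self.n_zero_mass_blocks += 1
        self._q = compute_q(self.op, self.p, x, j, L, block)
        if self.debug:
            q_direct = self.op.apply_E(s)
            self.max_q_err = max(self.max_q_err, float(np.max(np.abs(self._q - q_direct))))
        return s

    def step_size(self, x: np.ndarray, s: np.ndarray, block: np.ndarray) -> float:
        if self._q is None:
            raise RuntimeError("step_size called before block_lmo")
        return optimal_step(self.p, self._q)

    def post_update(self, x_new: np.ndarray, s: np.ndarray, gamma: float, block: np.ndarray) -> None:
        # p_{k+1} = p + gamma (q - p), the recurrence with q = E s reused.
        self.p = self.p + gamma * (self._q - self.p)
        self._q = None
        if self.debug:
            p_direct = self.op.apply_E(x_new)
            self.max_p_err = max(self.max_p_err, float(np.max(np.abs(self.p - p_direct))))

    def is_feasible(self, x: np.ndarray) -> bool:
        return abs(float(np.sum(x)) - 1.0) <= SIMPLEX_SUM_TOL and float(np.min(x)) >= -SIMPLEX_NEG_TOL

    def stop(self, x: np.ndarray) -> bool:
        """||Bhat x - x||_2 <= xi ||x||_2, from the tracked residual."""
        return float(np.linalg.norm(self.p)) <= self.xi * float(np.linalg.norm(x))

    def stop_ratio(self, x: np.ndarray) -> float:
        return float(np.linalg.norm(self.p)) / max(float(np.linalg.norm(x)), 1e-300)


def solve(
    qnet: Network,
    tnet: Network,
    sim: Optional[SimilarityTable] = None,
    alpha: Optional[float] = None,
    n_blocks: int = 30,
    xi: float = 0.1,
    seed: int = 42,
    max_iter: Optional[int] = None,
    mode: str = "repartition",
    debug: bool = False,
    trace_path=None,
    engine: str = "auto",
) -> tuple[np.ndarray, SolverState]:
    """End-to-end SBCFW-IsoRank: build the operator, initialise, iterate.

    ``alpha`` defaults to 0.5 when a similarity table is supplied and 1.0
    otherwise.  All randomness (initial block, block sampling) derives
    from ``seed``; identical inputs and engine give bitwise-identical
    runs.  ``engine`` selects the inner loop: "python" runs the modular
    reference path through :func:`sbcfw_core.run`, "compiled" the
    numba-jitted loop in :mod:`~sbcfw_isorank.engine` (two orders of
    magnitude faster on long runs), and "auto" (default) prefers
    "compiled" unless ``debug`` or ``trace_path`` asks for the
    instrumented path.  Returns the final simplex score vector and the
    solver state.
    """
    if alpha is None:
        alpha = 0.5 if sim is not None else 1.0
    op = build_product_operator(qnet, tnet, sim=sim, alpha=alpha)
    ss = np.random.SeedSequence(seed)
    init_seed, scheme_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    scheme = BlockScheme(N=op.N, n_blocks=n_blocks, mode=mode, seed=scheme_seed)
    x0 = init_x(scheme, seed=init_seed)
    problem = IsoRankProblem(op=op, xi=xi, debug=debug)
    problem.reset(x0)
    if engine == "auto":
        engine = "python" if (debug or trace_path is not None) else "compiled"
    if engine == "compiled":
        from .engine import run_compiled

        if max_iter is None:
            from .sbcfw_core import default_max_iter

            max_iter = default_max_iter(op.N, n_blocks)
        x, p, k, converged, n_stalls, last_gamma, trace = run_compiled(
            op, n_blocks, mode, scheme_seed, xi, max_iter, x0, problem.p
        )
        problem.p = p
        state = SolverState(
            x=x, k=k, objective_trace=trace, last_gamma=last_gamma,
            last_block=None, converged=converged, n_stalls=n_stalls,
        )
    elif engine == "python":
        state = run(problem, scheme, x0, max_iter=max_iter, trace_path=trace_path)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    state.problem = problem  # type: ignore[attr-defined]  # debug counters
    return state.x, state
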