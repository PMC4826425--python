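"""Generic stochastic block-coordinate Frank-Wolfe (SBCFW) loop.

Frank-Wolfe (conditional gradient) minimises a convex differentiable f
over a compact convex set by repeatedly moving toward the minimiser of
the linearised objective.  The block-coordinate variant splits the N
coordinates into n near-equal blocks, picks one uniformly at random each
iteration, and solves the linear subproblem only over the slice of the
feasible set where all other blocks are frozen at their current values.
With an exact line search the objective is non-increasing for every
sample path, which this loop enforces as a runtime check.

The loop is problem-agnostic: objective, block linear-minimisation
oracle, step size, feasibility and stopping rule come in as callbacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Optional, Protocol, runtime_checkable

import numpy as np

__all__ = ["BlockScheme", "SolverState", "ProblemCallbacks", "run"]

# Objective increases beyond this are treated as implementation bugs.
MONOTONICITY_TOL = 1e-9


@dataclass
class BlockScheme:
    """Partition/sampling rule for coordinate blocks of near-equal size N/n.

    ``fixed_partition`` splits [0, N) once into n contiguous blocks and
    samples among them; ``repartition`` (default) draws a fresh uniform
    random partition every iteration and picks one of its blocks, which
    is equivalent to sampling a uniform random subset of the block size.
    A fixed partition conserves per-block mass under the simplex-slice
    subproblem, so mass can never cross block boundaries; repartitioning
    removes that pathology while keeping the expected-descent argument.
    """

    N: int
    n_blocks: int
    mode: str = "repartition"
    seed: Optional[int] = None
    rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not 1 <= self.n_blocks <= self.N:
            raise ValueError(f"need 1 <= n_blocks <= N, got n={self.n_blocks}, N={self.N}")
        if self.mode not in ("fixed_partition", "repartition"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.rng = np.random.default_rng(self.seed)
        base, rem = divmod(self.N, self.n_blocks)
        self._sizes = [base + 1] * rem + [base] * (self.n_blocks - rem)
        bounds = np.cumsum([0] + self._sizes)
        self._fixed = [np.arange(bounds[i], bounds[i + 1]) for i in range(self.n_blocks)]

    @property
    def block_sizes(self) -> list[int]:
        return list(self._sizes)

    def sample_block(self, k: int | None = None) -> np.ndarray:
        """Sorted index array of the block sampled for iteration ``k``."""
        i = int(self.rng.integers(self.n_blocks))
        if self.mode == "fixed_partition":
            return self._fixed[i]
        block = self.rng.choice(self.N, size=self._sizes[i], replace=False)
        block.sort()
        return block


@dataclass
class SolverState:
    """Final iterate and bookkeeping returned by :func:`run`."""

    x: np.ndarray
    k: int
    objective_trace: list[float]
    last_gamma: float
    last_block: Optional[np.ndarray]
    converged: bool
    n_stalls: int = 0


@runtime_checkable
class ProblemCallbacks(Protocol):
    """Callbacks an optimisation problem supplies to the generic loop.

    ``block_lmo`` must return s feasible with s = x outside the block;
    ``step_size`` must return gamma in [0, 1].  ``post_update`` (optional)
    lets stateful problems refresh tracked quantities after the iterate
    moves.
    """

    def objective(self, x: np.ndarray) -> float: ...

    def block_lmo(self, x: np.ndarray, block: np.ndarray) -> np.ndarray: ...

    def step_size(self, x: np.ndarray, s: np.ndarray, block: np.ndarray) -> float: ...

    def is_feasible(self, x: np.ndarray) -> bool: ...

    def stop(self, x: np.ndarray) -> bool: ...


def default_max_iter(N: int, n_blocks: int) -> int:
    """Generous iteration guard: 50 * n * ceil(log N)."""
    return 50 * n_blocks * max(1, ceil(np.log(max(N, 2))))


def run(
    problem: ProblemCallbacks,
    scheme: BlockScheme,
    x0: np.ndarray,
    max_iter: Optional[int] = None,
    trace_path=None,
) -> SolverState:
    """Iterate x <- x + gamma (s - x) until the problem's stop rule or max_iter.

    The objective is evaluated every iteration; an increase beyond
    MONOTONICITY_TOL raises, since exact line search guarantees descent.
    Hitting max_iter returns converged=False rather than raising.
    """
    x = np.asarray(x0, dtype=np.float64).copy()
    if not problem.is_feasible(x):
        raise ValueError("x0 is not feasible")
    if max_iter is None:
        max_iter = default_max_iter(scheme.N, scheme.n_blocks)

    trace = [float(problem.objective(x))]
    gamma = 0.0
    block: Optional[np.ndarray] = None
    n_stalls = 0
    k = 0
    converged = problem.stop(x)
    trace_fh = open(trace_path, "w") if trace_path is not None else None
    if trace_fh:
        trace_fh.write("k\tblock_size\tgamma\tobjective\n")
    try:
        while not converged and k < max_iter:
            block = scheme.sample_block(k)
            s = problem.block_lmo(x, block)
            gamma = float(problem.step_size(x, s, block))
            if not 0.0 <= gamma <= 1.0:
                raise RuntimeError(f"step size {gamma} outside [0, 1]")
            if gamma == 0.0:
                n_stalls += 1
            x = x + gamma * (s - x)
            hook = getattr(problem, "post_update", None)
            if hook is not None:
                hook(x, s, gamma, block)
            f = float(problem.objective(x))
            if f > trace[-1] + MONOTONICITY_TOL:
                raise RuntimeError(
                    f"objective increased at iteration {k}: {trace[-1]!r} -> {f!r}"
                )
            trace.append(f)
            if trace_fh:
                trace_fh.write(f"{k}\t{block.size}\t{gamma:.6g}\t{f:.12g}\n")
            k += 1
            converged = problem.stop(x)
    finally:
        if trace_fh:
            trace_fh.close()

    return SolverState(
        x=x,
        k=k,
        objective_trace=trace,
        last_gamma=gamma,
        last_block=block,
        converged=converged,
        n_stalls=n_stalls,
    )
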