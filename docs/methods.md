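# Methods

## Model

Two undirected, unweighted PPI networks G_a (query, N_a nodes) and G_b
(target, N_b nodes) are aligned on the pair space of dimension
N = N_a·N_b.  With A_a, A_b the symmetric adjacencies, the Kronecker
product B = A_a ⊗ A_b is the adjacency of the product graph over node
pairs, d = B·1 its degree vector (d[(u,v)] = deg_a(u)·deg_b(v)), and
B̄ = B·Diag(d)⁻¹ the column-stochastic transition matrix of the product
random walk.  External node similarity enters as the rank-one mixture
B̂ = αB̄ + (1−α)S̄1ᵀ with S̄ = S/‖S‖₁, which keeps B̂ column-stochastic
on the simplex.  The pair-score vector is the maximal right eigenvector
of B̂, recast as the convex program

    min f(x) = ½‖B̂x − x‖² = ½xᵀMx,   M = EᵀE, E = B̂ − I,

over the unit simplex.  M is positive semi-definite by construction, so
f is convex with gradient Mx and minimum 0 exactly at the eigenvector.

If G_a and G_b are connected and at least one is non-bipartite, the
product walk restricted to positive-degree pairs is irreducible and
aperiodic, so the eigenvector is unique; for α = 1 it is d/‖d‖₁ in
closed form, which the tests and the acceptance script exploit as an
exact oracle.  Inputs violating these assumptions are accepted with a
logged warning; zero-degree pairs get all-zero transition columns
(0/0 := 0).

## The solver

The block-coordinate Frank-Wolfe iteration, given the current iterate
x on the simplex and its tracked residual p = Ex:

1. sample a coordinate block of size ≈ N/n;
2. partial gradient g = [Eᵀ]_block p;
3. closed-form block LMO: the feasible slice fixes all coordinates
   outside the block and conserves the block mass L = Σ_block x, so its
   vertices put L on one block coordinate; the linearised objective is
   minimised at j = argmin g (ties to the smallest index), giving
   s = x − U_i x + L·e_j;
4. q = Es via q = p + E(s − x), where s − x has ≤ |block|+1 nonzeros;
5. exact line search on the quadratic: γ̂ = (pᵀp − pᵀq)/‖p − q‖²,
   clipped to [0, 1], γ = 0 for null or non-descent directions;
6. x ← x + γ(s − x), p ← p + γ(q − p);
7. stop when ‖p‖₂ ≤ ξ‖x‖₂.

Exact line search makes f(x^k) = ½‖p_k‖² non-increasing along every
sample path, which both engines enforce at runtime (an increase beyond
1e−9 raises, since it can only mean an implementation bug).  The
iterate stays on the simplex by convexity of the update.

Initialisation puts mass 1/b uniformly on one random block of size b,
so the first residual costs one sparse operator application; when N is
not divisible by n, blocks have size ⌊N/n⌋ or ⌈N/n⌉ and the init mass
uses the chosen block's true size, keeping 1ᵀx = 1 exact.

### Block sampling

Default mode re-draws a uniformly random partition every iteration and
picks one of its blocks (equivalently, a uniform random size-b subset).
With a partition fixed once, the subproblem conserves each block's mass
forever, so mass can never cross block boundaries and a sparse start
could not spread; re-randomising removes this pathology while keeping
the expected-descent argument intact.  `fixed_partition` (contiguous
index ranges) is retained as an option and its mass-conservation
property is pinned by a test.

### Degenerate iterations

A sampled block holding zero mass yields s = x (γ = 0); the iteration
counts, a stall counter records it, and no resampling happens inside an
iteration.  In repartition mode such stalls are transient.

## Two engines

`engine="python"` wires the problem callbacks through the generic,
problem-agnostic loop in `sbcfw_core` — readable, instrumented
(per-iteration debug recomputation of p and q from scratch, optional
TSV trace).  `engine="compiled"` (default for plain runs) executes the
identical algorithm as a numba-jitted kernel over raw CSR arrays,
because runs to tight tolerances take 10⁵–10⁶ iterations of a few tens
of microseconds each, where interpreter overhead would dominate by two
orders of magnitude.  The engines consume different random streams, so
trajectories differ; the suite asserts both reach the same objective
level, equivalent optima and identical matchings, and that each is
bitwise reproducible under a fixed seed.

## Parameters

- `alpha` (topology weight, default 0.5 with a similarity table, 1.0
  without): the similarity term is both biological prior and
  regulariser; α = 1 is the pure random walk, α = 0 returns S̄.
- `n_blocks` (default 30): per-iteration cost shrinks ∝ 1/n while the
  iteration count grows with n; 30 is a good throughput compromise on
  query-scale problems and matches the regime where the method's
  cost/iteration trade-off flattens.
- `xi` (default 0.1): stopping tolerance on ‖B̂x−x‖/‖x‖.  0.1 suffices
  for matching extraction on query problems; the oracle-comparison
  tests run to 1e−4–1e−6 to pin the optimum itself.
- `mode` (default `repartition`): see block sampling above.
- `seed`: drives the initial block and all block sampling; identical
  configurations are bitwise reproducible per engine.
- `max_iter` (default 50·n·⌈log N⌉): generous guard for ξ = 0.1 scale
  runs; deep-tolerance runs should pass an explicit cap. Hitting the
  cap sets `converged=False` instead of raising.

## Alignment extraction

The converged vector reshapes to an N_a×N_b score matrix
(query-major: X[u,v] = x[u·N_b+v]).  Greedy maximum matching —
repeatedly take the best remaining pair, ties toward the smallest query
then target index, striking matched rows/columns — gives a one-to-one
mapping, following established IsoRank practice; an argmax-per-row mode
exists for diagnostics.  Accuracy against a ground-truth mapping counts
correct pairs over all query nodes.  The extraction is deliberately
simple and deterministic; an optimal-assignment solver is out of scope.

## Synthetic benchmarks

`testkit` emulates the cross-database network-query setting: a
connected non-bipartite Erdős–Rényi-style target (components bridged,
a triangle closed if needed), a connected induced subgraph planted as
the query with known correspondence, degree-preserving
connectivity-preserving double-edge swaps on a fraction of target edges
modelling archival disagreement between interaction databases, and a
similarity table carrying score `signal` on true pairs plus uniformly
smaller noise entries.  Defaults used in the end-to-end checks —
100-node targets of mean degree 8, 6-node queries, 5 % rewiring, one
noise pair per query node — are desk-scale stand-ins for curated
complex-vs-interactome queries; real PPI networks differ in degree
heterogeneity, clustering and similarity-score structure, so perfect
recovery here demonstrates solver correctness, not expected accuracy on
real interactomes.

Dense oracles (explicit B̂, power iteration with L1 renormalisation,
explicit M) are shipped in the package so installations can be
verified; they are quadratic in memory and guarded to small N.

## Numerical choices

- Simplex feasibility slack: |1ᵀx−1| ≤ 1e−9, min x ≥ −1e−12.
- Line-search denominator ‖p−q‖² < 1e−15 ⇒ γ = 0.
- ‖S‖₁ normalises the similarity vector (keeps B̂ stochastic).
- Argmin/argmax ties always break toward the smallest index, making
  every result seed-independent given x.
- Residual drift: p is tracked, not recomputed; debug mode measures the
  worst deviation from scratch recomputation (≈1e−16 per step,
  ≤1e−10 over the suite's runs).
- Problem sizes in tests and the acceptance script (targets ≤ 200
  nodes, N ≤ a few thousand) are chosen so every solver result can be
  cross-checked against dense brute force, closed forms, or exhaustive
  enumeration.

## Known limitations

- Plain Frank-Wolfe zigzags near optima with many small coordinates:
  reaching ξ = 1e−6 takes 10⁵–10⁶ iterations even on small instances.
  Away-step or pairwise variants would fix this but are deliberately
  out of scope.
- No convergence-rate certificate is claimed, only monotone descent to
  the global optimum; the rate/partition trade-off is characterised
  empirically (iterations grow with n).
- One query vs one target only; no multi-network alignment, no directed
  or weighted walks, no built-in BLAST or database parsers — similarity
  scores and edge lists are consumed as plain text.
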