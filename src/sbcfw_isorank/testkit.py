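"""Synthetic benchmark instances and dense brute-force oracles.

Real network-query benchmarks pit a known protein complex from one
interaction database against a whole network archived in another, where
the two databases disagree on some interactions.  The generators here
emulate that: a random connected non-bipartite target network, a planted
connected query subgraph with a known node correspondence, a
degree-preserving rewire of the target to model cross-database
interaction differences, and a noisy similarity table whose true pairs
carry the dominant signal.

The dense oracles (explicit Bhat, power iteration, explicit Hessian M)
are intentionally naive and quadratic in memory; they exist to verify
the matrix-free solver on small instances and to let users check an
installation, never to replace it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np

from .network_io import Network, SimilarityTable, write_edge_list
from .product_operator import ProductOperator

__all__ = [
    "PlantedInstance",
    "random_connected_graph",
    "plant_query",
    "synth_similarity",
    "network_from_nx",
    "dense_Bhat",
    "dense_M",
    "dense_oracle_stationary",
    "write_instance",
]


def network_from_nx(G: nx.Graph, names: Optional[list[str]] = None) -> Network:
    """Convert an undirected networkx graph, preserving node order."""
    nodes = list(G.nodes())
    index = {u: i for i, u in enumerate(nodes)}
    if names is None:
        names = [str(u) for u in nodes]
    edges = [(index[u], index[v]) for u, v in G.edges() if u != v]
    return Network.from_edges(names, edges)


def _to_nx(net: Network) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(net.n_nodes))
    G.add_edges_from(net.edges())
    return G


@dataclass
class PlantedInstance:
    """A query planted in a (possibly rewired) target with known truth."""

    query: Network
    target: Network
    truth: dict[int, int]
    sim: Optional[SimilarityTable]
    params: dict

    @property
    def N(self) -> int:
        return self.query.n_nodes * self.target.n_nodes


def random_connected_graph(n_nodes: int, mean_degree: float, seed: int) -> Network:
    """Erdos-Renyi draw patched to be connected and non-bipartite.

    Components are joined by random bridging edges; if the result is
    bipartite, a triangle is closed among three random mutually reachable
    nodes.  Node names are ``n0, n1, ...``; deterministic per seed.
    """
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    if mean_degree < 2:
        raise ValueError("mean_degree must be >= 2 to make connectivity plausible")
    rng = np.random.default_rng(seed)
    p = min(1.0, mean_degree / (n_nodes - 1))
    G = nx.gnp_random_graph(n_nodes, p, seed=int(rng.integers(2**31)))
    comps = [list(c) for c in nx.connected_components(G)]
    while len(comps) > 1:
        a = comps.pop(int(rng.integers(len(comps))))
        b = comps[int(rng.integers(len(comps)))]
        G.add_edge(a[int(rng.integers(len(a)))], b[int(rng.integers(len(b)))])
        comps = [list(c) for c in nx.connected_components(G)]
    if nx.is_bipartite(G):
        # Close a triangle on a random edge to break bipartiteness.
        u, v = list(G.edges())[int(rng.integers(G.number_of_edges()))]
        others = [w for w in G.nodes() if w not in (u, v)]
        w = others[int(rng.integers(len(others)))]
        G.add_edge(u, w)
        G.add_edge(v, w)
    return network_from_nx(G, names=[f"n{i}" for i in range(n_nodes)])


def plant_query(
    target: Network,
    query_size: int,
    rewire_fraction: float = 0.0,
    seed: int = 0,
    max_tries: int = 50,
) -> PlantedInstance:
    """Extract a connected induced query subgraph, then rewire the target.

    The query is grown by random neighbour expansion from a random start
    node of the *pre-perturbation* target, so it is a connected induced
    subgraph with truth = the inducing node map.  The target then
    undergoes degree-preserving, connectivity-preserving double-edge
    swaps on ``rewire_fraction`` of its edges, modelling two databases
    archiving overlapping-but-different interaction sets.
    """
    if not 3 <= query_size <= target.n_nodes:
        raise ValueError("query_size must be in [3, target.n_nodes]")
    if not 0.0 <= rewire_fraction < 0.5:
        raise ValueError("rewire_fraction must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    G = _to_nx(target)

    chosen: list[int] = []
    for _ in range(max_tries):
        start = int(rng.integers(target.n_nodes))
        grown = [start]
        frontier = set(G.neighbors(start))
        while len(grown) < query_size and frontier:
            nxt = sorted(frontier)[int(rng.integers(len(frontier)))]
            grown.append(nxt)
            frontier.update(G.neighbors(nxt))
            frontier -= set(grown)
        if len(grown) == query_size:
            chosen = grown
            break
    if not chosen:
        raise RuntimeError(f"no connected induced subgraph of size {query_size} found")

    sub = G.subgraph(chosen)
    q_index = {node: i for i, node in enumerate(chosen)}
    query = Network.from_edges(
        [target.node_names[u] for u in chosen],
        [(q_index[u], q_index[v]) for u, v in sub.edges()],
    )
    truth = {i: node for i, node in enumerate(chosen)}

    n_swaps = int(round(rewire_fraction * G.number_of_edges()))
    H = G
    if n_swaps > 0:
        for attempt in range(max_tries):
            H = G.copy()
            nx.connected_double_edge_swap(H, nswap=n_swaps, seed=int(rng.integers(2**31)))
            if not nx.is_bipartite(H):
                break
        else:
            raise RuntimeError("rewiring repeatedly produced a bipartite target")
    rewired = network_from_nx(H, names=list(target.node_names))

    return PlantedInstance(
        query=query,
        target=rewired,
        truth=truth,
        sim=None,
        params={
            "target_size": target.n_nodes,
            "query_size": query_size,
            "rewire_fraction": rewire_fraction,
            "seed": seed,
        },
    )


def synth_similarity(
    instance: PlantedInstance,
    signal: float = 1.0,
    noise_pairs: int = 0,
    seed: int = 0,
) -> SimilarityTable:
    """Similarity table with score ``signal`` on true pairs plus noise.

    ``noise_pairs`` spurious pairs get scores drawn uniformly from
    (0, signal), so the true correspondence always dominates; this
    mirrors sequence-similarity inputs where orthologs out-score chance
    hits.  The solver normalises the table, so only ratios matter.
    """
    if signal <= 0:
        raise ValueError("signal must be positive")
    rng = np.random.default_rng(seed)
    q, t = instance.query, instance.target
    entries = [(q.node_names[u], t.node_names[v], float(signal)) for u, v in instance.truth.items()]
    true_set = set(instance.truth.items())
    added = 0
    while added < noise_pairs:
        u = int(rng.integers(q.n_nodes))
        v = int(rng.integers(t.n_nodes))
        if (u, v) in true_set:
            continue
        entries.append((q.node_names[u], t.node_names[v], float(rng.uniform(0, signal))))
        added += 1
    table = SimilarityTable(entries)
    instance.sim = table
    return table


# -- dense oracles ---------------------------------------------------------


def dense_Bhat(op: ProductOperator) -> np.ndarray:
    """Explicit alpha Bbar + (1-alpha) sbar 1^T; O(N^2) memory, small N only."""
    B = np.kron(op.qnet.adjacency.toarray(), op.tnet.adjacency.toarray())
    with np.errstate(divide="ignore", invalid="ignore"):
        Bbar = np.where(op.d > 0, B / op.d, 0.0)
    if op.alpha == 1.0:
        return Bbar
    return op.alpha * Bbar + (1.0 - op.alpha) * np.outer(op.sbar, np.ones(op.N))


def dense_M(op: ProductOperator) -> np.ndarray:
    """Explicit Hessian M = (Bhat - I)^T (Bhat - I) for oracle tests."""
    E = dense_Bhat(op) - np.eye(op.N)
    return E.T @ E


def dense_oracle_stationary(op: ProductOperator, tol: float = 1e-12, max_iter: int = 100_000) -> np.ndarray:
    """Power iteration on the explicit Bhat from a uniform start.

    Iterates x <- Bhat x with L1 renormalisation until the successive
    L1 change drops below ``tol``; returns the stationary vector on the
    simplex.  For alpha = 1 on a connected non-bipartite product this is
    d / ||d||_1 in closed form, which tests exploit.
    """
    Bhat = dense_Bhat(op)
    x = np.full(op.N, 1.0 / op.N)
    for _ in range(max_iter):
        y = Bhat @ x
        y /= np.abs(y).sum()
        if np.abs(y - x).sum() < tol:
            return y
        x = y
    raise RuntimeError(f"power iteration did not converge in {max_iter} iterations")


def write_instance(instance: PlantedInstance, out_dir: str | Path) -> dict[str, Path]:
    """Serialise an instance to query.tsv / target.tsv / sim.tsv / truth.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "query": out_dir / "query.tsv",
        "target": out_dir / "target.tsv",
        "sim": out_dir / "sim.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_edge_list(instance.query, paths["query"])
    write_edge_list(instance.target, paths["target"])
    if instance.sim is not None:
        with open(paths["sim"], "w") as fh:
            for q, t, s in instance.sim.entries:
                fh.write(f"{q}\t{t}\t{s!r}\n")
    else:
        del paths["sim"]
    with open(paths["truth"], "w") as fh:
        for u, v in sorted(instance.truth.items()):
            fh.write(f"{instance.query.node_names[u]}\t{instance.target.node_names[v]}\n")
    return paths
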