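"""Reading and writing networks, similarity tables and alignment outputs.

Networks are undirected, unweighted protein-protein interaction (PPI)
graphs given as plain-text edge lists (two whitespace-separated node-name
columns per line, ``#`` comments).  Node indexing is 0-based in order of
first appearance in the file and is stable for the rest of the run; every
downstream vector and matrix is indexed by it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "SimilarityTable",
    "read_edge_list",
    "write_edge_list",
    "read_similarity",
    "read_truth",
    "write_alignment",
]


@dataclass
class Network:
    """An undirected, unweighted graph with a stable node order.

    Parameters
    ----------
    node_names
        Unique node identifiers; position in this list is the node index.
    adjacency
        Symmetric binary CSR matrix with zero diagonal.
    """

    node_names: list[str]
    adjacency: sp.csr_matrix
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.node_names)) != len(self.node_names):
            raise ValueError("duplicate node names")
        self._index = {name: i for i, name in enumerate(self.node_names)}

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    @property
    def degree(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    def index_of(self, name: str) -> int:
        return self._index[name]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    @classmethod
    def from_edges(cls, node_names: Sequence[str], edges: Iterable[tuple[int, int]]) -> "Network":
        """Build a network from 0-based index pairs (self-loops rejected)."""
        n = len(node_names)
        rows, cols = [], []
        seen: set[tuple[int, int]] = set()
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on index {u}")
            key = (min(u, v), max(u, v))
            if key in seen:
                continue
            seen.add(key)
            rows += [u, v]
            cols += [v, u]
        adj = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=np.float64
        )
        return cls(list(node_names), adj)

    def edges(self) -> list[tuple[int, int]]:
        """Undirected edges as sorted (u, v) index pairs with u < v."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return sorted(zip(coo.row.tolist(), coo.col.tolist()))


@dataclass
class SimilarityTable:
    """Sparse cross-network node-similarity scores (e.g. BLAST bit-scores).

    ``entries`` holds (query name, target name, score >= 0) triples; pairs
    not listed are implicitly 0.  Duplicated pairs are summed on read.
    """

    entries: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        for q, t, s in self.entries:
            if s < 0:
                raise ValueError(f"negative similarity score for ({q}, {t}): {s}")

    @property
    def total(self) -> float:
        return float(sum(s for _, _, s in self.entries))

    def to_vector(self, qnet: Network, tnet: Network) -> np.ndarray:
        """Dense score vector of length N_a*N_b in query-major pair order."""
        vec = np.zeros(qnet.n_nodes * tnet.n_nodes)
        for q, t, s in self.entries:
            vec[qnet.index_of(q) * tnet.n_nodes + tnet.index_of(t)] += s
        return vec


def read_edge_list(path: str | Path, comment_prefix: str = "#") -> Network:
    """Parse a two-column edge list into a :class:`Network`.

    Duplicate edges (either orientation) collapse to one; self-loops are
    dropped with a warning.  Node order is first appearance.  A third
    numeric column (edge weight) is ignored with a warning, since the
    alignment model treats interactions as binary.
    """
    path = Path(path)
    names: list[str] = []
    index: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    warned_weights = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(comment_prefix):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns, got {len(tokens)}")
            u_name, v_name = tokens[0], tokens[1]
            if len(tokens) >= 3 and not warned_weights:
                try:
                    float(tokens[2])
                except ValueError:
                    pass
                else:
                    logger.warning("%s: edge weights in column 3 are ignored (graphs are unweighted)", path)
                    warned_weights = True
            for name in (u_name, v_name):
                if name not in index:
                    index[name] = len(names)
                    names.append(name)
            u, v = index[u_name], index[v_name]
            if u == v:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, u_name)
                continue
            edges.add((min(u, v), max(u, v)))
    if not edges:
        raise ValueError(f"{path}: no edges found")
    return Network.from_edges(names, sorted(edges))


def write_edge_list(net: Network, path: str | Path) -> None:
    """Write one undirected edge per line, node names tab-separated."""
    with open(path, "w") as fh:
        for u, v in net.edges():
            fh.write(f"{net.node_names[u]}\t{net.node_names[v]}\n")


def read_similarity(path: str | Path, qnet: Network, tnet: Network) -> SimilarityTable:
    """Parse a 3-column similarity table, validating names against the networks.

    Duplicate (query, target) pairs are summed with a warning.  Negative
    scores and unknown node names are errors.
    """
    path = Path(path)
    merged: dict[tuple[str, str], float] = {}
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns (query, target, score)")
            q, t = tokens[0], tokens[1]
            try:
                score = float(tokens[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric score {tokens[2]!r}") from exc
            if q not in qnet:
                raise ValueError(f"{path}:{lineno}: unknown query node {q!r}")
            if t not in tnet:
                raise ValueError(f"{path}:{lineno}: unknown target node {t!r}")
            if score < 0:
                raise ValueError(f"{path}:{lineno}: negative score {score}")
            if (q, t) in merged:
                logger.warning("%s:%d: duplicate pair (%s, %s); scores summed", path, lineno, q, t)
            merged[(q, t)] = merged.get((q, t), 0.0) + score
            n_rows += 1
    if n_rows == 0:
        raise ValueError(f"{path}: similarity table has no rows")
    return SimilarityTable([(q, t, s) for (q, t), s in merged.items()])


def read_truth(path: str | Path, qnet: Network, tnet: Network) -> dict[int, int]:
    """Parse a 2-column ground-truth mapping (query name, target name)."""
    truth: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            q, t = tokens[0], tokens[1]
            if q not in qnet or t not in tnet:
                raise ValueError(f"{path}:{lineno}: unknown node in pair ({q}, {t})")
            truth[qnet.index_of(q)] = tnet.index_of(t)
    if not truth:
        raise ValueError(f"{path}: empty truth mapping")
    return truth


def write_alignment(result, path: str | Path, qnet: Network, tnet: Network) -> None:
    """Write an alignment as a 3-column TSV sorted by query index.

    Header is ``query\ttarget\tscore``; scores are written at full
    precision (repr round-trip).
    """
    if not result.pairs:
        raise ValueError("refusing to write an empty alignment")
    with open(path, "w") as fh:
        fh.write("query\ttarget\tscore\n")
        for u, v, score in sorted(result.pairs):
            fh.write(f"{qnet.node_names[u]}\t{tnet.node_names[v]}\t{score!r}\n")
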