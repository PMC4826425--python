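"""Matrix-free linear algebra on the Kronecker product network.

The alignment of a query network G_a (N_a nodes) with a target network
G_b (N_b nodes) lives on the product graph whose adjacency is the
Kronecker product B = A_a (x) A_b over node pairs.  The random-walk
transition matrix is the column-stochastic

    Bbar = B Diag(B 1)^-1,

and mixing in node similarity S gives

    Bhat = alpha Bbar + (1 - alpha) sbar 1^T,   sbar = S / ||S||_1.

B has (N_a N_b)^2 entries, which is prohibitive to materialise even for
mid-size networks; this module applies Bbar, Bhat and their transposes to
length-N vectors using only the two input adjacencies, exploiting
(A_a (x) A_b) vec(X') = vec(A_a X A_b) in the query-major pair order
t = u * N_b + v.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .network_io import Network, SimilarityTable

logger = logging.getLogger(__name__)

__all__ = ["ProductOperator", "build_product_operator", "restrict"]


@dataclass
class ProductOperator:
    """Implicit Bbar / Bhat over the pair space of two networks.

    Attributes
    ----------
    qnet, tnet
        The query (G_a) and target (G_b) networks.
    d
        Product-graph degree vector, d[u*N_b + v] = deg_a(u) * deg_b(v);
        this is the row-sum vector B 1 of the Kronecker adjacency.
    alpha
        Topology-vs-similarity mixing weight in [0, 1]; alpha = 1 is the
        pure random-walk model.
    sbar
        L1-normalised similarity vector of length N (None when alpha = 1).
    """

    qnet: Network
    tnet: Network
    alpha: float = 1.0
    sbar: Optional[np.ndarray] = None
    d: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        deg_a = self.qnet.degree.astype(np.float64)
        deg_b = self.tnet.degree.astype(np.float64)
        self.d = np.multiply.outer(deg_a, deg_b).ravel()
        if np.any(self.d == 0):
            logger.warning(
                "product graph has %d zero-degree pairs; the stationary "
                "distribution interpretation assumes connected non-bipartite inputs",
                int(np.sum(self.d == 0)),
            )

    @property
    def N(self) -> int:
        return self.qnet.n_nodes * self.tnet.n_nodes

    @property
    def shape(self) -> tuple[int, int]:
        return (self.N, self.N)

    # -- core matvecs ------------------------------------------------------

    def _kron_apply(self, x: np.ndarray) -> np.ndarray:
        """B x = vec(A_a X A_b) for symmetric adjacencies, O(sparse) time."""
        X = x.reshape(self.qnet.n_nodes, self.tnet.n_nodes)
        Z = self.qnet.adjacency @ X
        # Z @ A_b via the symmetric transpose to keep sparse-on-the-left.
        return np.ascontiguousarray((self.tnet.adjacency @ Z.T).T).ravel()

    def _div_d(self, x: np.ndarray) -> np.ndarray:
        out = np.zeros_like(x, dtype=np.float64)
        np.divide(x, self.d, out=out, where=self.d > 0)
        return out

    def apply_Bbar(self, x: np.ndarray) -> np.ndarray:
        """Bbar x = B Diag(d)^-1 x, with 0/0 := 0 at zero-degree pairs."""
        x = np.asarray(x, dtype=np.float64)
        if x.shape != (self.N,):
            raise ValueError(f"expected vector of length {self.N}, got shape {x.shape}")
        return self._kron_apply(self._div_d(x))

    def apply_Bhat(self, x: np.ndarray) -> np.ndarray:
        """Bhat x = alpha Bbar x + (1 - alpha) (1^T x) sbar."""
        y = self.apply_Bbar(x) if self.alpha > 0 else np.zeros(self.N)
        if self.alpha == 1.0:
            return y
        return self.alpha * y + (1.0 - self.alpha) * float(np.sum(x)) * self.sbar

    def apply_BbarT(self, p: np.ndarray) -> np.ndarray:
        """Bbar^T p = Diag(d)^-1 B p (B is symmetric)."""
        p = np.asarray(p, dtype=np.float64)
        if p.shape != (self.N,):
            raise ValueError(f"expected vector of length {self.N}, got shape {p.shape}")
        return self._div_d(self._kron_apply(p))

    def apply_BhatT(self, p: np.ndarray) -> np.ndarray:
        """Bhat^T p = alpha Bbar^T p + (1 - alpha) (sbar^T p) 1."""
        y = self.apply_BbarT(p) if self.alpha > 0 else np.zeros(self.N)
        if self.alpha == 1.0:
            return y
        return self.alpha * y + (1.0 - self.alpha) * float(self.sbar @ p)

    # -- residual operator E = Bhat - I ------------------------------------

    def apply_E(self, x: np.ndarray) -> np.ndarray:
        return self.apply_Bhat(x) - np.asarray(x, dtype=np.float64)

    def apply_ET(self, p: np.ndarray) -> np.ndarray:
        return self.apply_BhatT(p) - np.asarray(p, dtype=np.float64)

    def pair_index(self, u: int, v: int) -> int:
        """Query-major pair index t = u * N_b + v."""
        return u * self.tnet.n_nodes + v

    def pair_of(self, t: int) -> tuple[int, int]:
        return divmod(t, self.tnet.n_nodes)


def build_product_operator(
    qnet: Network,
    tnet: Network,
    sim: Optional[SimilarityTable] = None,
    alpha: float = 1.0,
) -> ProductOperator:
    """Assemble the implicit product operator for a pair of networks.

    ``alpha < 1`` requires a similarity table with positive total score;
    its vector is L1-normalised into sbar so that Bhat remains
    column-stochastic on the simplex.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    sbar = None
    if alpha < 1.0:
        if sim is None:
            raise ValueError("alpha < 1 requires a similarity table")
        svec = sim.to_vector(qnet, tnet)
        total = svec.sum()
        if total <= 0:
            raise ValueError("alpha < 1 requires a similarity table with positive total score")
        sbar = svec / total
    return ProductOperator(qnet=qnet, tnet=tnet, alpha=alpha, sbar=sbar)


def restrict(vector: np.ndarray, block: np.ndarray) -> np.ndarray:
    """U_i v: zero out every entry outside ``block``."""
    vector = np.asarray(vector)
    block = np.asarray(block, dtype=np.intp)
    if block.size and (block.min() < 0 or block.max() >= vector.shape[0]):
        raise IndexError("block index out of range")
    if block.size != np.unique(block).size:
        raise ValueError("block indices must be unique")
    out = np.zeros_like(vector)
    out[block] = vector[block]
    return out
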