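"""Confidence-weighted PPI network and its column-stochastic transition operator.

The network is undirected and weighted by an integration confidence score
(STRING's combined score, range 1-999).  Nodes are opaque protein/gene
identifiers; they are sorted lexicographically at construction so that every
vector and matrix derived from the network is reproducible byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from .errors import MissingNodeError, EmptyInputError, RejectedEdgeError

logger = logging.getLogger(__name__)

__all__ = ["PPINetwork", "build_network", "transition_matrix", "confidence"]


@dataclass(frozen=True)
class PPINetwork:
    """Undirected weighted graph over protein identifiers.

    Attributes
    ----------
    nodes : tuple of str
        All identifiers, sorted lexicographically.  Matrix row/column ``i``
        always refers to ``nodes[i]``.
    adjacency : scipy.sparse.csr_matrix
        Symmetric weight matrix aligned to ``nodes``; entry (i, j) is the
        confidence score of the edge, 0 if absent.  No diagonal entries.
    """

    nodes: tuple[str, ...]
    adjacency: sparse.csr_matrix
    _index: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self._index:
            object.__setattr__(
                self, "_index", {g: i for i, g in enumerate(self.nodes)}
            )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise MissingNodeError(f"gene {gene!r} is not in the network") from None

    def degree(self, gene: str, min_score: float = 0.0) -> int:
        """Number of neighbors connected at confidence > ``min_score``."""
        return len(self.neighbors(gene, min_score))

    def neighbors(self, gene: str, min_score: float = 0.0) -> tuple[str, ...]:
        """Neighbors of ``gene`` with edge confidence > ``min_score``."""
        i = self.index(gene)
        row = self.adjacency.getrow(i)
        keep = row.data > min_score
        return tuple(self.nodes[j] for j in row.indices[keep])


def build_network(edges: Iterable[tuple[str, str, float]]) -> PPINetwork:
    """Build a deduplicated undirected network from an edge list.

    Pairs may appear in either order or twice (STRING files list both
    directions).  Conflicting duplicate scores keep the maximum, with a
    warning.  Self-loops are dropped with a warning.  Non-positive or
    non-numeric scores are rejected.
    """
    weights: dict[tuple[str, str], float] = {}
    nodes: set[str] = set()
    for lineno, (u, v, w) in enumerate(edges, start=1):
        try:
            score = float(w)
        except (TypeError, ValueError):
            raise RejectedEdgeError(
                f"non-numeric confidence score {w!r} on edge ({u!r}, {v!r})",
                line=lineno,
            ) from None
        if not np.isfinite(score) or score <= 0:
            raise RejectedEdgeError(
                f"non-positive confidence score {score!r} on edge ({u!r}, {v!r})",
                line=lineno,
            )
        u, v = str(u), str(v)
        if u == v:
            logger.warning("dropping self-loop on %r (score %s)", u, score)
            nodes.add(u)
            continue
        key = (u, v) if u < v else (v, u)
        nodes.update(key)
        prev = weights.get(key)
        if prev is None:
            weights[key] = score
        elif prev != score:
            logger.warning(
                "duplicate edge %s with conflicting scores %s / %s; keeping max",
                key, prev, score,
            )
            weights[key] = max(prev, score)

    if not nodes:
        raise EmptyInputError("edge list produced an empty network")

    ordered = tuple(sorted(nodes))
    index = {g: i for i, g in enumerate(ordered)}
    n = len(ordered)
    if weights:
        ii = np.fromiter((index[k[0]] for k in weights), dtype=np.int64, count=len(weights))
        jj = np.fromiter((index[k[1]] for k in weights), dtype=np.int64, count=len(weights))
        ww = np.fromiter(weights.values(), dtype=np.float64, count=len(weights))
        adj = sparse.coo_matrix(
            (np.concatenate([ww, ww]), (np.concatenate([ii, jj]), np.concatenate([jj, ii]))),
            shape=(n, n),
        ).tocsr()
    else:
        adj = sparse.csr_matrix((n, n), dtype=np.float64)
    return PPINetwork(nodes=ordered, adjacency=adj)


def transition_matrix(net: PPINetwork) -> sparse.csc_matrix:
    """Column-stochastic transition operator M of the random walk.

    Entry (i, j) is weight(i, j) / sum_k weight(k, j): the probability that a
    walker at node j steps to node i.  Columns over isolated nodes are zero
    (the walk loses mass there; the propagation layer warns about it).
    """
    if net.n_nodes == 0:
        raise EmptyInputError("cannot build a transition matrix for an empty network")
    adj = net.adjacency.tocsc(copy=True).astype(np.float64)
    colsum = np.asarray(adj.sum(axis=0)).ravel()
    scale = np.divide(1.0, colsum, out=np.zeros_like(colsum), where=colsum > 0)
    adj.data *= np.repeat(scale, np.diff(adj.indptr))
    return adj


def confidence(net: PPINetwork, u: str, v: str) -> float:
    """Edge confidence score Q(u, v); 0 if the pair is not adjacent."""
    i, j = net.index(u), net.index(v)
    return float(net.adjacency[i, j])
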