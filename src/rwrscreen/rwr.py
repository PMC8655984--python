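"""Random walk with restart and candidate extraction.

The walk iterates

    P(t+1) = (1 - r) * M @ P(t) + r * P0

where M is the column-stochastic transition matrix of the PPI network, P0
puts mass 1/m on each of the m seed nodes, and r is the restart
probability (default 0.8).  Iteration stops when the L1 change between
successive vectors drops below ``tol`` (default 1e-6).  Because the update
is a contraction with factor (1 - r), convergence is geometric and the
fixed point is unique; non-convergence within ``max_iter`` signals bad
input rather than a hard problem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .errors import ConfigError, ConvergenceError, MissingNodeError
from .io import GeneSet
from .network import PPINetwork, transition_matrix

logger = logging.getLogger(__name__)

__all__ = ["ProbabilityVector", "CandidateSet", "init_probability", "rwr", "select_candidates"]

#: tolerance on |sum(P) - 1| beyond which mass loss is reported
_CONSERVATION_TOL = 1e-9


@dataclass(frozen=True)
class ProbabilityVector:
    """Stationary RWR probabilities aligned to the network node ordering."""

    nodes: tuple[str, ...]
    values: np.ndarray
    restart: float
    iterations: int
    residual: float

    def __getitem__(self, gene: str) -> float:
        return float(self.values[self.nodes.index(gene)])

    def as_dict(self) -> dict[str, float]:
        return {g: float(p) for g, p in zip(self.nodes, self.values)}


@dataclass(frozen=True)
class CandidateSet:
    """(gene, probability) pairs, descending probability, seeds excluded."""

    items: tuple[tuple[str, float], ...]

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)


def seed_vector(net: PPINetwork, seed_indices: np.ndarray) -> np.ndarray:
    """P0 with mass 1/m on each seed index."""
    p0 = np.zeros(net.n_nodes)
    p0[seed_indices] = 1.0 / len(seed_indices)
    return p0


def init_probability(net: PPINetwork, seeds: GeneSet) -> ProbabilityVector:
    """Initial distribution: each of the m seeds carries 1/m, others 0."""
    if len(seeds) == 0:
        raise ConfigError("seed set is empty")
    idx = np.array([net.index(g) for g in seeds])  # raises MissingNodeError
    return ProbabilityVector(
        nodes=net.nodes, values=seed_vector(net, idx),
        restart=float("nan"), iterations=0, residual=float("nan"),
    )


def propagate(
    M: sparse.spmatrix,
    p0: np.ndarray,
    r: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, int, float]:
    """Iterate the restart walk from p0 until the L1 residual falls below tol.

    ``p0`` may be a vector or a (n_nodes, k) matrix of k start distributions
    propagated simultaneously; the residual is then the maximum column L1
    change, so every column is individually converged on return.
    """
    p = p0.copy()
    for it in range(1, max_iter + 1):
        p_next = (1.0 - r) * (M @ p) + r * p0
        residual = float(np.max(np.abs(p_next - p).sum(axis=0)))
        p = p_next
        if residual < tol:
            return p, it, residual
    raise ConvergenceError(
        f"RWR did not converge within {max_iter} iterations (L1 residual {residual:.3e})",
        residual=residual, iterations=max_iter,
    )


def rwr(
    net: PPINetwork,
    seeds: GeneSet,
    r: float = 0.8,
    tol: float = 1e-6,
    max_iter: int = 10000,
) -> ProbabilityVector:
    """Run the random walk with restart from a seed set.

    Parameters
    ----------
    r
        Restart probability, 0 < r <= 1.  At r = 1 the walk never leaves the
        seed distribution and P0 is returned after one step.
    tol
        L1 stopping tolerance on successive iterates.
    max_iter
        Safety cap; the contraction factor is (1 - r) so real inputs converge
        in tens of iterations.
    """
    if not (0.0 < r <= 1.0):
        raise ConfigError(f"restart probability must be in (0, 1], got {r}")
    if tol <= 0:
        raise ConfigError(f"tolerance must be positive, got {tol}")
    p0 = init_probability(net, seeds).values
    M = transition_matrix(net)
    values, iterations, residual = propagate(M, p0, r, tol, max_iter)
    total = float(values.sum())
    if abs(total - 1.0) > _CONSERVATION_TOL:
        logger.warning(
            "probability mass %0.12f deviates from 1 (isolated nodes leak mass); "
            "not renormalizing", total,
        )
    return ProbabilityVector(
        nodes=net.nodes, values=values, restart=r,
        iterations=iterations, residual=residual,
    )


def select_candidates(
    p: ProbabilityVector,
    seeds: GeneSet,
    threshold: float = 1e-5,
) -> CandidateSet:
    """Non-seed nodes with probability >= threshold (inclusive).

    Sorted by descending probability; ties broken by gene id so the output
    is deterministic.
    """
    if threshold <= 0:
        raise ConfigError(f"probability threshold must be positive, got {threshold}")
    seed_set = set(seeds)
    picked = [
        (g, float(v))
        for g, v in zip(p.nodes, p.values)
        if v >= threshold and g not in seed_set
    ]
    picked.sort(key=lambda item: (-item[1], item[0]))
    if not picked:
        logger.info("no non-seed node reached probability %g", threshold)
    return CandidateSet(items=tuple(picked))
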