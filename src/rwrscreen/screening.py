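"""The three screening filters applied to RWR candidates.

1. **Permutation test** - re-runs the walk from random seed sets of the same
   size and standardizes each candidate's true probability against that null
   (Z-score, cut ``> 1.96`` strict).  This controls for hub nodes that
   accumulate probability regardless of where the walk starts.
2. **Linkage test** - maximum edge confidence between a candidate and any
   validated gene (MLS, cut ``>= 900`` inclusive, STRING's highest-confidence
   band).
3. **Enrichment test** - each gene gets a vector of -log10 hypergeometric
   upper-tail probabilities over all annotation terms, scored on its network
   neighborhood; a candidate passes when the cosine similarity between its
   vector and some validated gene's vector reaches the MES cut
   (``>= 0.98`` inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats

from .errors import ConfigError, EmptyInputError, MissingNodeError, RWRScreenError
from .io import AnnotationMap, GeneSet
from .network import PPINetwork, confidence, transition_matrix
from .rwr import CandidateSet, propagate, seed_vector

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationNull",
    "EnrichmentVector",
    "ScreeningRecord",
    "permutation_test",
    "z_score",
    "max_linkage_score",
    "hypergeom_tail_score",
    "enrichment_score",
    "enrichment_vector",
    "enrichment_vectors",
    "cosine_similarity",
    "max_enrichment_score",
    "apply_filters",
]

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class PermutationNull:
    """Per-candidate null mean/std of RWR probabilities over random seed sets.

    ``n_used`` is the number of permutations entering each candidate's
    statistics; it is below ``n_perm`` for candidates that were themselves
    drawn into some null seed sets (those draws describe the gene acting as
    a seed, not probability flowing to it, and are excluded by default).
    """

    genes: tuple[str, ...]
    mean: np.ndarray       # ProM(g)
    std: np.ndarray        # ProSTD(g), sample (n-1) standard deviation
    n_perm: int
    rng_seed: int
    n_used: np.ndarray | None = None

    def stats_for(self, gene: str) -> tuple[float, float]:
        i = self.genes.index(gene)
        return float(self.mean[i]), float(self.std[i])


@dataclass(frozen=True)
class EnrichmentVector:
    """Enrichment scores of one gene over the shared global term ordering."""

    gene: str
    terms: tuple[str, ...]
    scores: np.ndarray

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class ScreeningRecord:
    """All scores and pass flags for one candidate gene.

    ``mls``/``mes`` (and their flags) are None when lazy evaluation skipped
    them because an earlier filter already failed.
    """

    gene: str
    probability: float
    z_score: float
    mls: float | None
    mes: float | None
    pass_permutation: bool
    pass_linkage: bool | None
    pass_enrichment: bool | None
    inferred: bool


def _degree_bins(net: PPINetwork) -> np.ndarray:
    """log2 degree bin label per node, for degree-matched null sampling."""
    deg = np.asarray((net.adjacency > 0).sum(axis=1)).ravel()
    return np.floor(np.log2(np.maximum(deg, 1))).astype(int)


def _sample_seed_indices(
    net: PPINetwork,
    true_idx: np.ndarray,
    rng: np.random.Generator,
    degree_matched: bool,
) -> np.ndarray:
    n = net.n_nodes
    if not degree_matched:
        return rng.choice(n, size=len(true_idx), replace=False)
    # draw, for each true seed, a node from the same log2-degree bin
    bins = _degree_bins(net)
    members = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}
    picked: list[int] = []
    taken: set[int] = set()
    for i in true_idx:
        pool = members[bins[i]]
        choice = int(rng.choice(pool))
        while choice in taken and len(taken) < len(pool):
            choice = int(rng.choice(pool))
        taken.add(choice)
        picked.append(choice)
    return np.array(picked)


def permutation_test(
    net: PPINetwork,
    true_seeds: GeneSet,
    candidates: CandidateSet,
    n_perm: int = 1000,
    rng_seed: int = 0,
    r: float = 0.8,
    tol: float = 1e-6,
    max_iter: int = 10000,
    degree_matched: bool = False,
    exclude_self_draws: bool = True,
    batch_size: int = 250,
) -> PermutationNull:
    """Null distribution of candidate probabilities under random seed sets.

    Each permutation draws ``|true_seeds|`` nodes uniformly without
    replacement from all network nodes (optionally matched on degree), runs
    the same walk, and records every candidate's raw probability.  Start
    distributions are propagated in batches through the shared transition
    matrix; every batch column is iterated until its own L1 residual is
    below ``tol``.

    By default a candidate's mean/std exclude the permutations in which the
    candidate itself was drawn as a seed: a drawn node retains roughly
    ``r / |seeds|`` of the mass, orders of magnitude above any propagated
    probability, and those draws measure the gene acting as a seed rather
    than the walk reaching it — they would swamp the null standard
    deviation and make the Z cut unreachable for every gene.  Set
    ``exclude_self_draws=False`` for the unconditional null.  If fewer than
    two permutations remain for some candidate, all draws are used for it
    (with a warning).
    """
    if n_perm < 2:
        raise ConfigError("n_perm must be >= 2 (standard deviation undefined otherwise)")
    if len(true_seeds) > net.n_nodes:
        raise ConfigError("seed set larger than the network")
    true_idx = np.array([net.index(g) for g in true_seeds])
    cand_idx = np.array([net.index(g) for g in candidates.genes], dtype=np.int64)
    M = transition_matrix(net)
    rng = np.random.default_rng(rng_seed)

    probs = np.empty((len(cand_idx), n_perm))
    was_seed = np.zeros((len(cand_idx), n_perm), dtype=bool)
    cand_pos = {int(i): k for k, i in enumerate(cand_idx)}
    done = 0
    while done < n_perm:
        k = min(batch_size, n_perm - done)
        p0 = np.zeros((net.n_nodes, k))
        for j in range(k):
            idx = _sample_seed_indices(net, true_idx, rng, degree_matched)
            p0[idx, j] = 1.0 / len(idx)
            for i in idx:
                pos = cand_pos.get(int(i))
                if pos is not None:
                    was_seed[pos, done + j] = True
        p, _, _ = propagate(M, p0, r, tol, max_iter)
        probs[:, done:done + k] = p[cand_idx, :]
        done += k
        if done % 100 == 0 or done == n_perm:
            logger.info("permutation test: %d/%d seed sets done", done, n_perm)

    if exclude_self_draws:
        use = ~was_seed
        starved = use.sum(axis=1) < 2
        if np.any(starved):
            logger.warning(
                "%d candidate(s) were drawn as null seeds in nearly every "
                "permutation; using all draws for them", int(starved.sum()),
            )
            use[starved, :] = True
    else:
        use = np.ones_like(was_seed)
    n_used = use.sum(axis=1)
    masked = np.ma.MaskedArray(probs, mask=~use)
    mean = masked.mean(axis=1).filled(0.0)
    std = masked.std(axis=1, ddof=1).filled(0.0)

    return PermutationNull(
        genes=candidates.genes,
        mean=np.asarray(mean),
        std=np.asarray(std),
        n_perm=n_perm,
        rng_seed=rng_seed,
        n_used=n_used,
    )


def z_score(pro: float, prom: float, prostd: float) -> float:
    """Standardized deviation (Pro - ProM) / ProSTD.

    A degenerate null (ProSTD == 0) maps to signed infinity, or 0 when the
    observed probability equals the null mean, so the downstream strict
    ``> 1.96`` cut keeps its meaning without dividing by zero.
    """
    if prostd < 0:
        raise ConfigError("standard deviation must be non-negative")
    if prostd == 0:
        if pro > prom:
            return float("inf")
        if pro < prom:
            return float("-inf")
        return 0.0
    return (pro - prom) / prostd


def max_linkage_score(net: PPINetwork, candidate: str, validated: GeneSet) -> float:
    """MLS: maximum edge confidence from the candidate to any validated gene."""
    if len(validated) == 0:
        raise EmptyInputError("validated gene set is empty")
    i = net.index(candidate)
    row = net.adjacency.getrow(i)
    if row.nnz == 0:
        return 0.0
    validated_idx = {net.index(g) for g in validated}
    best = 0.0
    for j, w in zip(row.indices, row.data):
        if j in validated_idx and w > best:
            best = float(w)
    return best


def hypergeom_tail_score(N: int, M: int, n: int, m) -> np.ndarray | float:
    """-log10 of the hypergeometric upper tail P(X >= m).

    X counts the overlap when n items are drawn without replacement from N of
    which M are marked.  Computed in log space via the survival function for
    numerical stability; ``m`` may be an array (vectorized over terms).
    """
    m_arr = np.atleast_1d(np.asarray(m, dtype=np.int64))
    if N < n or N < M or n < 0 or M < 0:
        raise ConfigError(f"inadmissible hypergeometric context N={N}, M={M}, n={n}")
    if np.any(m_arr > np.minimum(n, M)) or np.any(m_arr < 0):
        raise RWRScreenError(
            f"impossible overlap m={m} for N={N}, M={M}, n={n}"
        )
    with np.errstate(divide="ignore"):
        score = -stats.hypergeom.logsf(m_arr - 1, N, M, n) / _LN10
    score = np.maximum(score, 0.0)  # clamp -0.0 / rounding at m == 0
    return score if np.ndim(m) else float(score[0])


def enrichment_score(
    gene: str,
    term: str,
    ann: AnnotationMap,
    net: PPINetwork,
    N: int,
    neighbor_min_score: float = 0.0,
) -> float:
    """ES(g, F) between a gene and one annotation term.

    n is the gene's number of network neighbors (at confidence >
    ``neighbor_min_score``), M the term's gene count, m their overlap, N the
    total number of human genes (a configuration value; the network does not
    cover the full genome).
    """
    neigh = set(net.neighbors(gene, neighbor_min_score))
    term_genes = ann[term]
    return hypergeom_tail_score(N, len(term_genes), len(neigh), len(neigh & term_genes))


def enrichment_vector(
    gene: str,
    ann: AnnotationMap,
    net: PPINetwork,
    N: int,
    neighbor_min_score: float = 0.0,
) -> EnrichmentVector:
    """ES(g, F) over every term F, in the annotation map's term ordering."""
    terms = ann.terms
    neigh = set(net.neighbors(gene, neighbor_min_score))
    n = len(neigh)
    if n == 0:
        logger.warning("gene %r has no network neighbors; enrichment vector is zero", gene)
        return EnrichmentVector(gene=gene, terms=terms, scores=np.zeros(len(terms)))
    M_arr = np.array([len(ann[t]) for t in terms], dtype=np.int64)
    m_arr = np.array([len(neigh & ann[t]) for t in terms], dtype=np.int64)
    with np.errstate(divide="ignore"):
        scores = -stats.hypergeom.logsf(m_arr - 1, N, M_arr, n) / _LN10
    scores = np.maximum(scores, 0.0)
    return EnrichmentVector(gene=gene, terms=terms, scores=scores)


def enrichment_vectors(
    genes,
    ann: AnnotationMap,
    net: PPINetwork,
    N: int,
    neighbor_min_score: float = 0.0,
) -> dict[str, EnrichmentVector]:
    return {
        g: enrichment_vector(g, ann, net, N, neighbor_min_score) for g in genes
    }


def cosine_similarity(v1: EnrichmentVector, v2: EnrichmentVector) -> float:
    """v1 . v2 / (|v1| |v2|); 0 by convention when either norm is zero."""
    if len(v1) != len(v2):
        raise ConfigError(
            f"enrichment vector length mismatch: {len(v1)} vs {len(v2)}"
        )
    n1 = float(np.linalg.norm(v1.scores))
    n2 = float(np.linalg.norm(v2.scores))
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    return float(np.dot(v1.scores, v2.scores) / (n1 * n2))


def max_enrichment_score(
    candidate: str,
    validated: GeneSet,
    vectors: dict[str, EnrichmentVector],
) -> float:
    """MES: maximum cosine similarity to any validated gene's vector."""
    try:
        cand_vec = vectors[candidate]
    except KeyError:
        raise MissingNodeError(f"no enrichment vector for candidate {candidate!r}") from None
    best = 0.0
    for g in validated:
        try:
            v = vectors[g]
        except KeyError:
            raise MissingNodeError(f"no enrichment vector for validated gene {g!r}") from None
        sim = cosine_similarity(cand_vec, v)
        if sim > best:
            best = sim
    return best


def apply_filters(
    candidates: CandidateSet,
    null: PermutationNull,
    net: PPINetwork,
    validated: GeneSet,
    vectors: dict[str, EnrichmentVector],
    z_cut: float = 1.96,
    mls_cut: float = 900.0,
    mes_cut: float = 0.98,
    lazy: bool = False,
) -> list[ScreeningRecord]:
    """Score every candidate and flag the filter cascade.

    Boundary semantics: Z strictly greater than ``z_cut``; MLS and MES
    inclusive (``>=``).  ``inferred`` is the conjunction of all three.  With
    ``lazy=True`` the linkage and enrichment scores are only computed for
    genes surviving the previous stage and are recorded as None otherwise.
    """
    if not (0.0 <= mls_cut <= 999.0):
        raise ConfigError(f"MLS cut must be in [0, 999], got {mls_cut}")
    if not (0.0 <= mes_cut <= 1.0):
        raise ConfigError(f"MES cut must be in [0, 1], got {mes_cut}")
    if not np.isfinite(z_cut):
        raise ConfigError(f"Z cut must be finite, got {z_cut}")

    null_idx = {g: i for i, g in enumerate(null.genes)}
    records: list[ScreeningRecord] = []
    for gene, pro in candidates:
        try:
            i = null_idx[gene]
        except KeyError:
            raise ConfigError(f"candidate {gene!r} missing from the permutation null") from None
        z = z_score(pro, float(null.mean[i]), float(null.std[i]))
        pass_z = z > z_cut

        mls: float | None
        mes: float | None
        if lazy and not pass_z:
            mls = mes = None
            pass_mls: bool | None = None
            pass_mes: bool | None = None
        else:
            mls = max_linkage_score(net, gene, validated)
            pass_mls = mls >= mls_cut
            if lazy and not pass_mls:
                mes = None
                pass_mes = None
            else:
                mes = max_enrichment_score(gene, validated, vectors)
                pass_mes = mes >= mes_cut

        inferred = bool(pass_z and pass_mls and pass_mes)
        records.append(
            ScreeningRecord(
                gene=gene, probability=pro, z_score=z, mls=mls, mes=mes,
                pass_permutation=pass_z, pass_linkage=pass_mls,
                pass_enrichment=pass_mes, inferred=inferred,
            )
        )
    return records
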