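"""Synthetic planted-module benchmarks.

Generates desk-scale analogues of the pipeline's three real inputs:

* a confidence-weighted background network with hub structure
  (preferential attachment, like real PPI networks — hubs are exactly what
  the permutation test must control for);
* a densely interconnected high-confidence planted module standing in for a
  disease-gene community, split into "validated" seeds and held-out truths;
* term -> gene annotations enriched in the module, so the enrichment test
  has signal to find.

Everything is driven by an integer rng_seed and is bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import sparse

from .errors import ConfigError
from .io import AnnotationMap, GeneSet
from .network import PPINetwork, build_network

__all__ = [
    "FixtureBundle",
    "generate_network",
    "plant_module",
    "generate_annotations",
    "make_benchmark",
    "write_bundle",
]


def _gene_name(i: int) -> str:
    return f"g{i:04d}"


@dataclass(frozen=True)
class FixtureBundle:
    """A complete synthetic study: network, seeds, held-out truths, decoys,
    annotations, and the parameters that generated them."""

    network: PPINetwork
    seeds: GeneSet
    truths: GeneSet
    decoys: GeneSet
    annotations: AnnotationMap
    params: dict = field(default_factory=dict)
    rng_seed: int = 0

    @property
    def module(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.seeds) | set(self.truths)))


def generate_network(
    n_nodes: int,
    attach_degree: int,
    weight_range: tuple[int, int] = (100, 899),
    rng_seed: int = 0,
) -> PPINetwork:
    """Preferential-attachment background network with integer edge weights.

    Growth starts from a complete clique on ``attach_degree + 1`` nodes and
    every later node attaches ``attach_degree`` edges preferentially, so the
    edge count is C(attach_degree+1, 2) + attach_degree*(n_nodes -
    attach_degree - 1) and the graph is connected.  Weights are drawn
    uniformly from ``weight_range`` (inclusive).
    """
    low, high = weight_range
    if n_nodes < attach_degree + 1:
        raise ConfigError("n_nodes must be at least attach_degree + 1")
    if not (1 <= low <= high <= 999):
        raise ConfigError(f"weight range must satisfy 1 <= low <= high <= 999, got {weight_range}")
    g = nx.barabasi_albert_graph(
        n_nodes, attach_degree, seed=int(rng_seed),
        initial_graph=nx.complete_graph(attach_degree + 1),
    )
    rng = np.random.default_rng(rng_seed)
    edges = sorted((min(u, v), max(u, v)) for u, v in g.edges())
    weights = rng.integers(low, high + 1, size=len(edges))
    return build_network(
        [(_gene_name(u), _gene_name(v), int(w)) for (u, v), w in zip(edges, weights)]
    )


def plant_module(
    net: PPINetwork,
    module_size: int,
    within_weight: int = 950,
    density: float = 0.8,
    rng_seed: int = 0,
) -> tuple[PPINetwork, GeneSet]:
    """Plant a dense high-confidence module into an existing network.

    ``module_size`` nodes are sampled uniformly; each within-module pair is
    added independently with probability ``density`` at weight
    ``within_weight`` (existing edges are upgraded to the maximum of old and
    new weight).  ``within_weight`` should sit at or above the linkage cut
    for the module to be recoverable.
    """
    if module_size < 2:
        raise ConfigError("module_size must be >= 2")
    if module_size > net.n_nodes:
        raise ConfigError("module_size exceeds the network size")
    if not (0.0 <= density <= 1.0):
        raise ConfigError(f"density must be a probability, got {density}")
    rng = np.random.default_rng(rng_seed)
    members = sorted(rng.choice(net.n_nodes, size=module_size, replace=False).tolist())
    member_names = [net.nodes[i] for i in members]

    tri = sparse.triu(net.adjacency, k=1).tocoo()
    edges = [
        (net.nodes[i], net.nodes[j], float(w))
        for i, j, w in zip(tri.row, tri.col, tri.data)
    ]
    existing = {(u, v): k for k, (u, v, _) in enumerate(edges)}
    for a in range(module_size):
        for b in range(a + 1, module_size):
            if rng.random() < density:
                u, v = sorted((member_names[a], member_names[b]))
                key = (u, v)
                if key in existing:
                    k = existing[key]
                    edges[k] = (u, v, max(edges[k][2], float(within_weight)))
                else:
                    existing[key] = len(edges)
                    edges.append((u, v, float(within_weight)))
    net2 = build_network(edges)
    return net2, GeneSet(identifiers=tuple(member_names), label="planted_module")


def generate_annotations(
    net: PPINetwork,
    module: GeneSet,
    n_module_terms: int = 6,
    n_background_terms: int = 30,
    term_size_range: tuple[int, int] = (10, 40),
    module_coverage: float = 0.8,
    max_fillers: int = 5,
    rng_seed: int = 0,
) -> AnnotationMap:
    """Term -> gene annotations with module-coherent signal.

    Module terms each cover at least ``module_coverage`` of the module genes
    plus up to ``max_fillers`` random non-module fillers; background terms
    are random gene sets with sizes drawn from ``term_size_range``.
    """
    lo, hi = term_size_range
    if n_module_terms < 0 or n_background_terms < 0:
        raise ConfigError("term counts must be non-negative")
    if hi > net.n_nodes:
        raise ConfigError("term size range exceeds the number of genes")
    rng = np.random.default_rng(rng_seed)
    module_genes = list(module)
    non_module = [g for g in net.nodes if g not in set(module_genes)]
    genes_by_term: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}

    min_cov = math.ceil(module_coverage * len(module_genes)) if module_genes else 0
    for t in range(n_module_terms):
        cov = int(rng.integers(min_cov, len(module_genes) + 1)) if module_genes else 0
        covered = rng.choice(len(module_genes), size=cov, replace=False) if cov else []
        fillers_n = int(rng.integers(0, max_fillers + 1))
        fillers = rng.choice(len(non_module), size=min(fillers_n, len(non_module)), replace=False)
        term = f"MOD{t:03d}"
        genes_by_term[term] = frozenset(
            [module_genes[i] for i in covered] + [non_module[i] for i in fillers]
        )
        descriptions[term] = "module-coherent functional term"

    for t in range(n_background_terms):
        size = int(rng.integers(lo, hi + 1))
        picked = rng.choice(net.n_nodes, size=size, replace=False)
        term = f"BG{t:03d}"
        genes_by_term[term] = frozenset(net.nodes[i] for i in picked)
        descriptions[term] = "background functional term"

    return AnnotationMap(genes_by_term=genes_by_term, descriptions=descriptions)


def make_benchmark(
    n_nodes: int = 500,
    module_size: int = 40,
    seed_fraction: float = 0.5,
    rng_seed: int = 0,
    attach_degree: int = 3,
    weight_range: tuple[int, int] = (100, 899),
    within_weight: int = 950,
    density: float = 0.8,
    n_module_terms: int = 6,
    n_background_terms: int = 30,
    term_size_range: tuple[int, int] = (10, 40),
) -> FixtureBundle:
    """Compose a full benchmark: network + planted module + annotations.

    The module is split into ``seed_fraction`` validated seeds and held-out
    truth genes; every non-module gene is a decoy.
    """
    if not (0.0 < seed_fraction < 1.0):
        raise ConfigError(f"seed_fraction must be in (0, 1), got {seed_fraction}")
    background = generate_network(n_nodes, attach_degree, weight_range, rng_seed)
    net, module = plant_module(background, module_size, within_weight, density, rng_seed + 1)
    ann = generate_annotations(
        net, module, n_module_terms, n_background_terms, term_size_range,
        rng_seed=rng_seed + 2,
    )
    rng = np.random.default_rng(rng_seed + 3)
    order = rng.permutation(len(module.identifiers))
    n_seeds = int(round(seed_fraction * len(module.identifiers)))
    seeds = tuple(sorted(module.identifiers[i] for i in order[:n_seeds]))
    truths = tuple(sorted(module.identifiers[i] for i in order[n_seeds:]))
    decoys = tuple(g for g in net.nodes if g not in set(module.identifiers))
    params = {
        "n_nodes": n_nodes, "module_size": module_size,
        "seed_fraction": seed_fraction, "attach_degree": attach_degree,
        "weight_range": list(weight_range), "within_weight": within_weight,
        "density": density, "n_module_terms": n_module_terms,
        "n_background_terms": n_background_terms,
        "term_size_range": list(term_size_range),
    }
    return FixtureBundle(
        network=net,
        seeds=GeneSet(identifiers=seeds, label="validated_seeds"),
        truths=GeneSet(identifiers=truths, label="held_out_truths"),
        decoys=GeneSet(identifiers=decoys, label="decoys"),
        annotations=ann,
        params=params,
        rng_seed=rng_seed,
    )


def write_bundle(bundle: FixtureBundle, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a bundle: STRING-dialect links (both directions, with
    header), seeds.txt, truths.txt, terms.gmt and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": out / "network_links.txt",
        "seeds": out / "seeds.txt",
        "truths": out / "truths.txt",
        "annotations": out / "terms.gmt",
        "manifest": out / "fixture_manifest.json",
    }
    net = bundle.network
    with open(paths["network"], "wt") as fh:
        fh.write("protein1 protein2 combined_score\n")
        coo = net.adjacency.tocoo()
        rows = [
            (net.nodes[i], net.nodes[j], int(w))
            for i, j, w in zip(coo.row, coo.col, coo.data)
        ]
        for u, v, w in sorted(rows):
            fh.write(f"{u} {v} {w}\n")
    for key, genes in (("seeds", bundle.seeds), ("truths", bundle.truths)):
        with open(paths[key], "wt") as fh:
            fh.write(f"# {genes.label}\n")
            for g in genes:
                fh.write(g + "\n")
    with open(paths["annotations"], "wt") as fh:
        for term in bundle.annotations.terms:
            desc = bundle.annotations.descriptions.get(term, "")
            genes = sorted(bundle.annotations[term])
            fh.write("\t".join([term, desc, *genes]) + "\n")
    manifest = {
        "rng_seed": bundle.rng_seed,
        "params": bundle.params,
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_seeds": len(bundle.seeds),
        "n_truths": len(bundle.truths),
        "n_decoys": len(bundle.decoys),
        "n_terms": len(bundle.annotations),
    }
    with open(paths["manifest"], "wt") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
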