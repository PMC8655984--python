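"""End-to-end orchestration of the prioritization pipeline.

read inputs -> restrict seeds to the network -> random walk with restart ->
candidate extraction -> permutation null -> three-filter screening ->
results + interaction summary + run manifest.

The manifest records every parameter, input checksums and the node counts at
each cascade stage, so a run is fully reproducible from the manifest alone;
it deliberately contains no timestamps, making repeat runs byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, EmptyInputError
from .io import (
    GeneSet,
    read_gene_set,
    read_gmt,
    read_string_links,
    restrict_to_network,
    write_results,
)
from .network import PPINetwork, build_network
from .rwr import rwr, select_candidates
from .screening import (
    ScreeningRecord,
    apply_filters,
    enrichment_vectors,
    permutation_test,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "InteractionSummary", "run_pipeline", "interaction_summary"]


@dataclass
class PipelineConfig:
    """All paths, thresholds and flags of one pipeline run."""

    network_path: str
    seeds_path: str
    annotations_path: str
    out_dir: str
    restart: float = 0.8
    tol: float = 1e-6
    prob_threshold: float = 1e-5
    n_perm: int = 1000
    z_cut: float = 1.96
    mls_cut: float = 900.0
    mes_cut: float = 0.98
    total_genes_N: int = 20000
    rng_seed: int = 0
    lazy: bool = False
    degree_matched_null: bool = False
    unconditional_null: bool = False
    neighbor_min_score: float = 0.0
    min_edge_score: float = 0.0
    max_iter: int = 10000

    def validate(self) -> None:
        if not (0.0 < self.restart <= 1.0):
            raise ConfigError(f"restart must be in (0, 1], got {self.restart}")
        if self.tol <= 0:
            raise ConfigError(f"tol must be positive, got {self.tol}")
        if self.prob_threshold <= 0:
            raise ConfigError(f"prob_threshold must be positive, got {self.prob_threshold}")
        if self.n_perm < 2:
            raise ConfigError(f"n_perm must be >= 2, got {self.n_perm}")
        if not (0.0 <= self.mls_cut <= 999.0):
            raise ConfigError(f"mls_cut must be in [0, 999], got {self.mls_cut}")
        if not (0.0 <= self.mes_cut <= 1.0):
            raise ConfigError(f"mes_cut must be in [0, 1], got {self.mes_cut}")
        if self.total_genes_N < 1:
            raise ConfigError(f"total_genes_N must be positive, got {self.total_genes_N}")


@dataclass(frozen=True)
class InteractionSummary:
    """Per-inferred-gene counts of high-confidence validated interactors."""

    genes: tuple[str, ...]
    counts: tuple[int, ...]
    cutoff: float
    mean_count: float
    fraction_above_5: float


def interaction_summary(
    inferred: GeneSet,
    validated: GeneSet,
    net: PPINetwork,
    cutoff: float = 900.0,
) -> InteractionSummary:
    """Count, per inferred gene, validated genes adjacent at confidence >= cutoff.

    Reports the mean count and the fraction of inferred genes with strictly
    more than five such interactors.
    """
    if len(inferred) == 0:
        raise EmptyInputError("inferred gene set is empty")
    validated_idx = {net.index(g) for g in validated}
    counts = []
    for g in inferred:
        row = net.adjacency.getrow(net.index(g))
        counts.append(
            sum(1 for j, w in zip(row.indices, row.data) if j in validated_idx and w >= cutoff)
        )
    counts_t = tuple(counts)
    return InteractionSummary(
        genes=tuple(inferred),
        counts=counts_t,
        cutoff=cutoff,
        mean_count=float(np.mean(counts_t)),
        fraction_above_5=float(np.mean([c > 5 for c in counts_t])),
    )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _StageTimer:
    def __init__(self) -> None:
        self._t0 = time.perf_counter()

    def lap(self, stage: str) -> None:
        t1 = time.perf_counter()
        logger.info("stage %-20s %.2fs", stage, t1 - self._t0)
        self._t0 = t1


def run_pipeline(
    config: PipelineConfig,
) -> tuple[list[ScreeningRecord], InteractionSummary | None, dict]:
    """Execute the full pipeline and write results, summary and manifest.

    Returns the screening records, the interaction summary (None when no
    gene survives all filters) and the manifest dict.  Files written to
    ``config.out_dir``: ``results.tsv``, ``interaction_summary.tsv``,
    ``manifest.json``.
    """
    config.validate()
    timer = _StageTimer()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = read_string_links(config.network_path, min_score=config.min_edge_score)
    net = build_network(rows)
    logger.info("network: %d nodes, %d edges", net.n_nodes, net.n_edges)
    timer.lap("read_network")

    raw_seeds = read_gene_set(config.seeds_path, label="seeds")
    seeds = restrict_to_network(raw_seeds, net)
    ann = read_gmt(config.annotations_path)
    timer.lap("read_inputs")

    prob = rwr(net, seeds, r=config.restart, tol=config.tol, max_iter=config.max_iter)
    logger.info("RWR converged in %d iterations (L1 residual %.3e)",
                prob.iterations, prob.residual)
    timer.lap("rwr")

    candidates = select_candidates(prob, seeds, threshold=config.prob_threshold)
    logger.info("candidates at threshold %g: %d", config.prob_threshold, len(candidates))
    timer.lap("select_candidates")

    null = permutation_test(
        net, seeds, candidates,
        n_perm=config.n_perm, rng_seed=config.rng_seed,
        r=config.restart, tol=config.tol, max_iter=config.max_iter,
        degree_matched=config.degree_matched_null,
        exclude_self_draws=not config.unconditional_null,
    )
    timer.lap("permutation_test")

    vector_genes = set(candidates.genes) | set(seeds)
    vectors = enrichment_vectors(
        sorted(vector_genes), ann, net, config.total_genes_N,
        neighbor_min_score=config.neighbor_min_score,
    )
    timer.lap("enrichment_vectors")

    records = apply_filters(
        candidates, null, net, seeds, vectors,
        z_cut=config.z_cut, mls_cut=config.mls_cut, mes_cut=config.mes_cut,
        lazy=config.lazy,
    )
    timer.lap("apply_filters")

    results_path = out_dir / "results.tsv"
    write_results(results_path, records)

    n_z = sum(1 for rec in records if rec.pass_permutation)
    n_mls = sum(1 for rec in records if rec.pass_permutation and rec.pass_linkage)
    inferred_genes = sorted(rec.gene for rec in records if rec.inferred)
    logger.info(
        "cascade: %d candidates -> %d Z-pass -> %d MLS-pass -> %d inferred",
        len(candidates), n_z, n_mls, len(inferred_genes),
    )

    summary: InteractionSummary | None = None
    summary_path = out_dir / "interaction_summary.tsv"
    with open(summary_path, "wt") as fh:
        fh.write("gene\tn_validated_interactors_ge_cutoff\n")
        if inferred_genes:
            summary = interaction_summary(
                GeneSet(identifiers=tuple(inferred_genes), label="inferred"),
                seeds, net, cutoff=config.mls_cut,
            )
            for g, c in zip(summary.genes, summary.counts):
                fh.write(f"{g}\t{c}\n")
    timer.lap("write_outputs")

    manifest = {
        "config": dataclasses.asdict(config),
        "inputs": {
            "network": {"path": str(config.network_path), "sha256": _sha256(config.network_path)},
            "seeds": {"path": str(config.seeds_path), "sha256": _sha256(config.seeds_path)},
            "annotations": {
                "path": str(config.annotations_path),
                "sha256": _sha256(config.annotations_path),
            },
        },
        "network": {"n_nodes": net.n_nodes, "n_edges": net.n_edges},
        "stages": {
            "seeds_supplied": len(raw_seeds),
            "seeds_in_network": len(seeds),
            "candidates": len(candidates),
            "pass_permutation": n_z,
            "pass_linkage": n_mls,
            "inferred": len(inferred_genes),
        },
        "rwr": {"iterations": prob.iterations, "final_l1_residual": prob.residual},
        "inferred_genes": inferred_genes,
        "interaction_summary": None if summary is None else {
            "cutoff": summary.cutoff,
            "mean_count": summary.mean_count,
            "fraction_above_5": summary.fraction_above_5,
        },
    }
    with open(out_dir / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return records, summary, manifest
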