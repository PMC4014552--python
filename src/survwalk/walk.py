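"""Pathway-based random walk with restart (RWR) and core-gene extraction.

For each survival pathway regulated by a survival miRNA, a random walker
starts from seed nodes (survival genes and the miRNA's filtered target genes
present in the pathway) and iterates

    p_{t+1} = (1 - r) * W @ p_t + r * p_0

with restart probability r (default 0.7) on the column-normalized adjacency
matrix W, until the L1 change falls below 1e-6.  The steady-state vector
scores every node by proximity to the seeds; the top 3% of gene nodes per
pathway are its core survival genes.

The walk treats pathway edges as undirected by default: signaling graphs are
sparse and strict directionality strands seed probability in sinks.  A
directed mode is available.  Dangling nodes receive a self-loop before
normalization so W stays column-stochastic and probability mass is
conserved.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PathwayGraph, RunConfig, SurvwalkError, targets_of

logger = logging.getLogger("survwalk")


class SeedError(SurvwalkError):
    """No seed node intersects the pathway: the walk is undefined."""


def column_normalize(graph: PathwayGraph,
                     mode: str = "undirected") -> tuple[list[str], np.ndarray]:
    """Column-stochastic transition matrix of a pathway graph.

    Node order is fixed lexicographically.  W[i, j] is the probability of
    stepping from node j to node i.  Columns with no outgoing edge get a
    self-loop before normalization.
    """
    if not graph.nodes:
        raise SurvwalkError(f"pathway {graph.pathway_id} is empty")
    if mode not in ("undirected", "directed"):
        raise SurvwalkError(f"unknown walk mode {mode!r}")
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for s, t in graph.edges:
        W[idx[t], idx[s]] = 1.0
        if mode == "undirected":
            W[idx[s], idx[t]] = 1.0
    col_sums = W.sum(axis=0)
    dangling = col_sums == 0
    W[dangling, dangling] = 1.0
    col_sums = np.where(dangling, 1.0, col_sums)
    return nodes, W / col_sums


def build_seed_vector(graph: PathwayGraph,
                      survival_genes: Iterable[str],
                      mirna_targets: Iterable[str]) -> np.ndarray:
    """Uniform restart vector over seed nodes, aligned to lexicographic order.

    Seeds are the survival genes and miRNA target genes that are gene nodes
    of this pathway; each receives probability 1/|seeds|.
    """
    nodes = sorted(graph.nodes)
    seeds = (set(survival_genes) | set(mirna_targets)) & graph.gene_nodes
    if not seeds:
        raise SeedError(
            f"pathway {graph.pathway_id}: no seed gene present in the graph")
    p0 = np.zeros(len(nodes))
    for i, n in enumerate(nodes):
        if n in seeds:
            p0[i] = 1.0 / len(seeds)
    return p0


def random_walk_restart(W: np.ndarray, p0: np.ndarray,
                        restart_prob: float = 0.7,
                        convergence_eps: float = 1e-6,
                        max_iterations: int = 10_000) -> tuple[np.ndarray, int]:
    """Iterate the RWR map to its steady state.

    Returns (steady-state vector, iterations used).  Raises if the L1
    residual has not fallen below ``convergence_eps`` within
    ``max_iterations`` (cannot happen for a stochastic W and r > 0, where
    the map is an L1 contraction with factor 1 - r).
    """
    if not (0.0 < restart_prob < 1.0):
        raise SurvwalkError("restart_prob must be in (0, 1)")
    p = p0.astype(float).copy()
    restart = restart_prob * p0
    for it in range(1, max_iterations + 1):
        p_next = (1.0 - restart_prob) * (W @ p) + restart
        residual = np.abs(p_next - p).sum()
        p = p_next
        if residual < convergence_eps:
            return p, it
    raise SurvwalkError(
        f"random walk did not converge in {max_iterations} iterations "
        f"(last L1 residual {residual:.3e})")


@dataclass
class WalkResult:
    """Steady-state of one pathway walk."""

    pathway_id: str
    nodes: list[str]
    probs: np.ndarray
    seed_nodes: set[str]
    gene_nodes: set[str]
    iterations: int

    def scores(self) -> pd.Series:
        return pd.Series(self.probs, index=self.nodes, name=self.pathway_id)

    def ranked_genes(self) -> list[str]:
        """Gene nodes by descending score; ties broken lexicographically."""
        s = self.scores()
        genes = sorted(self.gene_nodes)
        return sorted(genes, key=lambda g: (-s[g], g))


def walk_pathway(graph: PathwayGraph,
                 survival_genes: Iterable[str],
                 mirna_targets: Iterable[str],
                 config: RunConfig | None = None) -> WalkResult:
    """Run the full RWR on one pathway from the given seed sets."""
    config = config or RunConfig()
    nodes, W = column_normalize(graph, config.walk_mode)
    p0 = build_seed_vector(graph, survival_genes, mirna_targets)
    probs, iterations = random_walk_restart(
        W, p0, config.restart_prob, config.convergence_eps, config.max_iterations)
    return WalkResult(
        pathway_id=graph.pathway_id,
        nodes=nodes,
        probs=probs,
        seed_nodes={n for n, v in zip(nodes, p0) if v > 0},
        gene_nodes=graph.gene_nodes,
        iterations=iterations,
    )


def top_core_genes(result: WalkResult, top_fraction: float = 0.03) -> set[str]:
    """The ceil(top_fraction * G) highest-scoring gene nodes of one walk.

    G counts gene-type nodes only; non-gene nodes participate in the walk
    but are never returned.  Boundary ties break lexicographically.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise SurvwalkError("top_fraction must be in (0, 1]")
    genes = result.ranked_genes()
    if not genes:
        raise SurvwalkError(f"pathway {result.pathway_id} has no gene nodes")
    k = math.ceil(top_fraction * len(genes))
    return set(genes[:k])


def run_pbrw(pathways: Mapping[str, PathwayGraph],
             regulators: Mapping[str, set[str]],
             survival_genes: Iterable[str],
             filtered_targets: pd.DataFrame,
             config: RunConfig | None = None,
             ) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Per-miRNA core survival genes across all pathways the miRNA regulates.

    ``regulators`` maps pathway_id -> set of regulating survival miRNAs (the
    selection output of the enrichment step); ``filtered_targets`` is the
    support-filtered target map.  For each miRNA the walk is seeded per
    pathway with the survival genes plus that miRNA's targets, and its core
    set is the union of top-scoring genes over its pathways.

    Returns (miRNA -> core gene set, provenance table with one row per
    (miRNA, gene, pathway) and the gene's walk score and rank).
    """
    config = config or RunConfig()
    survival_genes = set(survival_genes)
    mirnas = sorted({m for ms in regulators.values() for m in ms})
    per_mirna: dict[str, set[str]] = {}
    records = []
    for mirna in mirnas:
        regulated = sorted(p for p, ms in regulators.items() if mirna in ms)
        targets = targets_of(filtered_targets, mirna)
        core: set[str] = set()
        for pid in regulated:
            try:
                result = walk_pathway(pathways[pid], survival_genes, targets, config)
            except SeedError:
                logger.warning("run_pbrw: %s has no seeds in %s; pathway skipped",
                               mirna, pid)
                continue
            ranked = result.ranked_genes()
            top = top_core_genes(result, config.top_fraction)
            scores = result.scores()
            for rank, gene in enumerate(ranked, start=1):
                if gene in top:
                    records.append((mirna, gene, pid, float(scores[gene]), rank))
            core |= top
        per_mirna[mirna] = core
        if not regulated:
            logger.info("run_pbrw: %s regulates no selected pathway", mirna)
    provenance = pd.DataFrame(
        records, columns=["mirna_id", "gene_id", "pathway_id", "score", "rank"])
    return per_mirna, provenance
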