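"""Bipartite miRNA-gene core module assembly and sub-module detection.

The per-miRNA core gene sets from the pathway walks merge into one bipartite
module: an edge links a miRNA to every core gene of the pathways it
regulates, with the source pathways kept as edge provenance.  Genes derived
from a single pathway carry that pathway as their class; genes reached
through several pathways are classed "multi".

Sub-modules are cut out of the module by hierarchical clustering of the
gene x miRNA incidence matrix with uncentered-correlation distance and
complete linkage (the classic Cluster 3.0 setting for bipartite heat maps).
"""

from __future__ import annotations

import re
from collections.abc import Iterable
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import SurvwalkError

MULTI_PATHWAY = "multi"


@dataclass
class CoreModule:
    """Bipartite miRNA-gene module with per-edge pathway provenance."""

    mirnas: set[str] = field(default_factory=set)
    genes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)
    provenance: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    gene_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m, g in self.edges:
            if m not in self.mirnas or g not in self.genes:
                raise SurvwalkError(f"edge ({m}, {g}) has endpoint outside node sets")


@dataclass
class SubModule:
    """A cluster of the bipartite module: a miRNA and a gene signature."""

    label: str
    mirna_signature: set[str]
    gene_signature: set[str]


def assemble_module(records: Iterable[tuple[str, str, str]] | pd.DataFrame
                    ) -> CoreModule:
    """Merge (miRNA, gene, pathway) provenance records into a CoreModule.

    Accepts any iterable of (mirna_id, gene_id, pathway_id) triples or a
    DataFrame with those columns.  Order-independent and idempotent: the
    same records in any order and multiplicity produce the same module.
    """
    if isinstance(records, pd.DataFrame):
        records = records[["mirna_id", "gene_id", "pathway_id"]].itertuples(index=False)
    module = CoreModule()
    gene_pathways: dict[str, set[str]] = {}
    for mirna, gene, pathway in records:
        module.mirnas.add(mirna)
        module.genes.add(gene)
        module.edges.add((mirna, gene))
        module.provenance.setdefault((mirna, gene), set()).add(pathway)
        gene_pathways.setdefault(gene, set()).add(pathway)
    module.gene_class = {
        g: (next(iter(pws)) if len(pws) == 1 else MULTI_PATHWAY)
        for g, pws in gene_pathways.items()
    }
    return module


def degree_distribution(module: CoreModule) -> tuple[pd.Series, pd.Series]:
    """Bipartite degrees: genes per miRNA and miRNAs per gene."""
    mirna_deg = pd.Series(0, index=sorted(module.mirnas), dtype=int)
    gene_deg = pd.Series(0, index=sorted(module.genes), dtype=int)
    for m, g in module.edges:
        mirna_deg[m] += 1
        gene_deg[g] += 1
    return mirna_deg, gene_deg


_RANGE_RE = re.compile(r"([A-Za-z0-9]*[A-Za-z])(\d+)-([A-Za-z0-9]*[A-Za-z])(\d+)\Z")


def expand_symbol_range(token: str) -> list[str]:
    """Expand a printed symbol-range token into individual gene symbols.

    ``"FZD1-FZD10"`` -> FZD1, FZD2, ..., FZD10; a plain symbol expands to
    itself.  A token is treated as a range only when both sides share the
    same alphabetic/alphanumeric prefix followed by an integer, so hyphenated
    miRNA names like ``miR-455-5p`` pass through unchanged.
    """
    token = token.strip()
    if not token:
        raise SurvwalkError("empty signature token")
    m = _RANGE_RE.fullmatch(token)
    if m is None:
        return [token]
    prefix_a, a, prefix_b, b = m.group(1), int(m.group(2)), m.group(3), int(m.group(4))
    if prefix_a != prefix_b:
        raise SurvwalkError(
            f"range token {token!r} has mismatched prefixes {prefix_a!r} vs {prefix_b!r}")
    if a > b:
        raise SurvwalkError(f"range token {token!r} runs backwards ({a} > {b})")
    return [f"{prefix_a}{i}" for i in range(a, b + 1)]


def _expand_cell(cell: str) -> set[str]:
    symbols: list[str] = []
    for token in cell.split(";"):
        token = token.strip()
        if token:
            symbols.extend(expand_symbol_range(token))
    return set(symbols)


def parse_submodule_table(rows: Iterable[tuple[str, str, str]]) -> list[SubModule]:
    """Parse printed sub-module signature rows into SubModule objects.

    Each row is (label, miRNA cell, gene cell) with semicolon-separated
    tokens; gene cells may contain symbol ranges.  Signatures are expanded
    and de-duplicated.
    """
    out = []
    for label, mirna_cell, gene_cell in rows:
        out.append(SubModule(
            label=label,
            mirna_signature=_expand_cell(mirna_cell),
            gene_signature=_expand_cell(gene_cell),
        ))
    return out


def load_reference_submodules() -> list[SubModule]:
    """The four published glioma survival sub-modules (S1-S4), expanded.

    Loaded from the packaged signature table; moduleS3 (6 miRNAs, 26 genes)
    is the headline prognostic signature.
    """
    path = resources.files("survwalk.data").joinpath("glioma_submodules.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return parse_submodule_table(
        df[["sub_module", "mirna_signature", "gene_signature"]].itertuples(index=False))


def uncentered_correlation_distance(X: np.ndarray) -> np.ndarray:
    """Pairwise 1 - sum(xy) / (||x|| * ||y||) between the rows of X.

    Rows with zero norm are at distance 1 from everything (0 from
    themselves), matching the Cluster 3.0 convention for empty profiles.
    """
    X = np.asarray(X, dtype=float)
    norms = np.sqrt((X ** 2).sum(axis=1))
    safe = np.where(norms == 0, 1.0, norms)
    sim = (X @ X.T) / np.outer(safe, safe)
    zero = norms == 0
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    D = 1.0 - sim
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def detect_submodules(module: CoreModule, k: int = 4) -> list[SubModule]:
    """Cut the bipartite module into k sub-modules.

    Genes are clustered hierarchically on the gene x miRNA incidence matrix
    (uncentered-correlation distance, complete linkage) and the tree is cut
    into k gene clusters; each miRNA joins the cluster holding the largest
    share of its neighbor genes (ties go to the first cluster in label
    order).  Gene sets partition the module's genes; the union of sub-module
    miRNAs is the module's miRNA set.
    """
    if not module.genes:
        raise SurvwalkError("cannot cluster an empty module")
    genes = sorted(module.genes)
    mirnas = sorted(module.mirnas)
    if k < 1 or k > len(genes):
        raise SurvwalkError(f"k must be in 1..{len(genes)}, got {k}")
    incidence = np.zeros((len(genes), len(mirnas)))
    g_idx = {g: i for i, g in enumerate(genes)}
    m_idx = {m: j for j, m in enumerate(mirnas)}
    for m, g in module.edges:
        incidence[g_idx[g], m_idx[m]] = 1.0

    if k == 1 or len(genes) == 1:
        labels = np.ones(len(genes), dtype=int)
    else:
        D = uncentered_correlation_distance(incidence)
        Z = linkage(squareform(D, checks=False), method="complete")
        labels = fcluster(Z, t=k, criterion="maxclust")

    # stable sub-module order: by lexicographically smallest member gene
    cluster_ids = sorted(set(labels),
                         key=lambda c: min(genes[i] for i in np.flatnonzero(labels == c)))
    gene_sets = [ {genes[i] for i in np.flatnonzero(labels == c)} for c in cluster_ids ]

    mirna_sets: list[set[str]] = [set() for _ in gene_sets]
    for m in mirnas:
        neighbors = {g for mm, g in module.edges if mm == m}
        shares = [len(neighbors & gs) for gs in gene_sets]
        mirna_sets[int(np.argmax(shares))].add(m)

    return [SubModule(label=f"S{i + 1}", mirna_signature=ms, gene_signature=gs)
            for i, (ms, gs) in enumerate(zip(mirna_sets, gene_sets))]
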