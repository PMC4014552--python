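"""Hypergeometric pathway enrichment and survival-pathway selection.

A pathway is scored by the upper tail P(X >= r) of a hypergeometric
distribution: population m (genome size), t successes (genes in the
pathway), n draws (the query gene set), r observed overlap.  Survival
pathways are those enriched for the survival genes (p < alpha, BH FDR below
threshold within the tested family) that are also regulated by at least one
survival miRNA, i.e. enriched for that miRNA's filtered targets.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import PathwayGraph, SurvwalkError


def hypergeometric_pvalue(m: int, t: int, n: int, r_overlap: int) -> float:
    """Exact upper-tail P(X >= r) for X ~ Hypergeom(m, t, n).

    m: genome size; t: pathway gene count; n: query set size; r_overlap:
    observed overlap.  Stable for genome sizes up to tens of thousands.
    """
    if not (0 <= t <= m and 0 <= n <= m):
        raise SurvwalkError(f"need t <= m and n <= m, got m={m}, t={t}, n={n}")
    if not (0 <= r_overlap <= min(n, t)):
        raise SurvwalkError(
            f"r_overlap must be in [0, min(n, t)], got {r_overlap} with n={n}, t={t}")
    if r_overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(r_overlap - 1, m, t, n))


def bh_fdr(p_values: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = list(p_values)
    if not p:
        return []
    if any(not (0.0 <= x <= 1.0) for x in p):
        raise SurvwalkError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def enrich_pathways(query_genes: Iterable[str],
                    pathways: Mapping[str, PathwayGraph] | Iterable[PathwayGraph],
                    genome_size: int) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene set against every pathway.

    Only gene-type nodes count toward the pathway size t and the overlap r.
    Returns a DataFrame indexed by pathway_id with columns m, t, n, overlap,
    p_value and fdr (BH within this tested family), sorted by pathway_id so
    the result is independent of input ordering.
    """
    if not isinstance(pathways, Mapping):
        pathways = {pw.pathway_id: pw for pw in pathways}
    query = set(query_genes)
    rows = []
    for pid in sorted(pathways):
        genes = pathways[pid].gene_nodes
        t = len(genes)
        if genome_size < t:
            raise SurvwalkError(
                f"genome_size {genome_size} smaller than pathway {pid} gene count {t}")
        r = len(query & genes)
        n = min(len(query), genome_size)
        p = hypergeometric_pvalue(genome_size, t, n, r) if query else 1.0
        rows.append((pid, genome_size, t, n, r, p))
    out = pd.DataFrame(rows, columns=["pathway_id", "m", "t", "n", "overlap",
                                      "p_value"]).set_index("pathway_id")
    out["fdr"] = bh_fdr(out["p_value"]) if len(out) else []
    return out


def select_survival_pathways(gene_level: pd.DataFrame,
                             mirna_level: Mapping[str, pd.DataFrame],
                             alpha_enrich: float = 0.01,
                             fdr_threshold: float = 0.15,
                             min_regulators: int = 1,
                             ) -> tuple[list[str], dict[str, set[str]]]:
    """Intersect gene-level and miRNA-level enrichment into survival pathways.

    A pathway is selected when (a) the survival-gene enrichment has
    p < alpha_enrich and BH FDR < fdr_threshold and (b) at least
    ``min_regulators`` survival miRNAs have target enrichment p < alpha_enrich
    in it.  Returns the selected pathway ids (sorted) and, for every selected
    pathway, its set of regulating miRNAs.
    """
    regulators: dict[str, set[str]] = {}
    for mirna, table in mirna_level.items():
        for pid in table.index[table["p_value"] < alpha_enrich]:
            regulators.setdefault(pid, set()).add(mirna)

    gene_hits = gene_level.index[
        (gene_level["p_value"] < alpha_enrich)
        & (gene_level["fdr"] < fdr_threshold)]
    selected = sorted(
        pid for pid in gene_hits
        if len(regulators.get(pid, ())) >= min_regulators)
    return selected, {pid: regulators[pid] for pid in selected}
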