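"""End-to-end orchestration: screen -> enrich -> walk -> module.

``run_pipeline`` chains the three workflow steps on aligned inputs:

1. mean-split Kaplan-Meier screening of miRNAs and genes (after the 30-day
   minimum-survival filter),
2. hypergeometric selection of survival pathways from the survival genes
   and each survival miRNA's support-filtered targets,
3. per-miRNA random walk with restart over the regulated pathways, top-3%
   core-gene extraction, and bipartite module assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .enrich import enrich_pathways, select_survival_pathways
from .io import (PathwayGraph, RunConfig, SurvwalkError, filter_min_survival,
                 filter_target_map, targets_of)
from .module import CoreModule, assemble_module
from .screen import screen_features, selected_features
from .walk import run_pbrw

logger = logging.getLogger("survwalk")


@dataclass
class PipelineResult:
    """Everything a full pipeline run produces."""

    config: RunConfig
    screen_genes: pd.DataFrame
    screen_mirnas: pd.DataFrame
    survival_genes: list[str]
    survival_mirnas: list[str]
    gene_enrichment: pd.DataFrame
    mirna_enrichment: dict[str, pd.DataFrame]
    selected_pathways: list[str]
    regulators: dict[str, set[str]] = field(default_factory=dict)
    per_mirna_core: dict[str, set[str]] = field(default_factory=dict)
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)
    module: CoreModule = field(default_factory=CoreModule)


def run_pipeline(mrna: pd.DataFrame, mirna: pd.DataFrame,
                 clinical: pd.DataFrame,
                 pathways: dict[str, PathwayGraph],
                 targets: pd.DataFrame,
                 config: RunConfig | None = None,
                 samples: list[str] | None = None) -> PipelineResult:
    """Run the full module-discovery pipeline on one sample set.

    ``samples`` restricts the analysis to a subset (e.g. a training half);
    the screen means are recomputed within whichever set is analyzed.
    """
    config = config or RunConfig()
    clin = filter_min_survival(clinical, config.min_survival_days)
    if samples is not None:
        clin = clin.loc[clin.index.intersection(samples)]
    if clin.empty:
        raise SurvwalkError("no samples left after filtering")

    # Step 1: survival-feature screen
    screen_genes = screen_features(mrna, clin, config.alpha_survival)
    screen_mirnas = screen_features(mirna, clin, config.alpha_survival)
    survival_genes = selected_features(screen_genes)
    survival_mirnas = selected_features(screen_mirnas)
    logger.info("screen: %d/%d survival genes, %d/%d survival miRNAs (alpha=%g)",
                len(survival_genes), len(screen_genes),
                len(survival_mirnas), len(screen_mirnas), config.alpha_survival)

    # Step 1b: survival pathways from gene-level and miRNA-level enrichment
    genome_size = config.genome_size or mrna.index.nunique()
    filtered_targets = filter_target_map(targets, config.support_min)
    gene_enrich = enrich_pathways(survival_genes, pathways, genome_size)
    mirna_enrich = {
        m: enrich_pathways(targets_of(filtered_targets, m), pathways, genome_size)
        for m in survival_mirnas
    }
    selected, regulators = select_survival_pathways(
        gene_enrich, mirna_enrich, config.alpha_enrich,
        config.fdr_threshold, config.min_regulating_mirnas)
    logger.info("enrich: %d/%d survival pathways selected "
                "(alpha=%g, fdr<%g, >=%d regulators)",
                len(selected), len(pathways), config.alpha_enrich,
                config.fdr_threshold, config.min_regulating_mirnas)

    # Steps 2-3: per-miRNA walks, core genes, module assembly
    per_mirna, provenance = run_pbrw(
        pathways, regulators, survival_genes, filtered_targets, config)
    module = assemble_module(provenance) if len(provenance) else CoreModule()
    logger.info("module: %d miRNAs, %d genes, %d edges",
                len(module.mirnas), len(module.genes), len(module.edges))

    return PipelineResult(
        config=config,
        screen_genes=screen_genes,
        screen_mirnas=screen_mirnas,
        survival_genes=survival_genes,
        survival_mirnas=survival_mirnas,
        gene_enrichment=gene_enrich,
        mirna_enrichment=mirna_enrich,
        selected_pathways=selected,
        regulators=regulators,
        per_mirna_core=per_mirna,
        provenance=provenance,
        module=module,
    )
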