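"""Input/output layer: domain containers, file formats, run configuration.

Expression matrices are plain pandas DataFrames (feature rows x sample
columns, log-scale values); clinical tables are DataFrames indexed by
sample id.  Validation helpers enforce the container invariants at the
boundaries, so downstream modules can assume well-formed inputs.

File formats are deliberately simple text: TSV expression matrices, CSV
clinical tables, TSV pathway node/edge lists and target maps, flat YAML
configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("survwalk")

VALID_GRADES = ("II", "III", "IV")
CLINICAL_COLUMNS = ("survival_days", "event", "grade", "age", "gender")


class SurvwalkError(ValueError):
    """Base class for input-validation failures."""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Thresholds and parameters for a full pipeline run.

    Defaults follow the published analysis settings: mean-split log-rank
    screen at P < 0.001, pathway enrichment at P < 0.01 with BH FDR < 0.15,
    target-support filter at >= 6 of 11 prediction sources, random walk
    restart probability 0.7 with L1 convergence below 1e-6, top-3% core-gene
    cutoff, 30-day minimum survival, K-means with K = 2, four sub-modules,
    and top-n signature optimization for n in 2..25.
    """

    alpha_survival: float = 0.001
    alpha_enrich: float = 0.01
    fdr_threshold: float = 0.15
    support_min: int = 6
    restart_prob: float = 0.7
    convergence_eps: float = 1e-6
    top_fraction: float = 0.03
    min_survival_days: int = 30
    kmeans_k: int = 2
    submodule_count: int = 4
    topn_range: tuple[int, int] = (2, 25)
    min_regulating_mirnas: int = 1
    genome_size: int | None = None
    walk_mode: str = "undirected"
    max_iterations: int = 10_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_survival", "alpha_enrich", "fdr_threshold",
                     "restart_prob", "top_fraction"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise SurvwalkError(f"{name} must be in (0, 1], got {v}")
        if not (0.0 < self.restart_prob < 1.0):
            raise SurvwalkError("restart_prob must be in (0, 1)")
        if self.convergence_eps <= 0:
            raise SurvwalkError("convergence_eps must be positive")
        if not (1 <= self.support_min <= 11):
            raise SurvwalkError("support_min must be in 1..11")
        if self.min_survival_days < 0:
            raise SurvwalkError("min_survival_days must be >= 0")
        if self.walk_mode not in ("undirected", "directed"):
            raise SurvwalkError("walk_mode must be 'undirected' or 'directed'")
        lo, hi = self.topn_range
        if not (1 <= lo <= hi):
            raise SurvwalkError("topn_range must satisfy 1 <= lo <= hi")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SurvwalkError(f"unknown config keys: {sorted(unknown)}")
        if "topn_range" in raw:
            raw["topn_range"] = tuple(raw["topn_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["topn_range"] = list(self.topn_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed.

        Keeps independent randomized stages decoupled: changing one stage's
        draws never perturbs another's.  Result is < 2**31.
        """
        h = np.random.SeedSequence([self.rng_seed, hash(stage) & 0x7FFFFFFF])
        return int(h.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# Pathway container
# ---------------------------------------------------------------------------


@dataclass
class PathwayGraph:
    """One pathway: typed nodes (gene vs other) plus directed edges.

    ``nodes`` maps node id -> node type ("gene" or "other"); ``edges`` is a
    set of (source, target) pairs whose endpoints must be declared nodes.
    """

    pathway_id: str
    name: str
    nodes: dict[str, str]
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad_types = {t for t in self.nodes.values() if t not in ("gene", "other")}
        if bad_types:
            raise SurvwalkError(
                f"pathway {self.pathway_id}: invalid node types {sorted(bad_types)}")
        for s, t in self.edges:
            if s not in self.nodes or t not in self.nodes:
                raise SurvwalkError(
                    f"pathway {self.pathway_id}: edge ({s}, {t}) has undeclared endpoint")

    @property
    def gene_nodes(self) -> set[str]:
        return {n for n, t in self.nodes.items() if t == "gene"}

    def to_networkx(self, directed: bool = True):
        import networkx as nx

        g = nx.DiGraph() if directed else nx.Graph()
        for n, t in self.nodes.items():
            g.add_node(n, node_type=t)
        g.add_edges_from(self.edges)
        return g


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise SurvwalkError(f"duplicate feature ids: {dups[:5]}")
    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise SurvwalkError(f"duplicate sample ids: {dups[:5]}")
    if expr.isna().any().any():
        raise SurvwalkError("expression matrix contains missing values")
    return expr


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a TSV expression matrix (feature rows, sample columns).

    Duplicate feature rows are collapsed by their mean; duplicate sample
    columns or non-numeric cells are errors.
    """
    path = Path(path)
    header = path.open().readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        dups = sorted({s for s in header if header.count(s) > 1})
        raise SurvwalkError(f"{path}: duplicate sample ids {dups[:5]}")
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise SurvwalkError(
                f"{path}: non-numeric value at row {row!r}, column {col!r}")
        if df[col].isna().any():
            row = df.index[df[col].isna()][0]
            raise SurvwalkError(
                f"{path}: missing value at row {row!r}, column {col!r}")
    out = df.astype(float)
    if out.index.has_duplicates:
        n_before = out.shape[0]
        out = out.groupby(level=0, sort=False).mean()
        logger.info("read_expression: collapsed %d duplicate feature rows by mean",
                    n_before - out.shape[0])
    return validate_expression(out)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    validate_expression(expr)
    expr.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing:
        raise SurvwalkError(f"clinical table missing columns: {missing}")
    if clinical.index.has_duplicates:
        dups = clinical.index[clinical.index.duplicated()].unique().tolist()
        raise SurvwalkError(f"duplicate sample ids: {dups[:5]}")
    if (clinical["survival_days"] < 0).any():
        bad = clinical.index[clinical["survival_days"] < 0].tolist()
        raise SurvwalkError(f"negative survival_days for samples {bad[:5]}")
    bad_event = ~clinical["event"].isin((0, 1))
    if bad_event.any():
        raise SurvwalkError(
            f"event must be 0 or 1; offending samples {clinical.index[bad_event].tolist()[:5]}")
    bad_grade = ~clinical["grade"].isin(VALID_GRADES)
    if bad_grade.any():
        raise SurvwalkError(
            f"unknown grade for samples {clinical.index[bad_grade].tolist()[:5]}; "
            f"expected one of {VALID_GRADES}")
    return clinical


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a CSV clinical table indexed by sample_id.

    Required columns: survival_days (non-negative int), event (0/1),
    grade (II/III/IV), age, gender.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "grade": str, "gender": str})
    if "sample_id" not in df.columns:
        raise SurvwalkError(f"{path}: missing sample_id column")
    df = df.set_index("sample_id")
    df["survival_days"] = pd.to_numeric(df["survival_days"], errors="raise").astype(int)
    df["event"] = pd.to_numeric(df["event"], errors="raise").astype(int)
    return validate_clinical(df)


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    validate_clinical(clinical)
    clinical.to_csv(path, index_label="sample_id")


def filter_min_survival(clinical: pd.DataFrame, min_days: int) -> pd.DataFrame:
    """Drop samples observed for fewer than ``min_days`` days.

    Samples with very short follow-up (default 30 days) are conventionally
    excluded because early deaths may be unrelated to the disease.  The
    boundary is kept: survival_days >= min_days is retained.
    """
    if min_days < 0:
        raise SurvwalkError("min_days must be >= 0")
    kept = clinical[clinical["survival_days"] >= min_days]
    logger.info("filter_min_survival: kept %d/%d samples (min_days=%d)",
                len(kept), len(clinical), min_days)
    return kept


# ---------------------------------------------------------------------------
# Pathway collections
# ---------------------------------------------------------------------------


def read_pathways(nodes_path: str | Path,
                  edges_path: str | Path) -> dict[str, PathwayGraph]:
    """Read a pathway collection from a node list and an edge list.

    The node file has columns (pathway_id, node_id, node_type) and an
    optional pathway_name column; the edge file has
    (pathway_id, source, target).
    """
    nodes = pd.read_csv(nodes_path, sep="\t", dtype=str)
    edges = pd.read_csv(edges_path, sep="\t", dtype=str)
    for col in ("pathway_id", "node_id", "node_type"):
        if col not in nodes.columns:
            raise SurvwalkError(f"{nodes_path}: missing column {col}")
    for col in ("pathway_id", "source", "target"):
        if col not in edges.columns:
            raise SurvwalkError(f"{edges_path}: missing column {col}")
    pathways: dict[str, PathwayGraph] = {}
    for pid, grp in nodes.groupby("pathway_id", sort=True):
        name = pid
        if "pathway_name" in grp.columns and not grp["pathway_name"].isna().all():
            name = grp["pathway_name"].iloc[0]
        node_map = dict(zip(grp["node_id"], grp["node_type"]))
        pathways[pid] = PathwayGraph(pathway_id=pid, name=name, nodes=node_map)
    for pid, grp in edges.groupby("pathway_id", sort=True):
        if pid not in pathways:
            raise SurvwalkError(f"edge file references unknown pathway {pid}")
        pw = pathways[pid]
        edge_set = set(zip(grp["source"], grp["target"]))
        for s, t in edge_set:
            if s not in pw.nodes or t not in pw.nodes:
                raise SurvwalkError(
                    f"pathway {pid}: edge ({s}, {t}) has undeclared endpoint")
        pw.edges |= edge_set
    return pathways


def write_pathways(pathways: dict[str, PathwayGraph],
                   nodes_path: str | Path, edges_path: str | Path) -> None:
    node_rows, edge_rows = [], []
    for pid in sorted(pathways):
        pw = pathways[pid]
        for n in sorted(pw.nodes):
            node_rows.append((pid, pw.name, n, pw.nodes[n]))
        for s, t in sorted(pw.edges):
            edge_rows.append((pid, s, t))
    pd.DataFrame(node_rows, columns=["pathway_id", "pathway_name", "node_id",
                                     "node_type"]).to_csv(
        nodes_path, sep="\t", index=False)
    pd.DataFrame(edge_rows, columns=["pathway_id", "source", "target"]).to_csv(
        edges_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Target maps
# ---------------------------------------------------------------------------


def validate_target_map(targets: pd.DataFrame) -> pd.DataFrame:
    for col in ("mirna_id", "gene_id", "support_count"):
        if col not in targets.columns:
            raise SurvwalkError(f"target map missing column {col}")
    bad = ~targets["support_count"].between(1, 11)
    if bad.any():
        raise SurvwalkError(
            f"support_count outside 1..11 in {int(bad.sum())} rows")
    if targets.duplicated(subset=["mirna_id", "gene_id"]).any():
        raise SurvwalkError("duplicate (mirna_id, gene_id) pairs in target map")
    return targets


def read_target_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"mirna_id": str, "gene_id": str})
    df["support_count"] = pd.to_numeric(df["support_count"], errors="raise").astype(int)
    return validate_target_map(df)


def write_target_map(targets: pd.DataFrame, path: str | Path) -> None:
    validate_target_map(targets)
    targets.to_csv(path, sep="\t", index=False)


def filter_target_map(targets: pd.DataFrame, support_min: int) -> pd.DataFrame:
    """Keep miRNA-target pairs supported by at least ``support_min`` of the
    11 prediction sources (default 6, the reliability threshold)."""
    if not (1 <= support_min <= 12):
        raise SurvwalkError("support_min must be in 1..12")
    kept = targets[targets["support_count"] >= support_min]
    logger.info("filter_target_map: kept %d/%d pairs (support_min=%d)",
                len(kept), len(targets), support_min)
    return kept


def targets_of(targets: pd.DataFrame, mirna_id: str) -> set[str]:
    """Target-gene set of one miRNA in a (possibly filtered) target map."""
    return set(targets.loc[targets["mirna_id"] == mirna_id, "gene_id"])
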