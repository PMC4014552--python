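"""Synthetic glioma-like cohorts with a planted miRNA-gene survival module.

The generator emulates the study conditions the pipeline is designed for: a
cohort of ~160 glioma samples in three WHO-grade strata with sample-matched
miRNA and mRNA log-expression, censored survival driven by a small planted
module, pathway graphs in which the planted genes sit within graph distance
1-2 of the planted hazard drivers, and a miRNA-target map in which planted
pairs carry high prediction support (>= 6 of 11 sources) and decoys do not.

Survival model: time-to-death is exponential with hazard
``h0 * exp(effect_size * risk)`` where the per-sample risk score is the mean
expression of the planted seed (driver) genes minus the mean expression of
the planted miRNAs (miRNAs act repressively).  Censoring times are drawn
independently of death times from U(0, c_max), with c_max calibrated by
bisection so the expected censored fraction equals ``censor_rate`` (an
administrative-follow-up model).  Planted features share a latent co-expression
factor (tumor module co-expression); every feature is marginally N(0, 1) and
all background features are i.i.d. N(0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PathwayGraph, SurvwalkError

#: baseline hazard per day, set so the median survival of a risk-0 sample is
#: about 680 days (a mixed-grade glioma cohort scale)
BASELINE_HAZARD = np.log(2) / 680.0

DEFAULT_N_SAMPLES = 160
DEFAULT_N_GENES = 2000
DEFAULT_N_MIRNAS = 100
DEFAULT_N_PATHWAYS = 20
DEFAULT_GENES_PER_PATHWAY = 140
DEFAULT_N_PLANTED_PATHWAYS = 6
DEFAULT_N_DECOY_PAIRS = 300


def gene_id(i: int) -> str:
    return f"G{i:04d}"


def mirna_id(i: int) -> str:
    return f"MIR{i:03d}"


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of the planted survival module.

    ``planted_seed_genes`` (a subset of ``planted_genes``) and
    ``planted_mirnas`` drive the hazard; the remaining planted genes are
    co-expressed module members recoverable through pathway wiring.
    """

    planted_mirnas: tuple[str, ...] = (mirna_id(1), mirna_id(2))
    planted_genes: tuple[str, ...] = tuple(gene_id(i) for i in range(1, 9))
    planted_seed_genes: tuple[str, ...] = (gene_id(1), gene_id(2))
    effect_size: float = 1.5
    censor_rate: float = 0.45
    co_expression: float = 0.9

    def __post_init__(self) -> None:
        if not self.planted_mirnas or not self.planted_genes:
            raise SurvwalkError("planted sets must be non-empty")
        if not set(self.planted_seed_genes) <= set(self.planted_genes):
            raise SurvwalkError("planted_seed_genes must be a subset of planted_genes")
        if not np.isfinite(self.effect_size):
            raise SurvwalkError("effect_size must be finite")
        if not (0.0 <= self.censor_rate < 1.0):
            raise SurvwalkError("censor_rate must be in [0, 1)")
        if not (0.0 <= self.co_expression < 1.0):
            raise SurvwalkError("co_expression must be in [0, 1)")


def _calibrate_censor_horizon(hazards: np.ndarray, censor_rate: float) -> float:
    """Uniform-censoring horizon c with E[fraction censored] = censor_rate.

    For exponential death times with rates ``hazards`` and an independent
    censoring time C ~ U(0, c), a sample is censored when C < T, which has
    probability (1 - exp(-h_i c)) / (h_i c); the mean over samples decreases
    monotonically from 1 toward 0 as c grows, so c is found by bisection.
    """
    h = np.asarray(hazards, dtype=float)

    def frac(c: float) -> float:
        x = h * c
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-9, 1.0 / h.min()
    while frac(hi) > censor_rate:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > censor_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _planted_block(rng: np.random.Generator, n_feat: int, n_samples: int,
                   rho: float) -> np.ndarray:
    """Correlated N(0,1) features sharing a single latent factor."""
    z = rng.standard_normal(n_samples)
    eps = rng.standard_normal((n_feat, n_samples))
    return np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps


def generate_cohort(n_samples: int = DEFAULT_N_SAMPLES,
                    n_genes: int = DEFAULT_N_GENES,
                    n_mirnas: int = DEFAULT_N_MIRNAS,
                    truth: PlantedTruth | None = None,
                    seed: int = 0,
                    baseline_hazard: float = BASELINE_HAZARD,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate (mRNA expression, miRNA expression, clinical table).

    Grades are assigned by risk-score tertile (low risk -> grade II, high ->
    grade IV); age and gender are drawn to resemble a mixed-grade adult
    glioma cohort and carry no survival signal.
    """
    if n_samples < 10:
        raise SurvwalkError("n_samples must be >= 10 for a meaningful log-rank test")
    truth = truth or PlantedTruth()
    genes = [gene_id(i) for i in range(1, n_genes + 1)]
    mirnas = [mirna_id(i) for i in range(1, n_mirnas + 1)]
    missing = (set(truth.planted_genes) - set(genes)) | (
        set(truth.planted_mirnas) - set(mirnas))
    if missing:
        raise SurvwalkError(f"planted ids outside feature ranges: {sorted(missing)[:5]}")

    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(1, n_samples + 1)]

    mrna = pd.DataFrame(rng.standard_normal((n_genes, n_samples)),
                        index=genes, columns=samples)
    mirna = pd.DataFrame(rng.standard_normal((n_mirnas, n_samples)),
                         index=mirnas, columns=samples)
    mrna.loc[list(truth.planted_genes)] = _planted_block(
        rng, len(truth.planted_genes), n_samples, truth.co_expression)
    mirna.loc[list(truth.planted_mirnas)] = _planted_block(
        rng, len(truth.planted_mirnas), n_samples, truth.co_expression)

    risk = (mrna.loc[list(truth.planted_seed_genes)].mean(axis=0)
            - mirna.loc[list(truth.planted_mirnas)].mean(axis=0)).to_numpy()
    hazard = baseline_hazard * np.exp(truth.effect_size * risk)
    death_time = rng.exponential(1.0 / hazard)
    if truth.censor_rate > 0.0:
        c_max = _calibrate_censor_horizon(hazard, truth.censor_rate)
        censor_time = rng.random(n_samples) * c_max
    else:
        censor_time = np.full(n_samples, np.inf)
    censored = censor_time < death_time
    observed = np.minimum(death_time, censor_time)
    days = np.maximum(np.rint(observed), 1).astype(int)

    # risk tertiles -> WHO grade strata
    order = np.argsort(risk, kind="stable")
    grade = np.empty(n_samples, dtype=object)
    for stratum, label in zip(np.array_split(order, 3), ("II", "III", "IV")):
        grade[stratum] = label

    clinical = pd.DataFrame(
        {
            "survival_days": days,
            "event": (~censored).astype(int),
            "grade": grade,
            "age": np.clip(np.rint(rng.normal(41.0, 12.5, n_samples)), 18, 80).astype(int),
            "gender": np.where(rng.random(n_samples) < 0.6, "M", "F"),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return mrna, mirna, clinical


def _connected_backbone(rng: np.random.Generator,
                        nodes: list[str]) -> set[tuple[str, str]]:
    """Random spanning tree plus ~N extra edges (mean degree ~4)."""
    n = len(nodes)
    perm = rng.permutation(n)
    edges: set[tuple[str, str]] = set()
    for k in range(1, n):
        j = int(perm[k])
        i = int(perm[rng.integers(0, k)])
        edges.add((nodes[i], nodes[j]))
    extra = 0
    while extra < n:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        a, b = nodes[int(i)], nodes[int(j)]
        if (a, b) in edges or (b, a) in edges:
            continue
        edges.add((a, b))
        extra += 1
    return edges


def generate_pathways(n_pathways: int = DEFAULT_N_PATHWAYS,
                      genes_per_pathway: int = DEFAULT_GENES_PER_PATHWAY,
                      truth: PlantedTruth | None = None,
                      seed: int = 0,
                      n_planted_pathways: int = DEFAULT_N_PLANTED_PATHWAYS,
                      n_other_nodes: int = 5,
                      n_genes: int = DEFAULT_N_GENES,
                      ) -> dict[str, PathwayGraph]:
    """Simulate a pathway collection containing the planted module.

    The first ``n_planted_pathways`` pathways each contain all planted seed
    genes plus a round-robin slice of the remaining planted genes, every
    planted gene wired directly (distance 1) to every seed gene.  Decoy
    pathways contain no planted genes at all.  Each pathway is a connected
    sparse graph over its gene nodes plus a few non-gene (e.g. compound)
    nodes; edge directions are drawn at random.
    """
    if genes_per_pathway < 10:
        raise SurvwalkError("genes_per_pathway must be >= 10")
    truth = truth or PlantedTruth()
    if n_planted_pathways > n_pathways:
        raise SurvwalkError("n_planted_pathways cannot exceed n_pathways")
    rng = np.random.default_rng(seed)
    all_genes = np.array([gene_id(i) for i in range(1, n_genes + 1)])
    planted = list(truth.planted_genes)
    seeds = list(truth.planted_seed_genes)
    non_seed = [g for g in planted if g not in set(seeds)]
    background = all_genes[~np.isin(all_genes, planted)]

    per_pathway_extra = 3  # non-seed planted genes carried by each planted pathway
    pathways: dict[str, PathwayGraph] = {}
    for p in range(n_pathways):
        pid = f"PW{p + 1:02d}"
        is_planted = p < n_planted_pathways
        members: list[str] = []
        if is_planted:
            members.extend(seeds)
            if non_seed:
                take = [non_seed[(p * per_pathway_extra + k) % len(non_seed)]
                        for k in range(per_pathway_extra)]
                members.extend(dict.fromkeys(take))
        n_fill = genes_per_pathway - len(members)
        fill = rng.choice(background, size=n_fill, replace=False)
        members.extend(fill.tolist())
        others = [f"{pid}_cpd{k}" for k in range(1, n_other_nodes + 1)]
        node_map = {g: "gene" for g in members}
        node_map.update({o: "other" for o in others})

        node_list = sorted(node_map)
        edges = _connected_backbone(rng, node_list)
        if is_planted:
            for g in members[: len(seeds) + (per_pathway_extra if non_seed else 0)]:
                for s in seeds:
                    if g != s and (g, s) not in edges and (s, g) not in edges:
                        edges.add((s, g))
        pathways[pid] = PathwayGraph(pathway_id=pid, name=pid,
                                     nodes=node_map, edges=edges)
    return pathways


def generate_target_map(truth: PlantedTruth | None = None,
                        n_decoys: int = DEFAULT_N_DECOY_PAIRS,
                        seed: int = 0,
                        n_genes: int = DEFAULT_N_GENES,
                        n_mirnas: int = DEFAULT_N_MIRNAS) -> pd.DataFrame:
    """Simulate a miRNA-target map with support counts.

    Every planted (miRNA, gene) pair gets support drawn uniformly from
    6..11; decoy pairs (any other combination) get 1..5, so filtering at
    support >= 6 recovers exactly the planted regulations.
    """
    truth = truth or PlantedTruth()
    rng = np.random.default_rng(seed)
    rows = [(m, g, int(rng.integers(6, 12)))
            for m in truth.planted_mirnas for g in truth.planted_genes]
    planted_pairs = {(m, g) for m in truth.planted_mirnas for g in truth.planted_genes}
    seen = set(planted_pairs)
    while len(seen) < len(planted_pairs) + n_decoys:
        m = mirna_id(int(rng.integers(1, n_mirnas + 1)))
        g = gene_id(int(rng.integers(1, n_genes + 1)))
        if (m, g) in seen:
            continue
        seen.add((m, g))
        rows.append((m, g, int(rng.integers(1, 6))))
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "support_count"])


@dataclass
class SyntheticStudy:
    """All simulated inputs of one study replicate plus the ground truth."""

    mrna: pd.DataFrame
    mirna: pd.DataFrame
    clinical: pd.DataFrame
    pathways: dict[str, PathwayGraph]
    targets: pd.DataFrame
    truth: PlantedTruth
    planted_pathways: tuple[str, ...] = field(default=())

    @property
    def decoy_genes(self) -> set[str]:
        return set(self.mrna.index) - set(self.truth.planted_genes)

    @property
    def decoy_mirnas(self) -> set[str]:
        return set(self.mirna.index) - set(self.truth.planted_mirnas)


def simulate_study(seed: int = 0,
                   n_samples: int = DEFAULT_N_SAMPLES,
                   n_genes: int = DEFAULT_N_GENES,
                   n_mirnas: int = DEFAULT_N_MIRNAS,
                   n_pathways: int = DEFAULT_N_PATHWAYS,
                   genes_per_pathway: int = DEFAULT_GENES_PER_PATHWAY,
                   n_planted_pathways: int = DEFAULT_N_PLANTED_PATHWAYS,
                   n_decoys: int = DEFAULT_N_DECOY_PAIRS,
                   truth: PlantedTruth | None = None) -> SyntheticStudy:
    """Generate a full input set (cohort, pathways, target map) from one seed."""
    truth = truth or PlantedTruth()
    ss = np.random.SeedSequence(seed).generate_state(3) & 0x7FFFFFFF
    mrna, mirna, clinical = generate_cohort(
        n_samples, n_genes, n_mirnas, truth, seed=int(ss[0]))
    pathways = generate_pathways(
        n_pathways, genes_per_pathway, truth, seed=int(ss[1]),
        n_planted_pathways=n_planted_pathways, n_genes=n_genes)
    targets = generate_target_map(truth, n_decoys, seed=int(ss[2]),
                                  n_genes=n_genes, n_mirnas=n_mirnas)
    planted_pw = tuple(f"PW{p + 1:02d}" for p in range(n_planted_pathways))
    return SyntheticStudy(mrna, mirna, clinical, pathways, targets, truth,
                          planted_pw)
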