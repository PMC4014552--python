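"""Survival evaluation of expression signatures and robustness analysis.

A signature (a miRNA set plus a gene set) is evaluated on a sample set by
merging the matched miRNA and mRNA profiles restricted to the signature,
normalizing rows then columns to z-scores, splitting the samples into two
risk groups — either by K-means (K = 2) or by leave-one-out nearest-centroid
classification — and comparing the groups with the log-rank test.  The
cluster with the higher observed death rate is called high-risk.

Robustness utilities: top-n signature optimization over the screen ranking,
the recurrence ratio of a result set under reruns, shuffle-and-split
partitions (500 repeats by default) and partial-sample perturbation of a
fixed train/test partition.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import SurvwalkError
from .screen import logrank_test

logger = logging.getLogger("survwalk")

MIN_EVAL_SAMPLES = 10


@dataclass(frozen=True)
class Signature:
    """An expression signature: miRNA ids plus gene ids (either may be empty)."""

    signature_id: str
    mirnas: frozenset[str] = frozenset()
    genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.mirnas and not self.genes:
            raise SurvwalkError(f"signature {self.signature_id} is empty")


@dataclass
class SignatureEvalResult:
    """Outcome of one signature evaluation on one sample set."""

    signature_id: str
    method: str
    risk_labels: pd.Series  # sample -> "high" | "low"
    statistic: float
    logrank_p: float
    group_sizes: dict[str, int]


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row to mean 0, sd 1 (population sd)."""
    sd = matrix.std(axis=1, ddof=0).replace(0.0, 1.0)
    return matrix.sub(matrix.mean(axis=1), axis=0).div(sd, axis=0)


def zscore_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each column to mean 0, sd 1 (population sd)."""
    sd = matrix.std(axis=0, ddof=0).replace(0.0, 1.0)
    return matrix.sub(matrix.mean(axis=0), axis=1).div(sd, axis=1)


def merge_and_normalize(mirna_expr: pd.DataFrame, mrna_expr: pd.DataFrame,
                        signature: Signature) -> pd.DataFrame:
    """Merge the matched profiles, normalize, then restrict to a signature.

    The *full* miRNA and mRNA matrices are stacked on their shared samples
    and z-scored by row (feature) and then by column (sample), so that
    platform scale and per-sample offsets are removed against the whole
    profile background; only afterwards is the matrix cut down to the
    signature features.  Normalizing after restriction would let a small
    signature normalize against itself — the column step of a two-feature
    signature, for instance, would cancel the features' common (and
    prognostically relevant) component.  Constant rows are dropped with a
    warning before normalization.
    """
    shared = mirna_expr.columns.intersection(mrna_expr.columns)
    if shared.empty:
        raise SurvwalkError("miRNA and mRNA matrices share no samples")
    missing = (set(signature.mirnas) - set(mirna_expr.index)) | (
        set(signature.genes) - set(mrna_expr.index))
    if missing:
        raise SurvwalkError(
            f"signature {signature.signature_id}: features absent from "
            f"expression data: {sorted(missing)[:5]}")
    merged = pd.concat([mirna_expr[shared], mrna_expr[shared]], axis=0)

    constant = merged.std(axis=1, ddof=0) == 0
    if constant.any():
        logger.warning("merge_and_normalize: dropped %d constant rows",
                       int(constant.sum()))
        merged = merged[~constant]
    if merged.empty:
        raise SurvwalkError("no non-constant features left")
    normalized = zscore_columns(zscore_rows(merged))

    wanted = sorted(set(signature.mirnas) | set(signature.genes))
    kept = [f for f in wanted if f in normalized.index]
    if not kept:
        raise SurvwalkError("no non-constant signature features left")
    return normalized.loc[kept]


def _death_rate_order(clinical: pd.DataFrame,
                      groups: dict[str, list[str]]) -> str:
    """Key of the group to call high-risk.

    Higher death rate wins; ties fall back to shorter median survival, then
    to the lexicographically first group key.
    """
    def sort_key(key: str):
        members = clinical.loc[groups[key]]
        rate = members["event"].mean() if len(members) else 0.0
        med = members["survival_days"].median() if len(members) else np.inf
        return (-rate, med, key)

    return min(groups, key=sort_key)


def _label_by_risk(clinical: pd.DataFrame, assignment: pd.Series) -> pd.Series:
    groups = {str(c): assignment.index[assignment == c].tolist()
              for c in sorted(assignment.unique(), key=str)}
    high_key = _death_rate_order(clinical, groups)
    return pd.Series(
        np.where(assignment.astype(str) == high_key, "high", "low"),
        index=assignment.index, name="risk")


def _fit_kmeans(matrix: pd.DataFrame, k: int, seed: int) -> pd.Series:
    if matrix.shape[1] < 2 * k:
        raise SurvwalkError(f"need at least {2 * k} samples for k={k} clustering")
    X = matrix.to_numpy(dtype=float).T  # samples as points
    if np.allclose(X, X[0]):
        raise SurvwalkError("all samples identical; clustering is degenerate")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed & 0x7FFFFFFF)
    labels = km.fit_predict(X)
    return pd.Series(labels, index=matrix.columns)


def kmeans_risk_groups(matrix: pd.DataFrame, clinical: pd.DataFrame,
                       k: int = 2, seed: int = 0) -> pd.Series:
    """Two-group K-means risk split of the samples (columns) of ``matrix``.

    Returns a 'high'/'low' label per sample; the cluster with the higher
    death rate is high-risk.  Deterministic given the seed (10 restarts,
    best inertia).
    """
    assignment = _fit_kmeans(matrix, k, seed)
    return _label_by_risk(clinical.loc[matrix.columns], assignment)


def nearest_centroid_classify(matrix: pd.DataFrame, clinical: pd.DataFrame,
                              seed: int = 0) -> pd.Series:
    """Leave-one-out nearest-centroid risk classification.

    For each sample, K-means (K = 2) clusters the remaining samples; the two
    clusters are risk-labeled by death rate among those samples, and the
    held-out sample joins the risk group of the nearer centroid (Euclidean);
    an exact tie goes to the high-risk group.
    """
    if matrix.shape[1] < 5:
        raise SurvwalkError("nearest-centroid evaluation needs >= 5 samples")
    clin = clinical.loc[matrix.columns]
    labels = {}
    for i, sample in enumerate(matrix.columns):
        rest = matrix.drop(columns=sample)
        assignment = _fit_kmeans(rest, 2, seed + i)
        risk = _label_by_risk(clin.loc[rest.columns], assignment)
        x = matrix[sample].to_numpy(dtype=float)
        dists = {}
        for c in np.unique(assignment):
            centroid = rest.loc[:, (assignment == c).to_numpy()].mean(axis=1).to_numpy()
            c_risk = risk[assignment.index[assignment == c][0]]
            d = float(np.linalg.norm(x - centroid))
            # keep the smaller distance per risk label
            dists[c_risk] = min(d, dists.get(c_risk, np.inf))
        labels[sample] = "high" if dists.get("high", np.inf) <= dists.get("low", np.inf) \
            else "low"
    return pd.Series(labels, name="risk").reindex(matrix.columns)


def evaluate_signature(mirna_expr: pd.DataFrame, mrna_expr: pd.DataFrame,
                       clinical: pd.DataFrame, signature: Signature,
                       method: str = "kmeans", seed: int = 0,
                       samples: Sequence[str] | None = None,
                       ) -> SignatureEvalResult:
    """Evaluate a signature's survival separation on a sample set.

    ``samples`` restricts the evaluation to a subset (e.g. a grade subgroup);
    by default all samples shared between the expression matrices and the
    clinical table are used.  Requires at least 10 samples.
    """
    if method not in ("kmeans", "nearest_centroid"):
        raise SurvwalkError(f"unknown evaluation method {method!r}")
    shared = mirna_expr.columns.intersection(mrna_expr.columns).intersection(
        clinical.index)
    if samples is not None:
        shared = shared.intersection(pd.Index(samples))
    if len(shared) < MIN_EVAL_SAMPLES:
        raise SurvwalkError(
            f"evaluation needs >= {MIN_EVAL_SAMPLES} samples, got {len(shared)}")
    merged = merge_and_normalize(mirna_expr[shared], mrna_expr[shared], signature)
    clin = clinical.loc[merged.columns]
    if method == "kmeans":
        risk = kmeans_risk_groups(merged, clin, k=2, seed=seed)
    else:
        risk = nearest_centroid_classify(merged, clin, seed=seed)

    sizes = risk.value_counts().to_dict()
    if len(sizes) < 2:
        stat, p = 0.0, 1.0
    else:
        stat, p = logrank_test(clin["survival_days"].to_numpy(),
                               clin["event"].to_numpy(), risk.to_numpy())
    return SignatureEvalResult(
        signature_id=signature.signature_id, method=method, risk_labels=risk,
        statistic=stat, logrank_p=p,
        group_sizes={"high": int(sizes.get("high", 0)),
                     "low": int(sizes.get("low", 0))})


def optimize_topn(ranked_genes: Sequence[str],
                  mirna_expr: pd.DataFrame, mrna_expr: pd.DataFrame,
                  clinical: pd.DataFrame,
                  n_range: tuple[int, int] = (2, 25),
                  method: str = "kmeans", seed: int = 0,
                  samples: Sequence[str] | None = None,
                  ) -> tuple[int, pd.DataFrame]:
    """Find the top-n gene subset with the best survival separation.

    ``ranked_genes`` must be ordered by ascending screen p-value.  Every
    top-n signature for n in ``n_range`` (inclusive) is evaluated; the best
    n minimizes the log-rank p (ties -> smallest n).  Returns (best n, the
    full p-vs-n curve).
    """
    lo, hi = n_range
    if hi > len(ranked_genes):
        logger.warning("optimize_topn: only %d ranked genes; truncating n to %d",
                       len(ranked_genes), len(ranked_genes))
        hi = len(ranked_genes)
    if lo > hi:
        raise SurvwalkError("n_range is empty after truncation")
    rows = []
    for n in range(lo, hi + 1):
        sig = Signature(signature_id=f"top{n}",
                        genes=frozenset(ranked_genes[:n]))
        res = evaluate_signature(mirna_expr, mrna_expr, clinical, sig,
                                 method=method, seed=seed, samples=samples)
        rows.append((n, res.logrank_p, res.statistic))
    curve = pd.DataFrame(rows, columns=["n", "p_value", "statistic"]).set_index("n")
    best_n = int(curve["p_value"].idxmin())  # idxmin takes the first minimum
    return best_n, curve


def recurrence_ratio(original: Iterable[str], rerun: Iterable[str]) -> float:
    """|original ∩ rerun| / |original|: how much of a result set recurs."""
    original = set(original)
    if not original:
        raise SurvwalkError("recurrence ratio undefined for an empty original set")
    return len(original & set(rerun)) / len(original)


def shuffle_and_split(samples: Sequence[str], n_repeats: int = 500,
                      train_fraction: float = 0.5, seed: int = 0,
                      ) -> list[tuple[list[str], list[str]]]:
    """Repeated random disjoint train/test partitions of a sample list."""
    samples = list(samples)
    if len(samples) < 4:
        raise SurvwalkError("need >= 4 samples to split")
    if not (0.0 < train_fraction < 1.0):
        raise SurvwalkError("train_fraction must be in (0, 1)")
    n_train = int(round(train_fraction * len(samples)))
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_repeats):
        perm = rng.permutation(len(samples))
        train = sorted(samples[i] for i in perm[:n_train])
        test = sorted(samples[i] for i in perm[n_train:])
        out.append((train, test))
    return out


def perturb_partition(train: Sequence[str], test: Sequence[str],
                      n_swap: int, seed: int = 0,
                      ) -> tuple[list[str], list[str]]:
    """Swap ``n_swap`` samples between a train and a test set.

    Models a partial-sample perturbation of a fixed partition before a full
    pipeline rerun.
    """
    train, test = list(train), list(test)
    if n_swap > min(len(train), len(test)):
        raise SurvwalkError("n_swap exceeds a partition size")
    rng = np.random.default_rng(seed)
    tr_idx = rng.choice(len(train), size=n_swap, replace=False)
    te_idx = rng.choice(len(test), size=n_swap, replace=False)
    for a, b in zip(tr_idx, te_idx):
        train[a], test[b] = test[b], train[a]
    return sorted(train), sorted(test)


def km_curve_data(times: np.ndarray, events: np.ndarray,
                  labels: pd.Series) -> pd.DataFrame:
    """Kaplan-Meier survival curves per risk group (for plotting/export)."""
    from lifelines import KaplanMeierFitter

    rows = []
    for grp in sorted(labels.unique()):
        mask = (labels == grp).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(np.asarray(times)[mask], np.asarray(events)[mask])
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(sf.index)
        for t, s, n in zip(sf.index, sf.iloc[:, 0], at_risk):
            rows.append((grp, float(t), float(s), int(n)))
    return pd.DataFrame(rows, columns=["group", "time", "survival", "at_risk"])
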