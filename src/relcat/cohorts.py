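"""Two-stage subgroup analysis for confidence-scale tables.

The pipeline standardizes every variable to z-scores, runs Ward
(squared-Euclidean) agglomeration to suggest the number of clusters from
the agglomeration schedule (largest relative jump in merge height — the
elbow — with a user override), seeds k-means at the Ward cluster centroids
(deterministic, no random restarts), and reports per-cluster per-variable
standardized effect sizes against the grand mean using the multi-group
pooled standard deviation:

    d_gv = (mean_gv - grand_mean_v) / pooled_sd_v,
    pooled_sd_v = sqrt( sum_g (n_g - 1) s_gv^2 / sum_g (n_g - 1) ).

Everything is deterministic given the input table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "zscore",
    "WardSchedule",
    "ward_schedule",
    "SubgroupResult",
    "kmeans_from_centroids",
    "effect_sizes",
    "run_subgroups",
]


def zscore(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize each column to mean 0, sample sd 1 (ddof = 1).

    Zero-variance columns are dropped with a warning; an all-constant
    table is an error.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows to standardize")
    sd = table.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if len(constant) == len(table.columns):
        raise ValueError("all columns are constant; nothing to standardize")
    if constant:
        warnings.warn(f"dropping zero-variance column(s): {', '.join(map(str, constant))}")
        table = table.drop(columns=constant)
        sd = sd.drop(index=constant)
    return (table - table.mean()) / sd


@dataclass
class WardSchedule:
    """Ward agglomeration schedule plus the elbow suggestion."""

    linkage_matrix: np.ndarray
    merge_heights: np.ndarray
    suggested_k: int

    def labels(self, k: int) -> np.ndarray:
        """Cluster labels (1..k) from cutting the Ward tree at k groups."""
        n = self.linkage_matrix.shape[0] + 1
        if k < 1 or k > n:
            raise ValueError(f"k must lie in 1..{n}")
        if k == 1:
            return np.ones(n, dtype=int)
        return fcluster(self.linkage_matrix, t=k, criterion="maxclust")


def ward_schedule(table: pd.DataFrame) -> WardSchedule:
    """Full Ward schedule; k suggested at the largest relative height jump.

    Heights are non-decreasing across merges; cutting just before merge j
    leaves n - j clusters, so the largest relative jump between successive
    heights picks the elbow.  All-identical rows give all-zero heights and
    k = 1.  The suggestion is advisory — ``WardSchedule.labels`` accepts
    any override.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows for an agglomeration schedule")
    data = np.asarray(table, dtype=float)
    Z = linkage(data, method="ward")
    heights = Z[:, 2]
    if heights[-1] <= 1e-12:
        return WardSchedule(Z, heights, suggested_k=1)
    n = data.shape[0]
    eps = 1e-12
    ratios = (heights[1:] - heights[:-1]) / np.maximum(heights[:-1], eps)
    j = int(np.argmax(ratios)) + 1  # cut before merge j (0-based)
    suggested = n - j
    return WardSchedule(Z, heights, suggested_k=max(2, min(suggested, n - 1)))


@dataclass
class SubgroupResult:
    """Outcome of the two-stage clustering.

    labels are 1..k; ``effects`` is a (cluster x variable) table of
    standardized mean differences vs. the grand mean (NaN where the pooled
    SD is zero).
    """

    k: int
    labels: np.ndarray
    centroids: pd.DataFrame
    merge_heights: np.ndarray | None = None
    effects: pd.DataFrame | None = None
    inertia: float = float("nan")


def kmeans_from_centroids(table: pd.DataFrame, ward_labels: np.ndarray) -> SubgroupResult:
    """k-means seeded at the Ward cluster centroids (no random restarts).

    Deterministic given the table and labels.  k = 1 degenerates to a
    single cluster whose centroid is the grand mean.
    """
    ward_labels = np.asarray(ward_labels)
    if len(ward_labels) != len(table):
        raise ValueError("ward_labels must cover every row")
    data = np.asarray(table, dtype=float)
    ks = np.unique(ward_labels)
    k = len(ks)
    if k == 1:
        centroid = pd.DataFrame([data.mean(axis=0)], columns=table.columns, index=[1])
        return SubgroupResult(
            k=1, labels=np.ones(len(table), dtype=int), centroids=centroid, inertia=0.0
        )
    seeds = np.vstack([data[ward_labels == val].mean(axis=0) for val in ks])
    km = KMeans(n_clusters=k, init=seeds, n_init=1, max_iter=300)
    fitted = km.fit(data)
    centroids = pd.DataFrame(fitted.cluster_centers_, columns=table.columns, index=range(1, k + 1))
    return SubgroupResult(
        k=k,
        labels=fitted.labels_ + 1,
        centroids=centroids,
        inertia=float(fitted.inertia_),
    )


def effect_sizes(result: SubgroupResult, table: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster per-variable d vs. the grand mean, pooled-SD denominator."""
    data = table.reset_index(drop=True)
    grand = data.mean()
    groups = [data[result.labels == g] for g in range(1, result.k + 1)]
    weights = np.array([max(len(g) - 1, 0) for g in groups], dtype=float)
    if weights.sum() == 0:
        pooled = pd.Series(0.0, index=data.columns)
    else:
        variances = np.vstack([g.var(ddof=1).fillna(0.0).to_numpy() for g in groups])
        pooled = pd.Series(
            np.sqrt((weights[:, None] * variances).sum(axis=0) / weights.sum()),
            index=data.columns,
        )
    rows = {}
    for g, group in enumerate(groups, start=1):
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (group.mean() - grand) / pooled
        d[pooled == 0] = np.nan
        rows[g] = d
    effects = pd.DataFrame(rows).T
    if effects.isna().any().any():
        logger.info("pooled SD is zero for some variable(s); effect sizes reported missing")
    result.effects = effects
    return effects


def run_subgroups(table: pd.DataFrame, k: int | str = "auto") -> SubgroupResult:
    """z-score -> Ward (choose k) -> seeded k-means -> effect sizes."""
    standardized = zscore(table)
    schedule = ward_schedule(standardized)
    chosen = schedule.suggested_k if k == "auto" else int(k)
    labels = schedule.labels(chosen)
    result = kmeans_from_centroids(standardized, labels)
    result.merge_heights = schedule.merge_heights
    effect_sizes(result, standardized)
    return result
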