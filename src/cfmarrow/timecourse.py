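"""Temporal analysis of cf-mRNA across marrow ablation and reconstitution.

The pipeline mirrors how longitudinal cf-mRNA studies summarize lineage
dynamics: keep genes that both reach a working expression level (max over
time points > 50 TPM) and actually vary (max/min ratio > 5); divide each
gene by its maximum so shapes, not levels, are compared; cluster the shapes
(k-means or hierarchical); and summarize named lineage gene sets as average
fold change or percent change relative to a reference day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "GeneCluster",
    "TrajectoryResult",
    "select_time_varying",
    "max_normalize",
    "cluster_genes",
    "lineage_trajectory",
]


@dataclass
class GeneCluster:
    """One cluster of genes sharing a temporal expression shape."""

    members: list[str]
    normalized_profiles: pd.DataFrame  # gene x day, rows peak at 1
    method: str  # "kmeans" or "hierarchical"
    k_or_cut: int


@dataclass
class TrajectoryResult:
    """Average lineage trajectory with per-gene traces."""

    summary: pd.DataFrame  # day-indexed: mean, sem, n_genes
    traces: pd.DataFrame  # gene x day per-gene ratios / percent changes
    excluded_genes: list[str]
    mode: str
    reference_day: int


def select_time_varying(
    matrix: pd.DataFrame,
    min_max_tpm: float = 50.0,
    min_ratio: float = 5.0,
    ratio_pseudocount: float = 1.0,
) -> list[str]:
    """Genes that are both expressed and dynamic across time points.

    A gene is selected when its maximum over days exceeds ``min_max_tpm``
    AND ``(max + pc) / (min + pc)`` exceeds ``min_ratio``.  The pseudocount
    (default 1 TPM) keeps the ratio finite when the minimum is 0; strict
    ratio behavior is obtained with ``ratio_pseudocount=0``, in which case
    any positive maximum over a zero minimum counts as infinite ratio.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two time points")
    hi = matrix.max(axis=1)
    lo = matrix.min(axis=1)
    with np.errstate(divide="ignore"):
        ratio = (hi + ratio_pseudocount) / (lo + ratio_pseudocount)
    ratio = ratio.where(~((lo + ratio_pseudocount == 0) & (hi > 0)), np.inf)
    keep = (hi > min_max_tpm) & (ratio > min_ratio)
    return [str(g) for g in matrix.index[keep]]


def max_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each gene's row by its maximum so every row peaks at exactly 1."""
    row_max = matrix.max(axis=1)
    if (row_max <= 0).any():
        bad = list(matrix.index[row_max <= 0])
        raise ValueError(f"cannot max-normalize all-zero rows: {bad[:5]}")
    return matrix.div(row_max, axis=0)


def cluster_genes(
    profiles: pd.DataFrame,
    method: str = "kmeans",
    k: int = 8,
    seed: int = 0,
    linkage: str = "average",
) -> list[GeneCluster]:
    """Partition max-normalized temporal profiles into k shape clusters.

    ``kmeans`` runs seeded k-means (10 restarts, best inertia kept);
    ``hierarchical`` builds an agglomerative tree with the given linkage on
    Euclidean distances and cuts it into k flat clusters.
    """
    n = profiles.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, {n}]")
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(profiles.to_numpy(dtype=float))
    elif method == "hierarchical":
        Z = scipy_linkage(profiles.to_numpy(dtype=float), method=linkage,
                          metric="euclidean")
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    clusters = []
    for lab in sorted(set(labels)):
        members = profiles.index[labels == lab]
        clusters.append(
            GeneCluster(
                members=[str(g) for g in members],
                normalized_profiles=profiles.loc[members],
                method=method,
                k_or_cut=k,
            )
        )
    return clusters


def lineage_trajectory(
    matrix: pd.DataFrame,
    lineage_genes: list[str],
    mode: str = "fold_change",
    reference_day: int = 0,
    max_tpm_cap: float | None = None,
    zero_reference: str = "exclude",
    zero_pseudocount: float = 1.0,
) -> TrajectoryResult:
    """Average relative trajectory of a lineage's marker genes.

    Each gene's values are expressed relative to its own level at
    ``reference_day`` — as a ratio (``fold_change``) or as
    ``100 * (value/ref - 1)`` (``percent_change``) — and the per-gene curves
    are averaged arithmetically at each day, with the standard error across
    genes.  Genes exceeding ``max_tpm_cap`` at any day are excluded when a
    cap is set (the figure-style convention caps at 5000 TPM so a few very
    abundant transcripts do not dominate the average).  Genes undetected at
    the reference day are excluded and logged by default
    (``zero_reference="exclude"``), or floored at ``zero_pseudocount`` TPM
    (``zero_reference="pseudocount"``).
    """
    if mode not in ("fold_change", "percent_change"):
        raise ValueError(f"unknown mode {mode!r}")
    if reference_day not in matrix.columns:
        raise ValueError(f"reference day {reference_day} not in matrix")
    missing = [g for g in lineage_genes if g not in matrix.index]
    if missing:
        raise ValueError(f"lineage genes absent from matrix: {missing[:5]}")

    sub = matrix.loc[list(lineage_genes)].astype(float)
    excluded: list[str] = []
    if max_tpm_cap is not None:
        over = sub.max(axis=1) > max_tpm_cap
        excluded += [str(g) for g in sub.index[over]]
        sub = sub.loc[~over]

    ref = sub[reference_day]
    if zero_reference == "exclude":
        zero = ref <= 0
        if zero.any():
            logger.info(
                "excluding %d genes undetected at reference day %s",
                int(zero.sum()), reference_day,
            )
            excluded += [str(g) for g in sub.index[zero]]
            sub, ref = sub.loc[~zero], ref[~zero]
    elif zero_reference == "pseudocount":
        ref = ref.clip(lower=zero_pseudocount)
    else:
        raise ValueError(f"unknown zero_reference policy {zero_reference!r}")
    if sub.empty:
        raise ValueError("no lineage genes left after filtering")

    traces = sub.div(ref, axis=0)
    if mode == "percent_change":
        traces = 100.0 * (traces - 1.0)

    n = traces.shape[0]
    summary = pd.DataFrame(
        {
            "mean": traces.mean(axis=0),
            "sem": traces.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else 0.0,
            "n_genes": n,
        }
    )
    summary.index.name = "day"
    return TrajectoryResult(
        summary=summary,
        traces=traces,
        excluded_genes=excluded,
        mode=mode,
        reference_day=reference_day,
    )
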