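"""Marker-gene selection and cluster-profile aggregation.

Candidate markers for each transcriptomic cluster are ranked by one-vs-rest
AUROC (Mann-Whitney rank separation with mid-rank ties) and filtered on the
fraction of expressing cells inside and outside the cluster, the same rule
presto-style marker selection applies.  Aggregated per-cluster read counts,
max-scaled per gene to [0, 1], form the reference profiles used downstream
to assign smFISH cells to clusters, and a Euclidean-distance dendrogram
relates the clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.stats import rankdata

from .simdata import AlignmentError, ParameterError

__all__ = [
    "ExpressionMatrix",
    "ClusterProfile",
    "Dendrogram",
    "compute_auc_markers",
    "top_markers",
    "aggregate_profiles",
    "cluster_dendrogram",
]


class ConfigurationError(ValueError):
    pass


class LookupError_(KeyError):
    """Requested gene or cluster id does not exist."""


@dataclass
class ExpressionMatrix:
    """Nonnegative cells x genes count matrix with one cluster label per cell."""

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    labels: pd.Series  # indexed by cell id

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ParameterError("counts must be 2-D (cells x genes)")
        n, g = self.counts.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise AlignmentError("id lists must match the count matrix shape")
        if self.counts.size and self.counts.min() < 0:
            raise ParameterError("counts must be nonnegative")
        self.labels = pd.Series(self.labels)
        if list(self.labels.index) != list(self.cell_ids):
            self.labels = self.labels.reindex(self.cell_ids)
        if self.labels.isna().any():
            raise ParameterError("every cell needs exactly one cluster label")

    @property
    def clusters(self) -> list[str]:
        return sorted(self.labels.unique())


@dataclass
class ClusterProfile:
    """Per-cluster aggregated marker expression, max-scaled per gene to [0, 1]."""

    clusters: list[str]
    genes: list[str]
    aggregate: np.ndarray  # clusters x genes, raw summed counts
    scaled: np.ndarray  # clusters x genes in [0, 1]

    @classmethod
    def from_aggregate(cls, clusters, genes, aggregate) -> "ClusterProfile":
        aggregate = np.asarray(aggregate, dtype=float)
        col_max = aggregate.max(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = np.where(col_max > 0, aggregate / np.where(col_max > 0, col_max, 1.0), 0.0)
        return cls(list(clusters), list(genes), aggregate, scaled)

    def row(self, cluster: str) -> np.ndarray:
        try:
            return self.scaled[self.clusters.index(cluster)]
        except ValueError as e:
            raise LookupError_(cluster) from e

    def to_frame(self, which: str = "scaled") -> pd.DataFrame:
        mat = self.scaled if which == "scaled" else self.aggregate
        return pd.DataFrame(mat, index=self.clusters, columns=self.genes)


def compute_auc_markers(
    expr: ExpressionMatrix,
    auc_min: float = 0.5,
    pct_in_min: float = 20.0,
    pct_out_max: float = 20.0,
    top_n: int = 5,
) -> pd.DataFrame:
    """One-vs-rest AUROC marker screen for every (gene, cluster) pair.

    AUC is the Mann-Whitney rank statistic (mid-rank ties); pct_in / pct_out
    are the percentages of cells with count > 0 inside / outside the cluster.
    A gene passes for a cluster iff auc > auc_min, pct_in >= pct_in_min and
    pct_out <= pct_out_max (strict on the AUC threshold only); passing genes
    are ranked per cluster by decreasing AUC, others get rank 0.  ``top_n``
    is recorded for use by :func:`top_markers`.
    """
    clusters = expr.clusters
    if len(clusters) < 2:
        raise ConfigurationError("marker selection needs >= 2 clusters")
    counts = expr.counts
    n_cells = counts.shape[0]
    ranks = rankdata(counts, axis=0)  # average ties -> mid-rank AUC
    expressed = counts > 0
    labels = expr.labels.to_numpy()
    records = []
    for cl in clusters:
        m = labels == cl
        n_in = int(m.sum())
        n_out = n_cells - n_in
        if n_in == 0 or n_out == 0:
            raise ConfigurationError(f"cluster {cl!r} is empty or covers all cells")
        r_in = ranks[m].sum(axis=0)
        auc = (r_in - n_in * (n_in + 1) / 2.0) / (n_in * n_out)
        pct_in = 100.0 * expressed[m].mean(axis=0)
        pct_out = 100.0 * expressed[~m].mean(axis=0)
        passed = (auc > auc_min) & (pct_in >= pct_in_min) & (pct_out <= pct_out_max)
        rec = pd.DataFrame(
            {
                "gene": expr.gene_ids,
                "cluster": cl,
                "auc": auc,
                "pct_in": pct_in,
                "pct_out": pct_out,
                "passed": passed,
                "rank": 0,
            }
        )
        order = rec[rec["passed"]].sort_values(["auc", "gene"], ascending=[False, True]).index
        rec.loc[order, "rank"] = np.arange(1, len(order) + 1)
        records.append(rec)
    out = pd.concat(records, ignore_index=True)
    out.attrs["top_n"] = top_n
    return out


def top_markers(markers: pd.DataFrame, top_n: int | None = None) -> pd.DataFrame:
    """Top-n passing genes per cluster by AUC (presto-style report)."""
    if top_n is None:
        top_n = markers.attrs.get("top_n", 5)
    sel = markers[(markers["passed"]) & (markers["rank"] >= 1) & (markers["rank"] <= top_n)]
    return sel.sort_values(["cluster", "rank"], ignore_index=True)


def aggregate_profiles(expr: ExpressionMatrix, genes: list[str]) -> ClusterProfile:
    """Sum read counts per (cluster, gene) and max-scale per gene to [0, 1].

    Genes with zero aggregate in every cluster scale to 0 everywhere.
    """
    missing = [g for g in genes if g not in expr.gene_ids]
    if missing:
        raise LookupError_(f"unknown gene id(s): {missing}")
    gi = [expr.gene_ids.index(g) for g in genes]
    labels = expr.labels.to_numpy()
    clusters = expr.clusters
    agg = np.vstack(
        [expr.counts[labels == cl][:, gi].sum(axis=0) for cl in clusters]
    )
    return ClusterProfile.from_aggregate(clusters, list(genes), agg)


@dataclass
class Dendrogram:
    """Agglomerative clustering of cluster profiles (scipy linkage encoding)."""

    labels: list[str]
    linkage: np.ndarray

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in sch.leaves_list(self.linkage)]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def cluster_dendrogram(
    profile: ClusterProfile, linkage: str = "average", values: str = "scaled"
) -> Dendrogram:
    """Hierarchical clustering of cluster rows by Euclidean distance.

    ``values`` selects the scaled ([0, 1]) or raw aggregated rows; average
    linkage is the default and guarantees monotone merge heights.
    """
    if len(profile.clusters) < 2:
        raise ConfigurationError("dendrogram needs >= 2 clusters")
    mat = profile.scaled if values == "scaled" else profile.aggregate
    Z = sch.linkage(mat, method=linkage, metric="euclidean")
    return Dendrogram(list(profile.clusters), Z)
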