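"""k-means co-expression clustering across tissues, with tissue-specificity
calls and a low-expression-cluster filter.

Expression values are log2(x + 1)-transformed and z-scored per gene before
clustering, so clusters group genes by expression *pattern* rather than
level.  A cluster is tissue-specific for tissue t when its centroid there
deviates from the centroid mean by more than ``fold`` standard deviations
(across tissues); the deviation's sign separates high-in-t from low-in-t
patterns.  Clusters of uniformly low expression are flagged and excluded
from tissue-specific gene lists, mirroring the removal of a low-expression
cluster in tissue-atlas analyses.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


@dataclass
class ClusterReport:
    assignments: pd.Series         # gene id -> cluster label
    centroids: pd.DataFrame        # cluster x tissue, z-scored log space
    gene_means: pd.Series          # per-gene mean log2 expression
    cluster_means: pd.Series       # cluster -> mean of member gene_means
    inertia: float
    tissue_specific: pd.DataFrame | None = None  # cluster x tissue in {-1,0,1}
    low_expression: pd.Series | None = None      # cluster -> bool

    def members(self, cluster: int) -> list[str]:
        return list(self.assignments.index[self.assignments == cluster])

    def tissue_specific_genes(self) -> dict[str, list[str]]:
        """Gene lists per tissue from tissue-specific, non-low clusters."""
        if self.tissue_specific is None:
            raise ValueError("run tissue_specific_clusters first")
        low = (self.low_expression if self.low_expression is not None
               else pd.Series(False, index=self.centroids.index))
        out: dict[str, list[str]] = {}
        for tissue in self.tissue_specific.columns:
            genes: list[str] = []
            for k in self.tissue_specific.index:
                if self.tissue_specific.loc[k, tissue] != 0 and not low[k]:
                    genes.extend(self.members(k))
            out[tissue] = sorted(genes)
        return out


def _preprocess(matrix: pd.DataFrame) -> tuple[np.ndarray, pd.Series]:
    if matrix.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    logx = np.log2(matrix.to_numpy(dtype=float) + 1.0)
    mean = logx.mean(axis=1, keepdims=True)
    sd = logx.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (logx - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return z, pd.Series(mean.ravel(), index=matrix.index)


def cluster_expression(matrix: pd.DataFrame, k: int = 10, seed: int = 0,
                       n_restarts: int = 10) -> ClusterReport:
    """Best-of-``n_restarts`` k-means on the z-scored log expression.

    Constant gene rows become zero vectors rather than being dropped.
    Deterministic for a fixed seed.
    """
    if k > len(matrix):
        raise ValueError("k exceeds the number of genes")
    z, gene_means = _preprocess(matrix)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(z)
    assignments = pd.Series(labels, index=matrix.index, name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_, columns=matrix.columns,
                             index=pd.RangeIndex(k, name="cluster"))
    cluster_means = pd.Series(
        [gene_means[labels == c].mean() if (labels == c).any() else 0.0
         for c in range(k)],
        index=centroids.index, name="mean_log2_expression")
    return ClusterReport(assignments, centroids, gene_means, cluster_means,
                         float(km.inertia_))


def tissue_specific_clusters(report: ClusterReport,
                             fold: float = 2.0) -> pd.DataFrame:
    """Flag cluster/tissue pairs where the centroid deviates from its mean
    by more than ``fold`` standard deviations (sample sd across tissues).

    Flags are +1 (high in the tissue) or -1 (low); a flat centroid has
    sd = 0 and, with the strict comparison, is never flagged.  The result
    is also stored on the report.
    """
    c = report.centroids.to_numpy(dtype=float)
    mean = c.mean(axis=1, keepdims=True)
    sd = c.std(axis=1, ddof=1, keepdims=True)
    dev = c - mean
    with np.errstate(invalid="ignore"):
        hit = np.abs(dev) > fold * sd
    flags = np.where(hit, np.sign(dev).astype(int), 0)
    out = pd.DataFrame(flags, index=report.centroids.index,
                       columns=report.centroids.columns)
    report.tissue_specific = out
    return out


def drop_low_expression(report: ClusterReport,
                        quantile: float = 0.1) -> ClusterReport:
    """Flag clusters whose mean member expression (log2 scale, before
    z-scoring) falls below the given quantile of per-gene means.

    Flagged clusters stay in the report but are excluded from
    :meth:`ClusterReport.tissue_specific_genes`.
    """
    threshold = float(report.gene_means.quantile(quantile))
    report.low_expression = report.cluster_means < threshold
    return report
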