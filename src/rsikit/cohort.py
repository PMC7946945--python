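"""Comparing model-system expression with a patient-like cohort.

Selects the top differentially expressed genes of a contrast, merges model
and patient log-expression by quantile normalization, and asks which model
samples co-cluster with patients (hierarchical clustering on row z-scores),
with per-gene Mann-Whitney contrasts between sample groups.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy import stats
from sklearn.decomposition import PCA

from .containers import DEResult, ExpressionMatrix
from .preprocess import quantile_normalize, row_zscore

MW_EXACT_MAX = 8  # per-group size at or below which the exact branch is used


def select_top_genes(de: DEResult, n: int = 1000) -> list[str]:
    """Top ``n`` genes by ascending p-value (ties: descending |lfc|, then name)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(de.table):
        raise ValueError(f"requested {n} genes but the result has {len(de.table)}")
    ranking = de.table.assign(_abs_lfc=de.table["lfc"].abs(), _name=de.table.index)
    ranking = ranking.sort_values(
        by=["p_value", "_abs_lfc", "_name"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return ranking.index[:n].tolist()


def mann_whitney_contrast(
    merged: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U test per gene between two sample groups.

    Uses the exact null distribution when both groups have at most 8
    samples and the gene has no tied values, and the tie-corrected normal
    approximation otherwise.  Returns a DataFrame indexed by gene with
    columns U and p_value.
    """
    for name, grp in (("group_a", group_a), ("group_b", group_b)):
        missing = [s for s in grp if s not in merged.sample_ids]
        if missing:
            raise ValueError(f"{name} samples not in matrix: {missing}")
        if len(grp) < 2:
            raise ValueError(f"{name} must have at least 2 samples")
    xa = merged.values[list(group_a)].to_numpy()
    xb = merged.values[list(group_b)].to_numpy()
    exact_ok = xa.shape[1] <= MW_EXACT_MAX and xb.shape[1] <= MW_EXACT_MAX
    u = np.empty(xa.shape[0])
    p = np.empty(xa.shape[0])
    for i in range(xa.shape[0]):
        row = np.concatenate([xa[i], xb[i]])
        ties = np.unique(row).size < row.size
        method = "exact" if (exact_ok and not ties) else "asymptotic"
        res = stats.mannwhitneyu(xa[i], xb[i], alternative="two-sided", method=method)
        u[i], p[i] = res.statistic, res.pvalue
    return pd.DataFrame({"U": u, "p_value": p}, index=merged.gene_ids)


def pca_embed(expr: ExpressionMatrix, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on gene-centered expression.

    Returns (scores, explained_variance_fractions).  Sign convention: for
    each component the gene loading with the largest magnitude is positive.
    """
    x = expr.values.to_numpy(float).T  # samples x genes
    if x.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    if np.allclose(x, x[0]):
        raise ValueError("constant matrix has no principal components")
    n_components = min(n_components, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    cols = [f"PC{j + 1}" for j in range(n_components)]
    return (
        pd.DataFrame(scores, index=expr.sample_ids, columns=cols),
        pca.explained_variance_ratio_,
    )


@dataclass
class ClusterResult:
    """Average-linkage hierarchy over samples (or genes).

    ``linkage``: scipy linkage matrix; ``leaves``: item labels in dendrogram
    order; ``items``: labels in input order.
    """

    linkage: np.ndarray
    items: list[str]

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("linkage heights must be non-decreasing")

    @property
    def leaves(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.items[i] for i in order]

    def cut(self, n_clusters: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.items, name="cluster")


def hierarchical_cluster(
    expr: ExpressionMatrix,
    axis: str = "samples",
    method: str = "average",
    metric: str = "euclidean",
) -> ClusterResult:
    """Agglomerative clustering of samples (columns) or genes (rows)."""
    if axis == "samples":
        x = expr.values.to_numpy(float).T
        items = [str(s) for s in expr.sample_ids]
    elif axis == "genes":
        x = expr.values.to_numpy(float)
        items = [str(g) for g in expr.gene_ids]
    else:
        raise ValueError("axis must be 'samples' or 'genes'")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if not np.isfinite(x).all():
        raise ValueError("NaN or infinite values in clustering input")
    z = hierarchy.linkage(pdist(x, metric=metric), method=method)
    return ClusterResult(linkage=z, items=items)


@dataclass
class CohortReport:
    """Bundle produced by :func:`cohort_report`."""

    merged: ExpressionMatrix
    top_genes: list[str]
    clusters: ClusterResult
    cluster_labels: pd.Series
    mw_table: pd.DataFrame
    cohort_of: pd.Series  # per sample: "model" or "patient"


def cohort_report(
    model_expr: ExpressionMatrix,
    patient_expr: ExpressionMatrix,
    de: DEResult,
    n_top: int = 1000,
    n_clusters: int = 2,
) -> CohortReport:
    """Patient-similarity analysis on the top DE genes of a model contrast.

    Restricts the DE ranking to genes shared by both matrices, selects the
    top ``n_top``, quantile-normalizes the merged matrix, row-z-scores it,
    clusters samples (average linkage, Euclidean) and runs per-gene
    Mann-Whitney contrasts of patients vs model samples.
    """
    shared = model_expr.gene_ids.intersection(patient_expr.gene_ids).intersection(
        de.gene_ids
    )
    if len(shared) < n_top:
        raise ValueError(
            f"only {len(shared)} genes shared between model, cohort and DE result; "
            f"need at least n_top = {n_top}"
        )
    de_shared = DEResult(
        table=de.table.loc[shared], contrast=de.contrast, priors=de.priors
    )
    top = select_top_genes(de_shared, n=n_top)
    merged = quantile_normalize(
        [model_expr.subset_genes(top), patient_expr.subset_genes(top)]
    )
    z = row_zscore(merged)
    clusters = hierarchical_cluster(z, axis="samples")
    labels = clusters.cut(n_clusters)
    model_ids = [str(s) for s in model_expr.sample_ids]
    patient_ids = [str(s) for s in patient_expr.sample_ids]
    mw = mann_whitney_contrast(merged, patient_ids, model_ids)
    cohort_of = pd.Series(
        ["model"] * len(model_ids) + ["patient"] * len(patient_ids),
        index=model_ids + patient_ids,
        name="cohort",
    )
    return CohortReport(
        merged=merged,
        top_genes=top,
        clusters=clusters,
        cluster_labels=labels,
        mw_table=mw,
        cohort_of=cohort_of,
    )
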