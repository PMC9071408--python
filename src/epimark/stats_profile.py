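"""Unsupervised profiling of modification matrices: clustering, PCA, t-tests.

Mirrors a Perseus-style workflow on mean-scaled modification x sample
matrices: hierarchical clustering of rows and columns (for heatmap
ordering), k-means row labels (capped at 300 clusters), PCA with five
components, and per-modification two-sided Welch t-tests at alpha 0.01
without multiple-testing correction (Benjamini-Hochberg q-values are
reported as a supplementary column).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy import stats as sp_stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .iodata import STAGES, NormalizedMatrix
from .quantify import mean_scale

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "PCAResult",
    "TestResult",
    "K_MAX",
    "row_mean_normalize",
    "cluster_rows_cols",
    "cut_columns",
    "cluster_purity",
    "ensure_mean_scaled",
    "pca",
    "ttest_by_modification",
    "tissue_discrimination",
]

#: Hard cap on the number of k-means clusters.
K_MAX = 300


def row_mean_normalize(matrix: NormalizedMatrix) -> NormalizedMatrix:
    """Divide each row by its mean (shared implementation with quantify)."""
    return mean_scale(matrix)


def ensure_mean_scaled(matrix: NormalizedMatrix) -> NormalizedMatrix:
    """Return the matrix at the mean-scaled stage, re-basing if necessary.

    Matrices already in absolute units are treated as relative input for
    profiling (mean scaling is scale-invariant per row, so the result is
    identical either way); a provenance note records the re-basing.
    """
    if matrix.stage == "mean_scaled":
        return matrix
    if STAGES.index(matrix.stage) > STAGES.index("mean_scaled"):
        matrix = NormalizedMatrix(
            matrix.values, "uv_normalized",
            matrix.provenance + [f"re-based from {matrix.stage} for profiling"])
    return mean_scale(matrix)


@dataclass(frozen=True)
class ClusterResult:
    row_order: list[int]
    column_order: list[int]
    row_linkage: np.ndarray
    column_linkage: np.ndarray
    kmeans_labels: np.ndarray | None
    metric: str
    linkage_method: str

    def __post_init__(self):
        for order, n in ((self.row_order, self.row_linkage.shape[0] + 1),
                         (self.column_order, self.column_linkage.shape[0] + 1)):
            if sorted(order) != list(range(n)):
                raise ValueError("leaf order is not a permutation")
        if self.kmeans_labels is not None:
            k = int(self.kmeans_labels.max()) + 1
            if k > K_MAX:
                raise ValueError(f"k-means used {k} clusters, cap is {K_MAX}")


def _linkage(data: np.ndarray, method: str, metric: str) -> tuple[np.ndarray, str]:
    if metric == "correlation" and (np.ptp(data, axis=1) == 0).any():
        warnings.warn(
            "correlation metric undefined for constant vectors; "
            "falling back to euclidean", stacklevel=3,
        )
        metric = "euclidean"
    if method == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires the euclidean metric")
    return hierarchy.linkage(pdist(data, metric=metric), method=method), metric


def cluster_rows_cols(
    matrix: NormalizedMatrix | pd.DataFrame,
    linkage: str = "average",
    metric: str = "euclidean",
    k: int | None = None,
    seed: int = 0,
) -> ClusterResult:
    """Hierarchical clustering of both axes plus optional k-means row labels.

    Deterministic given ``seed``.  ``k`` (the k-means cluster count over
    rows) is chosen by the caller and capped at :data:`K_MAX`.
    """
    df = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    data = df.to_numpy(float)
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("clustering needs at least 2 rows and 2 columns")
    row_Z, row_metric = _linkage(data, linkage, metric)
    col_Z, _ = _linkage(data.T, linkage, metric)
    labels = None
    if k is not None:
        k = min(int(k), K_MAX, data.shape[0])
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(data)
    return ClusterResult(
        row_order=list(hierarchy.leaves_list(row_Z)),
        column_order=list(hierarchy.leaves_list(col_Z)),
        row_linkage=row_Z,
        column_linkage=col_Z,
        kmeans_labels=labels,
        metric=row_metric,
        linkage_method=linkage,
    )


def cut_columns(result: ClusterResult, n_clusters: int) -> np.ndarray:
    """Cut the column dendrogram into ``n_clusters`` flat clusters."""
    return hierarchy.fcluster(result.column_linkage, n_clusters, criterion="maxclust")


def cluster_purity(labels: Sequence, truth: Sequence) -> float:
    """Fraction of samples whose cluster's majority truth label matches theirs."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape != truth.shape:
        raise ValueError("labels and truth must align")
    correct = 0
    for c in np.unique(labels):
        members = truth[labels == c]
        _, counts = np.unique(members, return_counts=True)
        correct += counts.max()
    return correct / len(labels)


@dataclass(frozen=True)
class PCAResult:
    """Principal components of samples in modification space.

    ``scores`` are samples x components projections of the row-centered
    data; ``loadings`` (modifications x components) have orthonormal
    columns with the largest-magnitude loading of each component positive.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_fraction: np.ndarray

    def __post_init__(self):
        evf = self.explained_variance_fraction
        if np.any(np.diff(evf) > 1e-12) or evf.sum() > 1 + 1e-9:
            raise ValueError("explained fractions must be non-increasing with sum <= 1")


def pca(matrix: NormalizedMatrix | pd.DataFrame, n: int = 5) -> PCAResult:
    """PCA of the samples with modifications as features.

    Each modification row is centered across samples; components come from
    the SVD of the centered sample x modification data.  ``n`` is reduced
    with a warning when it exceeds what the data supports.
    """
    df = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    if df.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = df.to_numpy(float).T  # samples x modifications
    X = X - X.mean(axis=0, keepdims=True)
    max_n = min(X.shape[0] - 1, X.shape[1])
    if n > max_n:
        warnings.warn(f"PCA components reduced from {n} to {max_n}", stacklevel=2)
        n = max_n
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-magnitude loading per component positive
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    var = S**2
    total = var.sum()
    evf = var[:n] / total if total > 0 else np.zeros(n)
    comp_names = [f"PC{i + 1}" for i in range(n)]
    scores = pd.DataFrame(U[:, :n] * S[:n], index=df.columns, columns=comp_names)
    loadings = pd.DataFrame(Vt[:n].T, index=df.index, columns=comp_names)
    return PCAResult(scores, loadings, evf)


@dataclass(frozen=True)
class TestResult:
    modification: str
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    q_value: float
    significant: bool
    alpha: float
    skipped: bool = False
    reason: str = ""

    def __post_init__(self):
        if not self.skipped and self.significant != (self.p_value < self.alpha):
            raise ValueError("significant flag must equal (p < alpha)")


def ttest_by_modification(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    alpha: float = 0.01,
) -> list[TestResult]:
    """Two-sided Welch t-test per modification row between two sample groups.

    Rows with fewer than 3 replicates in either group are skipped and
    reported as such.  No multiple-testing correction gates significance
    (the raw alpha rule); BH q-values are attached for transparency.
    Identical zero-variance groups give p = 1.
    """
    common = [m for m in group_a.index if m in set(group_b.index)]
    prelim: list[tuple[str, float, float, float, float]] = []
    skipped: list[TestResult] = []
    for mod in common:
        a = group_a.loc[mod].to_numpy(float)
        b = group_b.loc[mod].to_numpy(float)
        if a.size < 3 or b.size < 3:
            skipped.append(TestResult(mod, float(np.mean(a)), float(np.mean(b)),
                                      float("nan"), float("nan"), float("nan"),
                                      False, alpha, skipped=True,
                                      reason=f"needs >= 3 replicates per group "
                                             f"(got {a.size}/{b.size})"))
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = sp_stats.ttest_ind(a, b, equal_var=False)
            if not np.isfinite(p):
                t_stat, p = 0.0, 1.0
        prelim.append((mod, float(np.mean(a)), float(np.mean(b)), float(t_stat), float(p)))
    results: list[TestResult] = []
    if prelim:
        pvals = [p for *_, p in prelim]
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for (mod, ma, mb, t_stat, p), q in zip(prelim, qvals):
            results.append(TestResult(mod, ma, mb, t_stat, p, float(q), p < alpha, alpha))
    return results + skipped


def tissue_discrimination(
    matrix: NormalizedMatrix,
    tissue_of: Mapping[str, str],
    exclude: Iterable[str] = ("m6,6A", "Am"),
    rows: Iterable[str] | None = None,
    linkage: str = "average",
    metric: str = "euclidean",
    n_pca: int = 3,
    n_permutations: int = 0,
    seed: int = 0,
) -> dict:
    """Unsupervised tissue separation on a (marker-free) modification matrix.

    The rRNA marker rows are removed (they report degradation, not tissue),
    rows are mean-scaled, columns are clustered hierarchically and cut at
    the number of tissues; reported purity is the majority-label agreement.
    With ``n_permutations`` > 0 a permutation null for purity is computed
    by shuffling tissue labels against the fixed clustering.
    """
    tissues = sorted({tissue_of[s] for s in matrix.samples})
    if len(tissues) < 2:
        raise ValueError("tissue discrimination needs >= 2 tissues")
    values = matrix.values.drop(index=[m for m in exclude if m in matrix.values.index])
    if rows is not None:
        keep = [m for m in values.index if m in set(rows)]
        values = values.loc[keep]
    work = ensure_mean_scaled(
        NormalizedMatrix(values, matrix.stage, matrix.provenance))
    clustering = cluster_rows_cols(work, linkage=linkage, metric=metric, seed=seed)
    flat = cut_columns(clustering, len(tissues))
    truth = np.array([tissue_of[s] for s in work.samples])
    purity = cluster_purity(flat, truth)
    scores = pca(work, n=n_pca)
    out = {
        "purity": purity,
        "cluster_labels": dict(zip(work.samples, (int(c) for c in flat))),
        "pca": scores,
        "clustering": clustering,
        "tissues": tissues,
    }
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            null[i] = cluster_purity(flat, rng.permutation(truth))
        out["null_purity"] = null
        out["null_quantile"] = float((null >= purity).mean())
    return out
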