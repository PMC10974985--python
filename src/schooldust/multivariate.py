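"""Source-identification statistics: correlation, PCA, HCA, k-means.

The multivariate tool-chain mirrors standard geochemical practice: z-score
standardisation (sample standard deviation, ddof=1), Pearson correlation,
PCA by singular value decomposition, agglomerative Ward/Euclidean
clustering, and multi-start k-means with elbow (WCSS) and silhouette model
selection.  Sites or elements can be clustered; clustering elements works
on the transposed standardised grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .datamodel import ConcentrationMatrix, ValidationError

__all__ = [
    "zscore_standardize",
    "pearson_matrix",
    "pca_decomposition",
    "hierarchical_cluster",
    "select_k",
    "kmeans_cluster",
    "PCAResult",
    "ClusteringResult",
    "KSelection",
]


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, ConcentrationMatrix):
        return matrix.data
    return pd.DataFrame(matrix)


def zscore_standardize(matrix) -> pd.DataFrame:
    """Column-wise z-scores: mean 0, sample (ddof=1) standard deviation 1."""
    df = _as_frame(matrix).astype(float)
    sd = df.std(ddof=1)
    constant = sd[~(sd > 0)].index.tolist()
    if constant:
        raise ValidationError(f"constant column(s), z-score undefined: {constant}")
    return (df - df.mean()) / sd


def pearson_matrix(matrix) -> pd.DataFrame:
    """Pearson product-moment correlation matrix over columns.

    Zero-variance columns yield NaN rows/columns (flagged undefined rather
    than raising, so a degenerate element does not hide the others).
    """
    df = _as_frame(matrix).astype(float)
    if df.shape[0] < 3:
        raise ValidationError("Pearson correlation needs at least 3 rows")
    corr = df.corr(method="pearson")
    # exact unit diagonal for defined columns
    defined = df.std(ddof=1) > 0
    for c in df.columns[defined]:
        corr.at[c, c] = 1.0
    return corr


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # component × variable, orthonormal rows
    scores: pd.DataFrame  # observation × component
    explained_variance_ratio: np.ndarray  # over all possible components

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratio)


def pca_decomposition(matrix, n_components: int | None = None) -> PCAResult:
    """PCA of a standardised grid via SVD.

    Components are ordered by decreasing variance; the sign of each
    component is fixed so its largest-magnitude loading is positive.
    ``explained_variance_ratio`` covers the full spectrum (sums to 1), while
    loadings/scores are truncated to ``n_components``.
    """
    df = _as_frame(matrix).astype(float)
    n, m = df.shape
    max_comp = min(n - 1, m)
    if n_components is None:
        n_components = max_comp
    if not 1 <= n_components <= max_comp:
        raise ValidationError(
            f"n_components must be in [1, {max_comp}] for a {n}x{m} matrix, "
            f"got {n_components}"
        )
    X = df.to_numpy() - df.to_numpy().mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else var
    comps = [f"PC{i + 1}" for i in range(n_components)]
    loadings = pd.DataFrame(Vt[:n_components], index=comps, columns=df.columns)
    scores = pd.DataFrame(
        (U[:, :n_components] * s[:n_components]), index=df.index, columns=comps
    )
    return PCAResult(loadings=loadings, scores=scores, explained_variance_ratio=ratio)


@dataclass
class ClusteringResult:
    mode: str  # "sites" | "elements"
    item_ids: list[str]
    linkage_matrix: np.ndarray  # scipy (n-1) × 4 merge table
    k_selected: int
    labels: pd.Series  # item -> cluster id in 1..k_selected

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for item, lab in self.labels.items():
            out.setdefault(int(lab), []).append(item)
        return out


def hierarchical_cluster(matrix, mode: str = "sites", n_clusters: int | None = None) -> ClusteringResult:
    """Agglomerative Ward/Euclidean clustering of rows (sites) or columns.

    ``mode='elements'`` clusters the transposed grid.  If ``n_clusters`` is
    not given it is chosen by silhouette over cuts k = 2..min(10, n-1).
    Merge heights under Ward are monotone non-decreasing.
    """
    df = _as_frame(matrix).astype(float)
    if mode == "elements":
        df = df.T
    elif mode != "sites":
        raise ValidationError(f"mode must be 'sites' or 'elements', got {mode!r}")
    items = [str(i) for i in df.index]
    n = len(items)
    if n < 2:
        raise ValidationError("clustering needs at least 2 items")
    Z = linkage(df.to_numpy(), method="ward", metric="euclidean")
    if n_clusters is None:
        best_k, best_sil = 2, -np.inf
        for k in range(2, min(10, n - 1) + 1):
            labs = fcluster(Z, t=k, criterion="maxclust")
            if len(np.unique(labs)) < 2:
                continue
            sil = silhouette_score(df.to_numpy(), labs)
            if sil > best_sil:
                best_k, best_sil = k, sil
        n_clusters = best_k
    if not 1 <= n_clusters <= n:
        raise ValidationError(f"n_clusters must be in [1, {n}], got {n_clusters}")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return ClusteringResult(
        mode=mode,
        item_ids=items,
        linkage_matrix=Z,
        k_selected=int(n_clusters),
        labels=pd.Series(labels, index=items, name="cluster"),
    )


@dataclass
class KSelection:
    k_selected: int
    wcss: pd.Series  # elbow curve, within-cluster sum of squares per k
    silhouette: pd.Series  # mean silhouette per k


def select_k(matrix, k_range=range(2, 11), seed: int = 0) -> KSelection:
    """Elbow (WCSS) and silhouette diagnostics over ``k_range``.

    The selected k is the silhouette argmax; the elbow curve is reported
    for inspection rather than auto-interpreted.
    """
    df = _as_frame(matrix).astype(float)
    X = df.to_numpy()
    n = X.shape[0]
    if np.allclose(X, X[0]):
        raise ValidationError("all points identical; cluster selection undefined")
    ks = [k for k in k_range]
    if not ks or min(ks) < 2 or max(ks) > n - 1:
        raise ValidationError(f"k_range must lie within [2, {n - 1}], got {ks}")
    wcss, sil = {}, {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        wcss[k] = float(km.inertia_)
        sil[k] = float(silhouette_score(X, km.labels_))
    sil_s = pd.Series(sil, name="silhouette")
    return KSelection(
        k_selected=int(sil_s.idxmax()),
        wcss=pd.Series(wcss, name="wcss"),
        silhouette=sil_s,
    )


def kmeans_cluster(matrix, k: int, seed: int = 0, n_restarts: int = 10) -> pd.Series:
    """Seeded multi-start Lloyd k-means; best-inertia labelling (1-based)."""
    df = _as_frame(matrix).astype(float)
    n = df.shape[0]
    if k < 1 or k > n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(df.to_numpy())
    return pd.Series(km.labels_ + 1, index=[str(i) for i in df.index], name="cluster")


def partitions_agree(a: pd.Series, b: pd.Series) -> bool:
    """True when two labelings induce the same partition (up to relabelling)."""
    a, b = a.sort_index(), b.sort_index()
    if not a.index.equals(b.index):
        raise ValidationError("labelings cover different items")
    mapping: dict[int, int] = {}
    seen: set[int] = set()
    for la, lb in zip(a, b):
        if la in mapping:
            if mapping[la] != lb:
                return False
        else:
            if lb in seen:
                return False
            mapping[la] = lb
            seen.add(lb)
    return True
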