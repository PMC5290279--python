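"""Robust cell-type identification by resampled consensus clustering.

The base operation projects cells onto the top principal components of
their log2(RPM+1) expression and agglomerates them (Ward linkage on
Euclidean distances by default).  Robustness is assessed by repeating
the whole procedure on random subsamples of the cells (default 100 runs
on 80% of the cells, PCA recomputed per subsample) and recording, for
every pair of cells, the proportion of runs in which both were drawn and
ended up in the same cluster — the stability score.  Hierarchical
clustering of the resulting dissimilarity (1 - stability, average
linkage) gives the final robust assignment and the leaf order used for
the consensus heatmap.

``suggest_k`` is advisory only: it scans k and reports the mean
silhouette on the stability dissimilarity, flagging "no structure" when
even the best k gives a weak silhouette (< 0.5 on the conventional
interpretation scale, where anything weaker counts as artificial or no
substantial structure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

__all__ = [
    "ClusteringParams",
    "StabilityMatrix",
    "ClusterAssignment",
    "KSuggestion",
    "pca_hclust",
    "stability_matrix",
    "consensus_assign",
    "suggest_k",
]

#: best silhouette below which the partition is flagged as no substantial
#: structure (values up to 0.5 are "weak, could be artificial" on the
#: standard silhouette interpretation scale)
NO_STRUCTURE_SILHOUETTE = 0.5


@dataclass(frozen=True)
class ClusteringParams:
    n_components: int = 10
    distance: str = "euclidean"
    linkage: str = "ward"
    k: int = 3
    n_runs: int = 100
    sample_fraction: float = 0.8
    seed: int = 0
    scale: bool = False  # variance-scale genes before PCA (centering always on)

    def validate(self) -> None:
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


@dataclass
class StabilityMatrix:
    """Pairwise co-clustering proportions over resampled runs.

    ``s[i, j]`` = co_clustered / co_sampled when the pair was drawn
    together at least once, NaN otherwise (``undefined`` marks those
    pairs); the diagonal is 1 by convention.
    """

    s: np.ndarray
    co_sampled: np.ndarray
    co_clustered: np.ndarray
    cell_ids: list[str]

    @property
    def undefined(self) -> np.ndarray:
        return self.co_sampled == 0

    @property
    def n_undefined_pairs(self) -> int:
        m = self.undefined.copy()
        np.fill_diagonal(m, False)
        return int(m.sum()) // 2


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per cell, contiguous 1..K
    leaf_order: np.ndarray  # permutation of cells for heatmap display
    k: int
    cell_ids: list[str]


@dataclass
class KSuggestion:
    k: int
    silhouettes: dict[int, float]
    has_structure: bool


def _pca_scores(X: np.ndarray, n_components: int) -> np.ndarray:
    n_max = min(X.shape[0] - 1, X.shape[1])
    if n_components > n_max:
        warnings.warn(
            f"n_components reduced from {n_components} to {n_max} "
            f"for a {X.shape[0]}x{X.shape[1]} matrix",
            stacklevel=3,
        )
        n_components = n_max
    return PCA(n_components=n_components, svd_solver="full").fit_transform(X)


def pca_hclust(X: np.ndarray, params: ClusteringParams) -> np.ndarray:
    """PCA projection followed by hierarchical clustering cut into k labels.

    ``X`` is cells x selected genes, already log-transformed.  Genes are
    centered (PCA), optionally variance-scaled.  Deterministic: scipy's
    agglomeration breaks equal-height ties by observation index.
    """
    params.validate()
    if X.shape[0] <= params.k:
        raise ValueError("need more cells than clusters")
    X = np.asarray(X, dtype=float)
    if params.scale:
        sd = X.std(axis=0)
        X = X / np.where(sd > 0, sd, 1.0)
    scores = _pca_scores(X, params.n_components)
    Z = sch.linkage(scores, method=params.linkage, metric=params.distance)
    return sch.fcluster(Z, t=params.k, criterion="maxclust")


def stability_matrix(X: np.ndarray, params: ClusteringParams,
                     cell_ids: list[str] | None = None) -> StabilityMatrix:
    """Co-clustering stability over resampled PCA + hierarchical runs.

    Each run draws ceil(sample_fraction * n) cells without replacement,
    recomputes the PCA on the subsample, clusters into k, and updates the
    pair counters.  The score divides by the number of runs in which both
    cells of a pair were drawn (co-membership is only observable then);
    pairs never co-sampled are flagged NaN, not silently zeroed.
    """
    params.validate()
    n = X.shape[0]
    cell_ids = list(cell_ids) if cell_ids is not None else [str(i) for i in range(n)]
    rng = np.random.default_rng(params.seed)
    m = int(np.ceil(params.sample_fraction * n))
    co_sampled = np.zeros((n, n), dtype=np.int64)
    co_clustered = np.zeros((n, n), dtype=np.int64)
    for _ in range(params.n_runs):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        labels = pca_hclust(X[idx], params)
        same = labels[:, None] == labels[None, :]
        co_sampled[np.ix_(idx, idx)] += 1
        co_clustered[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        s = co_clustered / co_sampled
    np.fill_diagonal(s, 1.0)
    return StabilityMatrix(s=s, co_sampled=co_sampled,
                           co_clustered=co_clustered, cell_ids=cell_ids)


def _consensus_linkage(sm: StabilityMatrix) -> np.ndarray:
    d = 1.0 - sm.s
    if np.isnan(d).any():
        # never-co-sampled pairs: impute with the mean defined dissimilarity
        fill = float(np.nanmean(d[~np.eye(d.shape[0], dtype=bool)]))
        d = np.where(np.isnan(d), fill, d)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return sch.linkage(squareform(d, checks=False), method="average")


def consensus_assign(sm: StabilityMatrix, k: int) -> ClusterAssignment:
    """Final robust assignment: cut the stability-dissimilarity hierarchy at k.

    Labels are renumbered contiguously 1..K in order of first appearance
    along the dendrogram leaf order, which is also returned for heatmap
    display.
    """
    n = sm.s.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of cells ({n})")
    if np.allclose(np.nan_to_num(sm.s, nan=1.0), 1.0):
        warnings.warn("degenerate stability matrix (all ones): partition is arbitrary")
    Z = _consensus_linkage(sm)
    raw = sch.fcluster(Z, t=k, criterion="maxclust")
    order = np.asarray(sch.leaves_list(Z))
    relabel: dict[int, int] = {}
    for i in order:
        if raw[i] not in relabel:
            relabel[raw[i]] = len(relabel) + 1
    labels = np.array([relabel[r] for r in raw])
    return ClusterAssignment(labels=labels, leaf_order=order,
                             k=int(labels.max()), cell_ids=sm.cell_ids)


def suggest_k(sm: StabilityMatrix, k_max: int = 8) -> KSuggestion:
    """Advisory k: argmax of mean silhouette on d = 1 - stability.

    Flags ``has_structure=False`` when the best silhouette is below
    0.5 — e.g. for data with no planted types, where resampled runs
    split cells inconsistently.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    d = 1.0 - sm.s
    if np.isnan(d).any():
        fill = float(np.nanmean(d[~np.eye(d.shape[0], dtype=bool)]))
        d = np.where(np.isnan(d), fill, d)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    Z = sch.linkage(squareform(d, checks=False), method="average")
    sil: dict[int, float] = {}
    for k in range(2, min(k_max, d.shape[0] - 1) + 1):
        labels = sch.fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            sil[k] = -1.0
            continue
        sil[k] = float(silhouette_score(d, labels, metric="precomputed"))
    best = max(sil, key=lambda k: (sil[k], -k))
    return KSuggestion(k=best, silhouettes=sil,
                       has_structure=sil[best] >= NO_STRUCTURE_SILHOUETTE)
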