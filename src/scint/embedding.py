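"""t-SNE embeddings for cross-stage visualization and subtype parcellation.

The main embedding (perplexity 30) places all cells of all stages in one
map so that cells of the same type identified independently at different
stages can be seen to co-locate.  Subtype analysis re-embeds the cells of
one main type at perplexity 4 and clusters the 2-D coordinates
hierarchically (Euclidean, average linkage).

"Spectral" initialization: the embedding starts from the top-2 principal
components (scaled to the conventional 1e-4 spread), which makes the
result reproducible given the seed and a canonical cell order — cells are
sorted by identifier internally, so permuting the input rows does not
change any cell's coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

__all__ = ["EmbeddingParams", "embed", "subtype_clusters"]


@dataclass(frozen=True)
class EmbeddingParams:
    perplexity: float = 30.0  # use 4 for within-type subtype analysis
    seed: int = 0
    n_iter: int = 1000

    def validate(self) -> None:
        if self.perplexity <= 0:
            raise ValueError("perplexity must be positive")
        if self.n_iter < 250:
            raise ValueError("n_iter must be >= 250")


def embed(X: np.ndarray, cell_ids: list[str], params: EmbeddingParams | None = None) -> pd.DataFrame:
    """2-D t-SNE of cells; returns a (tsne1, tsne2) frame indexed by cell id.

    Requires at least 3x perplexity cells.  Coordinates are returned in
    the input cell order but computed in canonical (sorted-id) order, so
    they are a function of the (cell, profile) set, not of row order.
    """
    params = params or EmbeddingParams()
    params.validate()
    X = np.asarray(X, dtype=float)
    if len(cell_ids) != X.shape[0]:
        raise ValueError("one id per row required")
    if X.shape[0] < 3 * params.perplexity:
        raise ValueError(
            f"perplexity {params.perplexity} needs >= {int(3 * params.perplexity)} cells, "
            f"got {X.shape[0]}"
        )
    order = np.argsort(np.asarray(cell_ids, dtype=object))
    Xc = X[order]
    pca2 = PCA(n_components=2, svd_solver="full").fit_transform(Xc)
    sd = pca2[:, 0].std()
    init = pca2 / (sd if sd > 0 else 1.0) * 1e-4
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        coords = TSNE(
            n_components=2,
            perplexity=params.perplexity,
            init=init,
            random_state=params.seed,
            max_iter=params.n_iter,
        ).fit_transform(Xc)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("t-SNE produced non-finite coordinates")
    out = pd.DataFrame(coords, columns=["tsne1", "tsne2"],
                       index=pd.Index(np.asarray(cell_ids, dtype=object)[order], name="cell_id"))
    return out.loc[list(cell_ids)]


def subtype_clusters(coords: pd.DataFrame | np.ndarray, k_sub: int) -> np.ndarray:
    """Agglomerative clustering of t-SNE coordinates into k_sub subtypes.

    Average linkage on Euclidean distances in the 2-D embedding, labels
    contiguous from 1.  Identical coordinates collapse to zero-height
    merges (degenerate warning, single effective cluster).
    """
    if k_sub < 1:
        raise ValueError("k_sub must be >= 1")
    P = coords.to_numpy() if isinstance(coords, pd.DataFrame) else np.asarray(coords, dtype=float)
    n = P.shape[0]
    if k_sub > n:
        raise ValueError(f"k_sub={k_sub} exceeds the number of cells ({n})")
    if np.allclose(P, P[0]):
        warnings.warn("all embedding points identical: single effective cluster")
        return np.ones(n, dtype=int)
    Z = sch.linkage(P, method="average", metric="euclidean")
    raw = sch.fcluster(Z, t=k_sub, criterion="maxclust")
    _, labels = np.unique(raw, return_inverse=True)
    return labels + 1
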