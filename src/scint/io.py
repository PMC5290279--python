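"""Plain-text I/O: MatrixMarket counts + TSV metadata, tracks, DE tables."""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "write_counts",
    "read_counts",
    "write_tracks",
    "read_tracks",
    "write_reference_de",
    "read_reference_de",
]

_META_COLS = ["stage", "read_pairs", "frac_mapped", "frac_mito", "egfp_reads", "mapped_reads"]


def write_counts(adata: ad.AnnData, outdir: str | Path) -> Path:
    """Write matrix.mtx (genes x cells), genes.tsv, barcodes.tsv, meta.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sparse.csr_matrix(np.asarray(adata.X).T)  # genes x cells, CellRanger-style
    spio.mmwrite(str(outdir / "matrix.mtx"), X, field="integer")
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    meta = adata.obs[[c for c in _META_COLS if c in adata.obs.columns]].copy()
    meta.insert(0, "cell_id", adata.obs_names)
    meta.to_csv(outdir / "meta.tsv", sep="\t", index=False)
    return outdir


def read_counts(indir: str | Path) -> ad.AnnData:
    indir = Path(indir)
    X = spio.mmread(str(indir / "matrix.mtx")).toarray().T  # back to cells x genes
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    adata = ad.AnnData(
        X=np.asarray(X, dtype=np.int64),
        obs=pd.DataFrame(index=pd.Index(cells, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    meta_path = indir / "meta.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t").set_index("cell_id")
        adata.obs = adata.obs.join(meta)
    return adata


def write_tracks(tracks, path: str | Path) -> Path:
    from .migration import tracks_to_frame

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tracks_to_frame(tracks).to_csv(path, sep="\t", index=False)
    return path


def read_tracks(path: str | Path):
    from .migration import tracks_from_frame

    return tracks_from_frame(pd.read_csv(path, sep="\t"))


def write_reference_de(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_reference_de(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "z_score", "family"}
    if not required.issubset(df.columns):
        raise ValueError(f"reference DE table needs columns {sorted(required)}")
    return df
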