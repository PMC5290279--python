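"""RPM normalization and expressed-gene selection.

Counts are normalized to reads per million: count / mapped reads * 1e6,
per cell.  Clustering input is then restricted to genes expressed above
``rpm_threshold`` (strictly) in more than ``min_cell_fraction`` of the
cells (strictly), the filter applied independently within each analysis
subset (per stage for within-stage clustering).  The downstream log
transform is log2(RPM + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np

__all__ = ["FeatureSelectionParams", "to_rpm", "log_rpm", "select_genes"]


@dataclass(frozen=True)
class FeatureSelectionParams:
    rpm_threshold: float = 10.0
    min_cell_fraction: float = 0.05

    def validate(self) -> None:
        if self.rpm_threshold < 0 or self.min_cell_fraction < 0:
            raise ValueError("selection thresholds must be nonnegative")


def to_rpm(adata: ad.AnnData, mapped_key: str = "mapped_reads") -> ad.AnnData:
    """Add an ``rpm`` layer: counts * (1e6 / mapped reads), per cell.

    Raises a degenerate-cell error naming the first cell whose mapped-read
    count is zero.  Returns the same AnnData for chaining.
    """
    mapped = np.asarray(adata.obs[mapped_key], dtype=float)
    if np.any(mapped <= 0):
        bad = adata.obs_names[int(np.argmax(mapped <= 0))]
        raise ValueError(f"degenerate cell '{bad}': mapped_reads must be > 0")
    adata.layers["rpm"] = np.asarray(adata.X, dtype=float) / mapped[:, None] * 1.0e6
    return adata


def log_rpm(adata: ad.AnnData) -> ad.AnnData:
    """Add a ``log_rpm`` layer: log2(RPM + 1)."""
    if "rpm" not in adata.layers:
        to_rpm(adata)
    adata.layers["log_rpm"] = np.log2(adata.layers["rpm"] + 1.0)
    return adata


def select_genes(
    adata: ad.AnnData,
    params: FeatureSelectionParams | None = None,
    layer: str = "rpm",
) -> list[str]:
    """Genes expressed above the RPM threshold in more than the given cell fraction.

    Both inequalities are strict: a gene at exactly 10 RPM does not count
    as expressed, and expression in exactly 5% of cells does not qualify.
    Result is invariant to cell and gene order.
    """
    params = params or FeatureSelectionParams()
    params.validate()
    if adata.n_obs == 0:
        raise ValueError("empty matrix: no cells to select genes from")
    if layer not in adata.layers:
        to_rpm(adata)
    rpm = np.asarray(adata.layers[layer])
    frac = (rpm > params.rpm_threshold).mean(axis=0)
    keep = frac > params.min_cell_fraction
    return [g for g, k in zip(adata.var_names, keep) if k]
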