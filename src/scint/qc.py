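"""Per-cell quality control.

Five criteria, applied to the raw counts and the per-cell sequencing
metadata before any normalization:

1. at least 5 million read-pairs sequenced (``read_pairs >= min_read_pairs``),
2. more than 80% of read-pairs mapped (``frac_mapped > min_frac_mapped``),
3. less than 5% of reads on the mitochondrial chromosome
   (``frac_mito < max_frac_mito``),
4. at least one read aligned to the eGFP reporter
   (``egfp_reads >= min_egfp_reads``),
5. at least ten raw reads on at least one interneuron identity marker
   (Dlx1/2/5/6, Gad1/2 by default).

Inequality strictness follows the wording literally: "at least" is
inclusive, "more than"/"less than" are strict, so a cell at exactly 5%
mitochondrial reads fails.  ``frac_mito`` and ``frac_mapped`` are metadata
fields recorded upstream, not recomputed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

__all__ = ["QCThresholds", "QCReport", "apply_qc", "METADATA_COLUMNS"]

#: obs columns apply_qc expects on the AnnData
METADATA_COLUMNS = ("stage", "read_pairs", "frac_mapped", "frac_mito", "egfp_reads")


@dataclass(frozen=True)
class QCThresholds:
    min_read_pairs: int = 5_000_000
    min_frac_mapped: float = 0.80
    max_frac_mito: float = 0.05
    min_egfp_reads: int = 1
    marker_genes: tuple[str, ...] = ("Dlx1", "Dlx2", "Dlx5", "Dlx6", "Gad1", "Gad2")
    min_marker_reads: int = 10

    def validate(self) -> None:
        if min(self.min_read_pairs, self.min_frac_mapped, self.max_frac_mito,
               self.min_egfp_reads, self.min_marker_reads) < 0:
            raise ValueError("QC thresholds must be nonnegative")
        if not self.marker_genes:
            raise ValueError("marker gene list must be nonempty")


@dataclass
class QCReport:
    """Pass/fail per cell with the named criteria each failing cell violated."""

    table: pd.DataFrame  # index cell_id; columns: pass (bool), failed_criteria (str, ';'-joined)
    survivors_by_stage: pd.Series
    n_pass: int
    n_total: int

    @property
    def pass_mask(self) -> np.ndarray:
        return self.table["pass"].to_numpy()

    def failed(self, cell_id: str) -> list[str]:
        s = self.table.loc[cell_id, "failed_criteria"]
        return s.split(";") if s else []


def apply_qc(adata: ad.AnnData, thresholds: QCThresholds | None = None) -> QCReport:
    """Evaluate the five QC criteria on every cell.

    A cell passes iff no criterion fails.  Marker genes missing from the
    matrix contribute zero reads.  Raises on an empty cell list or on
    metadata columns missing from ``adata.obs``.
    """
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    if adata.n_obs == 0:
        raise ValueError("empty cell list: nothing to QC")
    missing = [c for c in METADATA_COLUMNS if c not in adata.obs.columns]
    if missing:
        raise ValueError(f"metadata/counts mismatch: obs lacks columns {missing}")

    obs = adata.obs
    X = np.asarray(adata.X)
    present = [g for g in thresholds.marker_genes if g in adata.var_names]
    if present:
        marker_max = X[:, [adata.var_names.get_loc(g) for g in present]].max(axis=1)
    else:
        marker_max = np.zeros(adata.n_obs)

    checks = {
        "min_read_pairs": obs["read_pairs"].to_numpy() >= thresholds.min_read_pairs,
        "min_frac_mapped": obs["frac_mapped"].to_numpy() > thresholds.min_frac_mapped,
        "max_frac_mito": obs["frac_mito"].to_numpy() < thresholds.max_frac_mito,
        "min_egfp_reads": obs["egfp_reads"].to_numpy() >= thresholds.min_egfp_reads,
        "min_marker_reads": marker_max >= thresholds.min_marker_reads,
    }
    ok = np.logical_and.reduce(list(checks.values()))
    failed = [
        ";".join(name for name, passed in checks.items() if not passed[i])
        for i in range(adata.n_obs)
    ]
    table = pd.DataFrame({"pass": ok, "failed_criteria": failed}, index=adata.obs_names)
    survivors = obs.loc[ok].groupby("stage", observed=False).size()
    return QCReport(table=table, survivors_by_stage=survivors,
                    n_pass=int(ok.sum()), n_total=adata.n_obs)
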