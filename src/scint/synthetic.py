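"""Synthetic single-cell data with known ground truth.

Emulates the experimental design the pipeline was built for: Htr3a-GFP+
cortical interneurons captured at three developmental stages (E18, P2, P5),
with a small number of transcriptionally distinct cell types planted as
disjoint marker-gene sets at a fixed log2 fold change.  Counts are negative
binomial with a mean-dependent dropout (logistic in log mean) layered on
top, the standard emulation of detection failure in full-length single-cell
protocols.  Per-cell QC metadata (sequencing depth, mapped fraction,
mitochondrial fraction, eGFP reads) are drawn consistent with QC pass,
except for a controlled fraction of cells that each violate exactly one
named criterion.

Also provides reference differential-expression tables with a controlled
gene overlap (for the shared-enrichment comparison) and correlated-random-
walk migration tracks with tunable directional persistence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy.special import expit

from .migration import Track

__all__ = [
    "SyntheticParams",
    "TrackParams",
    "GroundTruth",
    "IN_IDENTITY_MARKERS",
    "QC_CRITERIA",
    "generate_counts",
    "generate_reference_de",
    "generate_tracks",
    "generate_two_group_tracks",
]

#: Interneuron-identity transcripts every real cell is expected to express;
#: the first genes of every synthetic matrix carry these names so the QC
#: marker criterion is exercised end-to-end.
IN_IDENTITY_MARKERS = ("Dlx1", "Dlx2", "Dlx5", "Dlx6", "Gad1", "Gad2")

#: Named QC criteria a planted failing cell can violate (exactly one each).
QC_CRITERIA = (
    "min_read_pairs",
    "min_frac_mapped",
    "max_frac_mito",
    "min_egfp_reads",
    "min_marker_reads",
)


@dataclass(frozen=True)
class SyntheticParams:
    """Design of a planted-type count matrix.

    Defaults mirror the study layout: 3 types x 3 stages, 25 cells per
    type per stage, 2,000 genes with 50 markers per type at log2FC 3,
    and an ~8% QC failure rate (243 captured -> 223 passing in the
    cohort this emulates).
    """

    n_genes: int = 2000
    cells_per_type_per_stage: int = 25
    n_types: int = 3
    n_stages: int = 3
    stage_labels: tuple[str, ...] = ("E18", "P2", "P5")
    markers_per_type: int = 50
    marker_log2fc: float = 3.0
    #: natural-log range of the baseline NB mean per gene
    baseline_mean_log_range: tuple[float, float] = (0.0, 4.0)
    #: NB size parameter (smaller = more overdispersed)
    dispersion: float = 1.0
    #: expression level at which dropout probability is 0.5
    dropout_midpoint: float = 8.0
    dropout_slope: float = 1.0
    qc_fail_fraction: float = 0.08
    #: optional per-stage multiplicative drift: chosen genes get their mean
    #: scaled by 2**(stage_log2fc * stage_index); off by default
    stage_log2fc: float = 0.0
    stage_effect_gene_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_types < 1:
            raise ValueError("n_types must be >= 1")
        if self.n_genes < 1 or self.cells_per_type_per_stage < 1:
            raise ValueError("n_genes and cells_per_type_per_stage must be positive")
        if self.n_stages < 1 or len(self.stage_labels) < self.n_stages:
            raise ValueError("need a stage label for each stage")
        if self.markers_per_type < 0:
            raise ValueError("markers_per_type must be >= 0")
        if self.n_types * self.markers_per_type > self.n_genes - len(IN_IDENTITY_MARKERS):
            raise ValueError("not enough genes for disjoint marker sets")
        if self.dispersion <= 0 or self.dropout_midpoint <= 0:
            raise ValueError("dispersion and dropout_midpoint must be positive")
        if not 0.0 <= self.qc_fail_fraction <= 1.0:
            raise ValueError("qc_fail_fraction must lie in [0, 1]")
        lo, hi = self.baseline_mean_log_range
        if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
            raise ValueError("baseline_mean_log_range must be a finite (lo, hi)")


@dataclass(frozen=True)
class TrackParams:
    """Correlated-random-walk migration tracks.

    ``dt`` defaults to the 10-minute frame interval of the time-lapse
    movies the track analysis expects; ``turning_concentration`` is the
    von Mises kappa of the per-step turning angle (0 = isotropic walk,
    large = nearly straight).
    """

    n_tracks: int = 50
    n_steps: int = 49  # samples; 49 samples @ 10 min span the 8 h analysis window
    dt: float = 10.0  # minutes
    step_length_mean: float = 10.0  # micrometres per frame
    turning_concentration: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        if self.step_length_mean < 0 or self.turning_concentration < 0:
            raise ValueError("step_length_mean and turning_concentration must be >= 0")


@dataclass
class GroundTruth:
    """Planted truth accompanying a synthetic count matrix."""

    type_labels: pd.Series  # cell_id -> planted type (1..K)
    stage_labels: pd.Series  # cell_id -> stage
    marker_map: dict[str, int]  # marker gene -> type it marks
    log2fc: pd.DataFrame  # genes x types, true log2 fold change vs baseline
    qc_should_fail: pd.Series  # cell_id -> bool
    qc_fail_criterion: pd.Series  # cell_id -> criterion name or ""

    def markers_of(self, type_label: int) -> list[str]:
        return [g for g, t in self.marker_map.items() if t == type_label]


def dropout_probability(mean: np.ndarray, midpoint: float, slope: float) -> np.ndarray:
    """P(detection failure) for a transcript with NB mean ``mean``."""
    mean = np.asarray(mean, dtype=float)
    with np.errstate(divide="ignore"):
        logm = np.log(np.maximum(mean, np.finfo(float).tiny))
    p = expit(-slope * (logm - math.log(midpoint)))
    return np.where(mean > 0, p, 0.0)


def generate_counts(params: SyntheticParams) -> tuple[ad.AnnData, GroundTruth]:
    """Draw a planted-type count matrix with QC metadata and ground truth.

    Returns an AnnData (cells x genes, integer counts in ``X``) whose
    ``obs`` carries the QC metadata columns (stage, read_pairs,
    frac_mapped, frac_mito, egfp_reads, mapped_reads) and a
    :class:`GroundTruth`.  ``obs['mapped_reads']`` equals the column sum
    of the counts ("reads aligned to expressed genes") and is the RPM
    denominator downstream.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    n_id = len(IN_IDENTITY_MARKERS)
    gene_names = list(IN_IDENTITY_MARKERS) + [
        f"G{i:05d}" for i in range(params.n_genes - n_id)
    ]
    stages = list(params.stage_labels[: params.n_stages])
    n_cells = params.n_types * params.n_stages * params.cells_per_type_per_stage
    cell_ids = [f"C{i:04d}" for i in range(n_cells)]

    cell_type = np.empty(n_cells, dtype=int)
    cell_stage = np.empty(n_cells, dtype=object)
    i = 0
    for s in stages:
        for t in range(1, params.n_types + 1):
            for _ in range(params.cells_per_type_per_stage):
                cell_type[i] = t
                cell_stage[i] = s
                i += 1

    lo, hi = params.baseline_mean_log_range
    base_mean = np.exp(rng.uniform(lo, hi, size=params.n_genes))
    # identity markers are robustly expressed so the QC marker criterion
    # passes unless deliberately violated
    base_mean[:n_id] = rng.uniform(100.0, 300.0, size=n_id)

    # disjoint marker blocks, drawn after the identity genes
    marker_pool = rng.permutation(np.arange(n_id, params.n_genes))
    marker_map: dict[str, int] = {}
    log2fc = np.zeros((params.n_genes, params.n_types))
    for t in range(1, params.n_types + 1):
        block = marker_pool[(t - 1) * params.markers_per_type : t * params.markers_per_type]
        log2fc[block, t - 1] = params.marker_log2fc
        for g in block:
            marker_map[gene_names[g]] = t

    stage_genes = np.array([], dtype=int)
    if params.stage_log2fc != 0.0:
        n_drift = int(round(params.stage_effect_gene_fraction * params.n_genes))
        stage_genes = rng.choice(
            np.arange(n_id, params.n_genes), size=n_drift, replace=False
        )

    mean = np.tile(base_mean[:, None], (1, n_cells))
    for t in range(1, params.n_types + 1):
        cols = cell_type == t
        mean[:, cols] *= 2.0 ** log2fc[:, [t - 1]]
    if stage_genes.size:
        for k, s in enumerate(stages):
            cols = cell_stage == s
            mean[np.ix_(stage_genes, cols)] *= 2.0 ** (params.stage_log2fc * k)

    theta = params.dispersion
    p_nb = theta / (theta + mean)
    counts = rng.negative_binomial(theta, p_nb)
    drop_p = dropout_probability(mean, params.dropout_midpoint, params.dropout_slope)
    counts = np.where(rng.random(mean.shape) < drop_p, 0, counts)

    # planted QC failures: exactly round(fraction * n) cells, one criterion each
    n_fail = int(round(params.qc_fail_fraction * n_cells))
    fail_cells = rng.choice(n_cells, size=n_fail, replace=False)
    fail_criterion = np.full(n_cells, "", dtype=object)
    for j, c in enumerate(np.sort(fail_cells)):
        fail_criterion[c] = QC_CRITERIA[j % len(QC_CRITERIA)]

    read_pairs = rng.lognormal(math.log(1.0e7), 0.15, size=n_cells)
    read_pairs = np.maximum(read_pairs, 5.5e6).astype(np.int64)
    frac_mapped = rng.uniform(0.82, 0.95, size=n_cells)
    frac_mito = rng.uniform(0.002, 0.04, size=n_cells)
    egfp_reads = rng.poisson(50.0, size=n_cells) + 1

    id_rows = np.arange(n_id)
    for c in range(n_cells):
        crit = fail_criterion[c]
        if crit == "min_read_pairs":
            read_pairs[c] = int(4.0e6)
        elif crit == "min_frac_mapped":
            frac_mapped[c] = 0.70
        elif crit == "max_frac_mito":
            frac_mito[c] = 0.09
        elif crit == "min_egfp_reads":
            egfp_reads[c] = 0
        elif crit == "min_marker_reads":
            counts[id_rows, c] = 0

    mapped_reads = counts.sum(axis=0).astype(np.int64)

    obs = pd.DataFrame(
        {
            "stage": pd.Categorical(cell_stage, categories=stages),
            "read_pairs": read_pairs,
            "frac_mapped": frac_mapped,
            "frac_mito": frac_mito,
            "egfp_reads": egfp_reads,
            "mapped_reads": mapped_reads,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    adata = ad.AnnData(
        X=counts.T.astype(np.int64),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(gene_names, name="gene")),
    )
    adata.uns["synthetic_params"] = {
        "dispersion": theta,
        "dropout_midpoint": params.dropout_midpoint,
        "dropout_slope": params.dropout_slope,
        "marker_log2fc": params.marker_log2fc,
        "seed": params.seed,
    }

    truth = GroundTruth(
        type_labels=pd.Series(cell_type, index=adata.obs_names, name="true_type"),
        stage_labels=pd.Series(cell_stage, index=adata.obs_names, name="stage"),
        marker_map=marker_map,
        log2fc=pd.DataFrame(
            log2fc, index=gene_names, columns=[t + 1 for t in range(params.n_types)]
        ),
        qc_should_fail=pd.Series(
            fail_criterion != "", index=adata.obs_names, name="qc_should_fail"
        ),
        qc_fail_criterion=pd.Series(
            fail_criterion, index=adata.obs_names, name="qc_fail_criterion"
        ),
    )
    return adata, truth


def generate_reference_de(
    n_genes: int,
    shared_genes: list[str] | tuple[str, ...],
    z_shared: float | tuple[float, float] | np.ndarray,
    seed: int,
    family: str = "Reln-like",
    z_background: tuple[float, float] = (0.0, 1.0),
    gene_prefix: str = "R",
) -> pd.DataFrame:
    """Reference subtype DE table with a controlled query-gene overlap.

    ``shared_genes`` appear in the table with Z-scores given by
    ``z_shared`` (a constant, a (mean, sd) pair, or one value per gene);
    ``n_genes`` additional background genes get Z ~ Normal(*z_background*).
    Shape matches the extracted grey-matter Reln-/Vip-subtype tables the
    cross-reference module consumes: one (gene, z_score, family) row each.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    shared = list(dict.fromkeys(shared_genes))
    if len(shared) != len(list(shared_genes)):
        raise ValueError("shared_genes contains duplicates")
    rng = np.random.default_rng(seed)

    if isinstance(z_shared, tuple):
        z_sh = rng.normal(z_shared[0], z_shared[1], size=len(shared))
    else:
        z_sh = np.broadcast_to(np.asarray(z_shared, dtype=float), (len(shared),)).copy()
    if z_sh.shape != (len(shared),):
        raise ValueError("z_shared must broadcast to one value per shared gene")

    bg_names = [f"{gene_prefix}{i:05d}" for i in range(n_genes)]
    taken = {g.upper() for g in shared}
    bg_names = [g for g in bg_names if g.upper() not in taken]
    z_bg = rng.normal(z_background[0], z_background[1], size=len(bg_names))

    return pd.DataFrame(
        {
            "gene": shared + bg_names,
            "z_score": np.concatenate([z_sh, z_bg]),
            "family": family,
        }
    )


def generate_tracks(params: TrackParams, group: str = "", id_prefix: str = "T") -> list[Track]:
    """Correlated random walks sampled every ``dt`` minutes.

    Turning angles are von Mises(0, kappa=turning_concentration); kappa=0
    gives an isotropic walk, large kappa a nearly straight path.  Step
    lengths are gamma-distributed with the requested mean (shape 4).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    tracks: list[Track] = []
    n_disp = params.n_steps - 1  # displacement steps between samples
    t = np.arange(params.n_steps) * params.dt
    for i in range(params.n_tracks):
        heading0 = rng.uniform(-math.pi, math.pi)
        if params.turning_concentration == 0:
            turns = rng.uniform(-math.pi, math.pi, size=n_disp)
        else:
            turns = rng.vonmises(0.0, params.turning_concentration, size=n_disp)
        headings = heading0 + np.cumsum(turns)
        if params.step_length_mean == 0:
            steps = np.zeros(n_disp)
        else:
            steps = rng.gamma(4.0, params.step_length_mean / 4.0, size=n_disp)
        x = np.concatenate([[0.0], np.cumsum(steps * np.cos(headings))])
        y = np.concatenate([[0.0], np.cumsum(steps * np.sin(headings))])
        tracks.append(Track(track_id=f"{id_prefix}{i:04d}", t=t.copy(), x=x, y=y, group=group))
    return tracks


def generate_two_group_tracks(
    params_a: TrackParams,
    params_b: TrackParams,
    labels: tuple[str, str] = ("PSB", "CGE"),
) -> dict[str, list[Track]]:
    """Two graft-like groups of tracks (e.g. PSB vs CGE) in one call."""
    return {
        labels[0]: generate_tracks(params_a, group=labels[0], id_prefix=f"{labels[0]}-"),
        labels[1]: generate_tracks(params_b, group=labels[1], id_prefix=f"{labels[1]}-"),
    }
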