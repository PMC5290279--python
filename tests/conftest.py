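import numpy as np
import pytest

import scint
from scint.normalize import log_rpm, select_genes


@pytest.fixture(scope="session")
def study_scale():
    """Planted dataset at study scale: 3 types x 3 stages, 25 cells each,
    2,000 genes, 50 markers/type at log2FC 3."""
    params = scint.SyntheticParams(seed=3)
    adata, truth = scint.generate_counts(params)
    return params, adata, truth


@pytest.fixture(scope="session")
def qc_passed(study_scale):
    _, adata, truth = study_scale
    report = scint.apply_qc(adata)
    return adata[report.pass_mask].copy(), truth, report


def stage_matrix(adata, stage):
    """Log2(RPM+1) matrix of per-stage selected genes, plus cell ids."""
    sub = adata[adata.obs["stage"] == stage].copy()
    log_rpm(sub)
    genes = select_genes(sub)
    return np.asarray(sub[:, genes].layers["log_rpm"]), list(sub.obs_names)


@pytest.fixture(scope="session")
def small_planted():
    """Compact planted dataset for fast unit tests: 3 types, one stage."""
    params = scint.SyntheticParams(
        n_genes=500,
        cells_per_type_per_stage=20,
        n_stages=1,
        markers_per_type=30,
        qc_fail_fraction=0.0,
        seed=9,
    )
    adata, truth = scint.generate_counts(params)
    return params, adata, truth
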