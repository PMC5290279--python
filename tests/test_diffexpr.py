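"""ZINB error model and profile-likelihood differential expression."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

import scint
from scint.diffexpr import (
    EnrichmentCriteria,
    de_test,
    enriched_genes,
    fit_error_model,
    timecourse_expression,
    top_n_table,
)


def _manual_adata(X, mapped=None):
    n, g = X.shape
    mapped = mapped if mapped is not None else X.sum(axis=1)
    obs = pd.DataFrame({"mapped_reads": mapped}, index=[f"c{i}" for i in range(n)])
    return ad.AnnData(X=np.asarray(X, dtype=np.int64), obs=obs,
                      var=pd.DataFrame(index=[f"g{j}" for j in range(g)]))


class TestErrorModel:
    def test_dispersion_recovered_within_20_percent(self):
        true_theta = 1.0
        p = scint.SyntheticParams(n_genes=2000, cells_per_type_per_stage=34, n_types=1,
                                  n_stages=3, markers_per_type=0, dispersion=true_theta,
                                  qc_fail_fraction=0.0, seed=11)
        adata, _ = scint.generate_counts(p)  # 102 cells
        model = fit_error_model(adata, np.ones(adata.n_obs, dtype=bool))
        assert abs(model.theta - true_theta) / true_theta < 0.2

    def test_no_zeros_means_no_dropout(self):
        rng = np.random.default_rng(0)
        X = rng.integers(5, 50, size=(30, 100))
        model = fit_error_model(_manual_adata(X), np.ones(30, dtype=bool))
        assert model.dropout_prob(model.mu).max() < 0.01

    def test_constant_gene_mean_on_rpm_scale(self):
        X = np.full((20, 3), 10)
        X[:, 1] = 30
        X[:, 2] = 5
        adata = _manual_adata(X, mapped=np.full(20, 45))  # size factor 45e-6
        model = fit_error_model(adata, np.ones(20, dtype=bool))
        assert model.mu[0] == pytest.approx(10 / 45 * 1e6, rel=1e-6)

    def test_too_small_group_rejected(self):
        X = np.ones((4, 5), dtype=int)
        with pytest.raises(ValueError):
            fit_error_model(_manual_adata(X), np.ones(4, dtype=bool))


class TestDeTest:
    @pytest.fixture(scope="class")
    def planted_de(self):
        p = scint.SyntheticParams(n_genes=600, cells_per_type_per_stage=30, n_types=3,
                                  n_stages=1, markers_per_type=20, marker_log2fc=3.0,
                                  qc_fail_fraction=0.0, seed=6)
        adata, truth = scint.generate_counts(p)
        de = de_test(adata, truth.type_labels.to_numpy(), 1)
        return adata, truth, de

    def test_planted_markers_detected(self, planted_de):
        _, truth, de = planted_de
        markers = truth.markers_of(1)
        sets = enriched_genes(de)
        assert len(set(sets.up) & set(markers)) / len(markers) >= 0.8

    def test_marker_fold_change_near_truth(self, planted_de):
        _, truth, de = planted_de
        markers = truth.markers_of(1)
        assert abs(de.loc[markers, "mle_log2fc"].median() - 3.0) < 0.6

    def test_sign_consistency_and_finite_z(self, planted_de):
        _, _, de = planted_de
        assert np.isfinite(de["z_score"]).all()
        nz = de["mle_log2fc"] != 0
        assert (np.sign(de.loc[nz, "z_score"]) == np.sign(de.loc[nz, "mle_log2fc"])).all()

    def test_swap_negates_mle_and_z(self, planted_de):
        adata, truth, _ = planted_de
        sub = adata[:, :150].copy()
        labels = truth.type_labels.to_numpy()
        labels = np.where(labels == 1, 1, 2)  # two groups
        d12 = de_test(sub, labels, 1)
        d21 = de_test(sub, labels, 2)
        np.testing.assert_allclose(d12["mle_log2fc"], -d21["mle_log2fc"], atol=1e-9)
        np.testing.assert_allclose(d12["z_score"], -d21["z_score"], atol=1e-6)

    def test_all_zero_gene_flagged_uninformative(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 40, size=(30, 10))
        X[:, 4] = 0
        adata = _manual_adata(X, mapped=np.full(30, 1000))
        de = de_test(adata, np.repeat([1, 2], [10, 20]), 1)
        assert de.iloc[4]["mle_log2fc"] == 0
        assert de.iloc[4]["z_score"] == 0
        assert de.iloc[4]["flag"] == "uninformative"

    def test_scale_covariance(self):
        # doubling one group's means twice (2^2) shifts the median MLE by ~2
        rng = np.random.default_rng(8)
        mu = np.exp(rng.uniform(1, 4, size=200))
        theta = 2.0
        c = 2.0
        Xa = rng.negative_binomial(theta, theta / (theta + mu), size=(40, 200))
        Xb = rng.negative_binomial(theta, theta / (theta + mu * 2**c), size=(40, 200))
        X = np.vstack([Xa, Xb])
        adata = _manual_adata(X, mapped=np.full(80, 10_000))
        de = de_test(adata, np.repeat([1, 2], 40), 2)
        assert abs(de["mle_log2fc"].median() - c) < 0.35

    def test_small_groups_rejected(self):
        X = np.ones((8, 5), dtype=int)
        with pytest.raises(ValueError):
            de_test(_manual_adata(X), np.repeat([1, 2], 4), 1)


class TestEnrichmentRule:
    def _de(self, rows):
        return pd.DataFrame(rows, columns=["mle_log2fc", "z_score"],
                            index=[f"g{i}" for i in range(len(rows))])

    def test_inclusive_thresholds(self):
        de = self._de([[2.0, 2.0], [3.0, 1.5], [-2.0, -2.0], [1.9, 5.0]])
        sets = enriched_genes(de)
        assert sets.up == ["g0"]  # exactly at both thresholds -> included
        assert sets.down == ["g2"]

    def test_empty_table_gives_empty_sets(self):
        de = self._de([])
        sets = enriched_genes(de)
        assert sets.up == [] and sets.down == []

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            enriched_genes(self._de([]), EnrichmentCriteria(mle_threshold=0))


class TestTopN:
    def _de(self, n_enriched, n_other=10):
        rng = np.random.default_rng(0)
        mle = np.concatenate([rng.uniform(2, 6, n_enriched), rng.uniform(-1, 1, n_other)])
        z = np.concatenate([rng.uniform(2, 9, n_enriched), rng.uniform(-1, 1, n_other)])
        return pd.DataFrame({"mle_log2fc": mle, "z_score": z,
                             "adj_expr_target": 1.0, "adj_expr_rest": 1.0},
                            index=[f"g{i:03d}" for i in range(n_enriched + n_other)])

    def test_truncation_to_n(self):
        top = top_n_table(self._de(60), 50)
        assert len(top) == 50
        assert top.attrs["n_enriched"] == 60

    def test_fewer_than_n_returns_all(self):
        top = top_n_table(self._de(7), 50)
        assert len(top) == 7

    def test_deterministic_tie_break(self):
        de = pd.DataFrame(
            {"mle_log2fc": [2.5, 3.5, 3.5], "z_score": [4.0, 4.0, 4.0],
             "adj_expr_target": 1.0, "adj_expr_rest": 1.0},
            index=["gB", "gC", "gA"],
        )
        top = top_n_table(de, 3)
        assert list(top.index) == ["gA", "gC", "gB"]  # |mle| desc, then name

    def test_ranking_ordered_by_z(self):
        top = top_n_table(self._de(30), 30)
        assert (np.diff(top["z_score"]) <= 0).all()


class TestTimecourse:
    def test_absent_stage_flagged_not_interpolated(self):
        de = pd.DataFrame({"mle_log2fc": [3.0], "z_score": [4.0],
                           "adj_expr_target": [120.0], "adj_expr_rest": [10.0],
                           "flag": [""]}, index=["Meis2"])
        tc = timecourse_expression({"P2": de, "P5": de.drop(index=["Meis2"])}, "Meis2")
        assert tc.loc[tc["stage"] == "P2", "adj_expr"].iloc[0] == 120.0
        p5 = tc[tc["stage"] == "P5"].iloc[0]
        assert p5["adj_expr"] == 0.0 and p5["flag"] == "absent"

    def test_stage_constant_marker_trajectory_is_flat(self):
        # same planted fold change at all three stages -> near-constant estimates
        p = scint.SyntheticParams(n_genes=400, cells_per_type_per_stage=25, n_types=2,
                                  n_stages=3, markers_per_type=15, marker_log2fc=3.0,
                                  qc_fail_fraction=0.0, seed=19)
        adata, truth = scint.generate_counts(p)
        de_by_stage = {}
        for stage in ("E18", "P2", "P5"):
            sub = adata[adata.obs["stage"] == stage].copy()
            de_by_stage[stage] = de_test(sub, truth.type_labels.loc[sub.obs_names].to_numpy(), 1)
        gene = truth.markers_of(1)[0]
        tc = timecourse_expression(de_by_stage, gene)
        vals = tc["adj_expr"].to_numpy()
        assert (tc["flag"] == "").all()
        assert vals.max() / vals.min() < 2.0  # flat within sampling noise

    def test_stage_increasing_gene_monotone(self):
        p = scint.SyntheticParams(n_genes=400, cells_per_type_per_stage=25, n_types=2,
                                  n_stages=3, markers_per_type=10, marker_log2fc=3.0,
                                  stage_log2fc=1.5, stage_effect_gene_fraction=0.1,
                                  qc_fail_fraction=0.0, seed=29)
        adata, truth = scint.generate_counts(p)
        drifting = [g for g in adata.var_names
                    if g not in truth.marker_map and g.startswith("G")]
        # find genes actually planted with stage drift via empirical stage means
        X = np.asarray(adata.X, dtype=float)
        stages = truth.stage_labels
        de_by_stage = {}
        for stage in ("E18", "P2", "P5"):
            sub = adata[adata.obs["stage"] == stage].copy()
            de_by_stage[stage] = de_test(sub, truth.type_labels.loc[sub.obs_names].to_numpy(), 1)
        m_e18 = X[(stages == "E18").to_numpy()].mean(axis=0)
        m_p5 = X[(stages == "P5").to_numpy()].mean(axis=0)
        ratio = (m_p5 + 1) / (m_e18 + 1)
        gene = adata.var_names[int(np.argmax(ratio))]
        tc = timecourse_expression(de_by_stage, gene).set_index("stage")
        vals = tc.loc[["E18", "P2", "P5"], "adj_expr"].to_numpy()
        assert vals[0] < vals[1] < vals[2]
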