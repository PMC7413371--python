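"""Cis window selection, elastic-net training, filters, external validation."""

import numpy as np
import pandas as pd
import pytest

from methylwas import models, preprocess, synthio
from methylwas.models import TrainingConfig


def toy_panel(positions, chrom="chr1"):
    vt = pd.DataFrame({
        "chrom": chrom, "pos": positions,
        "id": [f"v{i}" for i in range(len(positions))],
        "effect_allele": "A", "other_allele": "G",
        "maf": 0.3, "imputation_quality": 1.0, "block": 0,
    })
    return synthio.GenotypePanel(["s"], vt, np.zeros((1, len(positions))), {0: 0.0})


class TestCisWindow:
    def test_boundary_inclusive_at_one_megabase(self):
        panel = toy_panel([1_000_000])
        assert len(models.select_cis_variants("chr1", 2_000_000, panel)) == 1

    def test_just_outside_excluded(self):
        panel = toy_panel([999_999])
        assert len(models.select_cis_variants("chr1", 2_000_000, panel)) == 0

    def test_other_chromosome_excluded(self):
        panel = toy_panel([2_000_000], chrom="chr2")
        assert len(models.select_cis_variants("chr1", 2_000_000, panel)) == 0


class TestTraining:
    @pytest.fixture(scope="class")
    def signal_fit(self):
        panel = synthio.simulate_genotypes(1200, [(20, 0.3)], seed=1)
        rng = np.random.default_rng(2)
        g = panel.dosages[:, 5]
        g = (g - g.mean()) / g.std() * np.sqrt(0.5)
        y = g + rng.normal(0, np.sqrt(0.5), panel.n_samples)
        cfg = TrainingConfig(seed=3)
        m = models.train_feature_model("cg_t", y, panel.dosages,
                                       panel.variant_table, cfg)
        return panel, y, cfg, m

    def test_recovers_causal_snp_and_r2(self, signal_fit):
        panel, y, cfg, m = signal_fit
        assert 0.3 < m.cv_r2 < 0.65
        top = m.weights.iloc[int(m.weights["weight"].abs().argmax())]
        assert top["variant_id"] == panel.variant_table["id"][5]

    def test_deterministic_under_seed(self, signal_fit):
        panel, y, cfg, m = signal_fit
        m2 = models.train_feature_model("cg_t", y, panel.dosages,
                                        panel.variant_table, cfg)
        assert m2.lambda_selected == m.lambda_selected
        assert np.array_equal(m2.weights["weight"], m.weights["weight"])
        assert m2.cv_r2 == m.cv_r2

    def test_cv_r2_affine_invariant(self, signal_fit):
        panel, y, cfg, m = signal_fit
        m2 = models.train_feature_model("cg_t", 3.0 * y - 7.0, panel.dosages,
                                        panel.variant_table, cfg)
        assert m2.cv_r2 == pytest.approx(m.cv_r2, abs=1e-10)

    def test_duplicate_causal_column_leaves_r2_stable(self, signal_fit):
        panel, y, cfg, m = signal_fit
        vt = pd.concat(
            [panel.variant_table,
             panel.variant_table.iloc[[5]].assign(id="v_dup")],
            ignore_index=True,
        )
        D = np.column_stack([panel.dosages, panel.dosages[:, 5]])
        m2 = models.train_feature_model("cg_t", y, D, vt, cfg)
        assert m2.cv_r2 == pytest.approx(m.cv_r2, abs=0.02)

    def test_pure_noise_yields_filtered_model(self):
        panel = synthio.simulate_genotypes(500, [(50, 0.4)], seed=4)
        rng = np.random.default_rng(5)
        m = models.train_feature_model("null", rng.standard_normal(500),
                                       panel.dosages, panel.variant_table,
                                       TrainingConfig(seed=6))
        assert m.cv_r2 < 0.05

    def test_r2_approaches_h2_with_sample_size(self):
        r2s = []
        for n in (500, 2000, 6000):
            panel = synthio.simulate_genotypes(n, [(15, 0.3)], seed=7)
            rng = np.random.default_rng(8)
            g = panel.dosages[:, 3]
            g = (g - g.mean()) / g.std() * np.sqrt(0.4)
            y = g + rng.normal(0, np.sqrt(0.6), n)
            m = models.train_feature_model("cg", y, panel.dosages,
                                           panel.variant_table,
                                           TrainingConfig(seed=9))
            r2s.append(m.cv_r2)
        assert r2s[0] < r2s[2] + 0.05  # nondecreasing within MC error
        assert r2s[2] == pytest.approx(0.4, abs=0.05)


class TestFilters:
    @staticmethod
    def stub(fid, cv_r2, n_weights=1):
        w = pd.DataFrame({"variant_id": [f"v{i}" for i in range(n_weights)],
                          "effect_allele": "A", "other_allele": "G",
                          "weight": 1.0})
        return models.PredictionModel(fid, "cpg", "chr1", 1, w, cv_r2, 0.1)

    def test_threshold_boundary_and_probe_rule(self):
        cpg_table = pd.DataFrame({"id": ["a", "b", "c"],
                                  "probe_snp_flag": [False, True, False]})
        store = {"a": self.stub("a", 0.009), "b": self.stub("b", 0.5),
                 "c": self.stub("c", 0.01)}
        retained, counts = models.apply_model_filters(store, cpg_table)
        assert set(retained) == {"c"}  # 0.01 retained at the boundary
        assert counts["low_r2"] == 1 and counts["probe_snp"] == 1
        assert store["a"].passed_filters is False
        assert "probe_snp" in store["b"].filter_reasons


class TestExternalValidation:
    @pytest.fixture(scope="class")
    def trained_cohorts(self):
        panel = synthio.simulate_genotypes(800, [(15, 0.4)] * 6, seed=10)
        meth, truth = synthio.simulate_methylome(panel, 60, (0.02, 0.7), 1,
                                                 None, seed=11)
        y = preprocess.rank_inverse_normal(meth.betas)
        cfg = TrainingConfig(seed=12, n_lambda=40)
        store = {}
        for j, crow in enumerate(meth.cpg_table.itertuples(index=False)):
            cis = models.select_cis_variants(crow.chrom, crow.pos, panel)
            store[crow.id] = models.train_feature_model(
                crow.id, y[:, j], panel.dosages[:, cis],
                panel.variant_table.iloc[cis], cfg)
        # external cohort: same generative process, fresh genotype/noise draws
        rng = np.random.default_rng(13)
        ext_panel = synthio.GenotypePanel(
            [f"e{i}" for i in range(800)], panel.variant_table.copy(),
            synthio.draw_dosages(panel, 800, rng), dict(panel.block_corr))
        ext_meth = _remeasure(ext_panel, truth, meth, seed=14)
        return store, ext_panel, ext_meth

    def test_cross_cohort_r2_concordance(self, trained_cohorts):
        store, ext_panel, ext_meth = trained_cohorts
        out = models.validate_external(store, ext_panel, ext_meth)
        assert out.attrs["r2_correlation"] > 0.8

    def test_permuted_external_methylation_is_null(self, trained_cohorts):
        store, ext_panel, ext_meth = trained_cohorts
        rng = np.random.default_rng(15)
        perm = synthio.MethylomePanel(
            ext_meth.sample_ids, ext_meth.cpg_table,
            ext_meth.betas[rng.permutation(len(ext_meth.sample_ids))])
        out = models.validate_external(store, ext_panel, perm)
        assert np.nanmedian(out["external_r2"]) < 0.01

    def test_zero_weight_model_flagged_nan(self, trained_cohorts):
        store, ext_panel, ext_meth = trained_cohorts
        fid = next(iter(store))
        empty = models.PredictionModel(
            fid, "cpg", "chr1", 1,
            store[fid].weights.iloc[0:0], 0.0, 0.1)
        out = models.validate_external({fid: empty}, ext_panel, ext_meth)
        assert out["flagged"][0] and np.isnan(out["external_r2"][0])


def _remeasure(panel, truth, meth_template, seed):
    """Fresh methylation measurement of the same CpGs on a new cohort."""
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    vidx = pd.Index(panel.variant_table["id"])
    betas = np.empty((panel.n_samples, len(meth_template.cpg_table)))
    for j, cid in enumerate(meth_template.cpg_table["id"]):
        ids, eff = truth.cpg_causal[cid]
        g = panel.dosages[:, vidx.get_indexer(ids)] @ eff if len(ids) else 0.0
        latent = g + rng.normal(0, truth.cpg_noise_sd[cid], panel.n_samples)
        betas[:, j] = expit(truth.cpg_baseline[cid] + latent)
    return synthio.MethylomePanel(list(panel.sample_ids),
                                  meth_template.cpg_table.copy(), betas)
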