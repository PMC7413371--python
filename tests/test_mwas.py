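"""Summary-statistic association, individual-level oracle, multiple testing."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from methylwas import formats, models, mwas, studies, synthio

from conftest import make_gwas


def simple_model(weights_rows, fid="cg_test"):
    w = pd.DataFrame(weights_rows, columns=["variant_id", "effect_allele",
                                            "other_allele", "weight"])
    return models.PredictionModel(fid, "cpg", "chr1", 1, w, 0.5, 0.1)


class TestLdReference:
    def test_unit_diagonal_and_bruteforce_pairwise(self, small_panel):
        ids = list(small_panel.variant_table["id"][:5])
        ld = mwas.build_ld_reference(small_panel, ids)
        assert np.allclose(np.diag(ld.corr), 1.0)
        brute = np.corrcoef(small_panel.dosages[:, :5].T)
        assert np.allclose(ld.corr, brute, atol=1e-10)

    def test_duplicated_variant_gives_unit_offdiagonal(self):
        vt = pd.DataFrame({"chrom": "chr1", "pos": [1, 2], "id": ["a", "b"],
                           "effect_allele": "A", "other_allele": "G",
                           "maf": 0.3, "imputation_quality": 1.0, "block": 0})
        d = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        panel = synthio.GenotypePanel(["x", "y", "z"], vt, d, {0: 0.0})
        ld = mwas.build_ld_reference(panel)
        # duplicate columns: correlation 1 before shrinkage; the PSD
        # regularization shrinks it by at most the configured epsilon
        assert ld.corr[0, 1] == pytest.approx(1.0, abs=2e-3)

    def test_monomorphic_variant_flagged_by_zero_sd(self):
        vt = pd.DataFrame({"chrom": "chr1", "pos": [1], "id": ["a"],
                           "effect_allele": "A", "other_allele": "G",
                           "maf": 0.3, "imputation_quality": 1.0, "block": 0})
        panel = synthio.GenotypePanel(["x", "y"], vt, np.ones((2, 1)), {0: 0.0})
        ld = mwas.build_ld_reference(panel)
        assert ld.sd[0] == 0


class TestSummaryAssociation:
    def test_single_variant_model_collapses_to_snp_z(self, small_panel):
        vid = small_panel.variant_table["id"][0]
        a1 = small_panel.variant_table["effect_allele"][0]
        a2 = small_panel.variant_table["other_allele"][0]
        model = simple_model([(vid, a1, a2, -0.7)])
        gwas = make_gwas([vid], a1=a1, a2=a2, beta=0.12, se=0.03)
        aligned, _ = formats.harmonize_alleles(model.weights, gwas)
        ld = mwas.build_ld_reference(small_panel, [vid])
        res = mwas.summary_association(model, aligned, ld)
        assert res.z == pytest.approx(-0.12 / 0.03, rel=1e-12)
        assert res.p == pytest.approx(2 * norm.sf(4.0), rel=1e-9)
        assert res.or_per_sd == pytest.approx(np.exp(res.beta_per_sd))

    def test_zero_weights_degenerate_flag(self, small_panel):
        vid = small_panel.variant_table["id"][0]
        model = simple_model([(vid, "A", "G", 0.0)])
        gwas = make_gwas([vid])
        aligned, _ = formats.harmonize_alleles(model.weights, gwas)
        ld = mwas.build_ld_reference(small_panel, [vid])
        res = mwas.summary_association(model, aligned, ld)
        assert res.flag == "degenerate-variance" and np.isnan(res.z)

    def test_matches_individual_level_oracle(self):
        gap = studies.study_oracle_equivalence(n_cpgs=40, n_samples=800, seed=5)
        assert gap < 1e-6

    def test_sign_correctness_positive_effect_gives_or_above_one(self):
        hits = 0
        for seed in range(10):
            panel = synthio.simulate_genotypes(500, [(10, 0.3)], seed=seed)
            _, truth = synthio.simulate_methylome(panel, 1, 0.6, 1, None,
                                                  seed=seed + 1)
            cid = next(iter(truth.cpg_causal))
            synthio.define_disease_model(truth, {cid: 0.8}, 0.2)
            gwas = synthio.simulate_gwas_summary(panel, truth, 1200, 1200,
                                                 seed=seed + 2,
                                                 population_multiplier=5)
            model = studies.truth_model(cid, truth, panel)
            aligned, _ = formats.harmonize_alleles(model.weights, gwas)
            ld = mwas.build_ld_reference(panel,
                                         aligned["variant_id"].tolist())
            res = mwas.summary_association(model, aligned, ld)
            hits += res.or_per_sd > 1
        assert hits >= 9

    def test_power_ranking_separates_causal_cpgs(self):
        # CpGs with liability effects must out-rank null CpGs by |z|
        panel = synthio.simulate_genotypes(800, [(10, 0.3)] * 8, seed=50)
        _, truth = synthio.simulate_methylome(panel, 40, 0.5, 1, None, seed=51)
        cids = list(truth.cpg_causal)
        causal_set = [c for c in cids if truth.cpg_causal[c][0]][:5]
        synthio.define_disease_model(truth, {c: 0.5 for c in causal_set}, 0.15)
        gwas = synthio.simulate_gwas_summary(panel, truth, 2000, 2000, seed=52,
                                             population_multiplier=6)
        zs, labels = [], []
        for cid in cids:
            if not truth.cpg_causal[cid][0]:
                continue
            model = studies.truth_model(cid, truth, panel)
            aligned, _ = formats.harmonize_alleles(model.weights, gwas)
            ld = mwas.build_ld_reference(panel, aligned["variant_id"].tolist())
            res = mwas.summary_association(model, aligned, ld)
            if np.isfinite(res.z):
                zs.append(abs(res.z))
                labels.append(cid in causal_set)
        zs, labels = np.array(zs), np.array(labels)
        # rank-sum AUC of causal vs null CpGs; LD leakage between CpGs
        # sharing blocks with causal SNPs keeps this below a perfect 1
        from scipy.stats import rankdata
        r = rankdata(zs)
        n1, n0 = labels.sum(), (~labels).sum()
        auc = (r[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        assert auc > 0.9


class TestIndividualLevel:
    def test_perfect_continuous_phenotype_saturates(self, small_panel):
        vid = small_panel.variant_table["id"][0]
        a1 = small_panel.variant_table["effect_allele"][0]
        a2 = small_panel.variant_table["other_allele"][0]
        model = simple_model([(vid, a1, a2, 1.0)])
        y = small_panel.dosages[:, 0].astype(float)
        res = mwas.individual_level_association(model, small_panel, y)
        # score-convention z is bounded by sqrt(n); p is astronomically small
        assert res.z > 30
        assert res.p < 1e-180

    def test_binary_type1_calibration(self, small_panel):
        vid = small_panel.variant_table["id"][0]
        a1 = small_panel.variant_table["effect_allele"][0]
        a2 = small_panel.variant_table["other_allele"][0]
        model = simple_model([(vid, a1, a2, 1.0)])
        rng = np.random.default_rng(0)
        rej = 0
        n_rep = 400
        for _ in range(n_rep):
            y = (rng.random(small_panel.n_samples) < 0.3).astype(float)
            res = mwas.individual_level_association(model, small_panel, y,
                                                    family="binary")
            rej += res.p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rej / n_rep - 0.05) < 3 * se + 1e-9

    def test_constant_prediction_raises(self, small_panel):
        model = simple_model([("absent_snp", "A", "G", 1.0)])
        with pytest.raises(ValueError, match="degenerate"):
            mwas.individual_level_association(
                model, small_panel, np.zeros(small_panel.n_samples))


class TestMultipleTesting:
    def test_bonferroni_printed_value(self):
        t = mwas.bonferroni_threshold(77_243)
        assert t == pytest.approx(6.47e-7, rel=5e-3)
        assert mwas.bonferroni_threshold(1) == 0.05
        assert mwas.bonferroni_threshold(20) == pytest.approx(2.5e-3)

    def test_bonferroni_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            mwas.bonferroni_threshold(0)

    def test_bh_stepup_hand_oracle(self):
        q = mwas.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert mwas.bh_fdr([0.03])[0] == pytest.approx(0.03)
        assert len(mwas.bh_fdr([])) == 0

    def test_bh_order_equivariant(self):
        p = [0.2, 0.001, 0.05, 0.5, 0.03]
        qa = mwas.bh_fdr(p)
        qb = mwas.bh_fdr(p[::-1])[::-1]
        assert np.allclose(qa, qb)
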