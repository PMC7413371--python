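"""Generator behaviour: determinism, LD structure, variance accounting,
liability-model GWAS calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from methylwas import synthio

# Monte-Carlo oracle for the thresholded-Gaussian LD scheme: dosage
# correlation at latent corr 0.8, both allele frequencies 0.3, from a single
# 10^6-haplotype-pair simulation (rng seed 12345).
MC_DOSAGE_CORR = 0.5772


class TestSimulateGenotypes:
    def test_independent_block_has_no_ld(self):
        p = synthio.simulate_genotypes(2000, [(10, 0.0)], maf_range=(0.5, 0.5),
                                       seed=1)
        r = np.corrcoef(p.dosages.T)
        off = r[np.triu_indices(10, 1)]
        assert np.abs(off).max() < 0.08
        assert abs(np.corrcoef(p.dosages[:, 0], p.dosages[:, 1])[0, 1]) < 0.05

    def test_ld_matches_monte_carlo_oracle(self):
        p = synthio.simulate_genotypes(5000, [(2, 0.8)], maf_range=(0.3, 0.3),
                                       seed=2)
        r = np.corrcoef(p.dosages[:, 0], p.dosages[:, 1])[0, 1]
        assert r == pytest.approx(MC_DOSAGE_CORR, abs=0.05)

    def test_deterministic_given_seed(self):
        a = synthio.simulate_genotypes(50, [(5, 0.3)], seed=7)
        b = synthio.simulate_genotypes(50, [(5, 0.3)], seed=7)
        assert np.array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.variant_table, b.variant_table)

    def test_dosages_in_range_and_positions_increasing(self, small_panel):
        assert small_panel.dosages.min() >= 0
        assert small_panel.dosages.max() <= 2
        for _, sub in small_panel.variant_table.groupby("chrom"):
            assert sub["pos"].is_monotonic_increasing

    def test_declared_maf_close_to_empirical(self, small_panel):
        emp = small_panel.dosages.mean(axis=0) / 2
        assert np.abs(emp - small_panel.variant_table["maf"]).max() < 0.05

    def test_empty_blocks_rejected(self):
        with pytest.raises(synthio.ConfigurationError):
            synthio.simulate_genotypes(10, [])


class TestSimulateMethylome:
    def test_betas_in_unit_interval_and_unique_ids(self, methylome_truth):
        meth, _ = methylome_truth
        assert meth.betas.min() > 0 and meth.betas.max() < 1
        assert meth.cpg_table["id"].is_unique

    def test_null_h2_gives_no_genetic_signal(self):
        p = synthio.simulate_genotypes(2000, [(10, 0.2)], seed=3)
        meth, truth = synthio.simulate_methylome(p, 5, 0.0, 1, None, seed=4)
        for cid, (ids, eff) in truth.cpg_causal.items():
            assert np.all(eff == 0)
            assert truth.cpg_cis_h2[cid] == 0

    def test_variance_fraction_matches_request(self):
        p = synthio.simulate_genotypes(5000, [(20, 0.3)], seed=5)
        _, truth = synthio.simulate_methylome(p, 8, 0.4, 1, None, seed=6)
        realized = np.array(list(truth.cpg_cis_h2.values()))
        assert np.abs(realized - 0.4).max() < 0.05

    def test_probe_snp_fraction_exact(self):
        p = synthio.simulate_genotypes(100, [(10, 0.2)], seed=7)
        meth, _ = synthio.simulate_methylome(p, 100, 0.2, 1, None, seed=8,
                                             probe_snp_fraction=0.05)
        assert int(meth.cpg_table["probe_snp_flag"].sum()) == 5

    def test_deterministic_given_seed(self, small_panel, covariates):
        a, _ = synthio.simulate_methylome(small_panel, 5, 0.3, 1, covariates,
                                          seed=9)
        b, _ = synthio.simulate_methylome(small_panel, 5, 0.3, 1, covariates,
                                          seed=9)
        assert np.array_equal(a.betas, b.betas)


class TestSimulateExpression:
    def test_slope_recovered_with_low_noise(self, methylome_truth, small_panel):
        meth, _ = methylome_truth
        cid = meth.cpg_table["id"][0]
        expr = synthio.simulate_expression(meth, small_panel,
                                           [(cid, "geneA", 0.21)],
                                           noise_sd=1e-4, seed=10)
        beta = meth.betas[:, 0]
        slope = np.polyfit(beta, expr.values[:, 0], 1)[0]
        assert slope == pytest.approx(0.21, abs=0.01)

    def test_null_and_negative_slopes(self, methylome_truth, small_panel):
        meth, _ = methylome_truth
        cid = meth.cpg_table["id"][1]
        for true_slope in (0.0, -0.08):
            expr = synthio.simulate_expression(meth, small_panel,
                                               [(cid, "g", true_slope)],
                                               noise_sd=1.0, seed=11)
            beta = meth.betas[:, 1]
            X = np.column_stack([np.ones_like(beta), beta])
            coef, res, *_ = np.linalg.lstsq(X, expr.values[:, 0], rcond=None)
            dof = len(beta) - 2
            sigma2 = float(res[0]) / dof
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
            assert abs(coef[1] - true_slope) < 3 * se

    def test_duplicate_link_rejected(self, methylome_truth, small_panel):
        meth, _ = methylome_truth
        cid = meth.cpg_table["id"][0]
        with pytest.raises(synthio.ConfigurationError):
            synthio.simulate_expression(
                meth, small_panel, [(cid, "g", 1.0), (cid, "g", 2.0)]
            )


class TestSimulateGwas:
    @pytest.fixture(scope="class")
    def null_gwas(self):
        p = synthio.simulate_genotypes(50, [(10_000, 0.0)], seed=20)
        _, truth = synthio.simulate_methylome(p, 1, 0.0, 1, None, seed=21)
        synthio.define_disease_model(truth, {}, 0.3)
        return p, synthio.simulate_gwas_summary(p, truth, 1500, 1500, seed=22,
                                                population_multiplier=3)

    def test_null_mean_z2_near_one(self, null_gwas):
        _, gwas = null_gwas
        z = gwas["BETA"] / gwas["SE"]
        assert (z**2).mean() == pytest.approx(1.0, abs=0.05)

    def test_null_z_is_standard_normal(self, null_gwas):
        _, gwas = null_gwas
        z = gwas["BETA"] / gwas["SE"]
        assert kstest(z, "norm").pvalue > 0.01

    def test_frq_is_exact_dosage_mean(self, null_gwas):
        # FRQ must be within [0,1] and consistent with the declared maf
        panel, gwas = null_gwas
        assert gwas["FRQ"].between(0, 1).all()
        assert np.abs(gwas["FRQ"] - panel.variant_table["maf"]).max() < 0.06

    def test_causal_snp_attains_top_signal(self):
        hits = 0
        for seed in range(10):
            p = synthio.simulate_genotypes(400, [(15, 0.2), (15, 0.2)],
                                           seed=seed)
            _, truth = synthio.simulate_methylome(p, 1, 0.8, 1, None,
                                                  seed=seed + 1)
            cid = next(iter(truth.cpg_causal))
            synthio.define_disease_model(truth, {cid: 1.0}, 0.2)
            gwas = synthio.simulate_gwas_summary(p, truth, 1200, 1200,
                                                 seed=seed + 2,
                                                 population_multiplier=5)
            causal = truth.cpg_causal[cid][0][0]
            causal_block = p.variant_table.set_index("id").loc[causal, "block"]
            # strongest signal must sit in the causal SNP's LD block
            top = gwas.loc[gwas["P"].idxmin(), "SNP"]
            top_block = p.variant_table.set_index("id").loc[top, "block"]
            hits += top_block == causal_block
        assert hits >= 9

    def test_requires_disease_model(self, small_panel, methylome_truth):
        _, truth = methylome_truth
        t = synthio.TruthBundle(rng_seed=0, cpg_causal=truth.cpg_causal,
                                cpg_noise_sd=truth.cpg_noise_sd)
        with pytest.raises(synthio.ConfigurationError):
            synthio.simulate_gwas_summary(small_panel, t, 10, 10, seed=1)

    def test_insufficient_population_raises(self):
        p = synthio.simulate_genotypes(20, [(5, 0.0)], seed=30)
        _, truth = synthio.simulate_methylome(p, 1, 0.0, 1, None, seed=31)
        synthio.define_disease_model(truth, {}, 0.05)
        with pytest.raises(synthio.ConfigurationError, match="multiplier"):
            synthio.simulate_gwas_summary(p, truth, 500, 100, seed=32,
                                          population_multiplier=2)

    def test_deterministic_given_seed(self, null_gwas):
        p = synthio.simulate_genotypes(50, [(20, 0.0)], seed=40)
        _, truth = synthio.simulate_methylome(p, 1, 0.0, 1, None, seed=41)
        synthio.define_disease_model(truth, {}, 0.25)
        a = synthio.simulate_gwas_summary(p, truth, 200, 200, seed=42)
        b = synthio.simulate_gwas_summary(p, truth, 200, 200, seed=42)
        pd.testing.assert_frame_equal(a, b)
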