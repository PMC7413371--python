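"""Simulation studies validating the pipeline's statistical behaviour.

Each function runs a self-contained, seeded experiment against the synthetic
generator and returns summary numbers: the summary-vs-individual oracle gap,
type-I error of the summary association, conditional-analysis mediation
recovery, LD-score heritability recovery, and elastic-net model fidelity.
They are used by the test suite and the reproduction script; sizes default
to the scales at which the checks are specified.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import condh2, formats, models, mwas, synthio

__all__ = [
    "truth_model",
    "study_oracle_equivalence",
    "study_type1_error",
    "study_mediation",
    "study_h2_recovery",
    "study_enet_fidelity",
]


def truth_model(cpg_id, truth: synthio.TruthBundle,
                panel: synthio.GenotypePanel) -> models.PredictionModel:
    """Prediction model whose weights are the generator's causal effects."""
    ids, eff = truth.cpg_causal[cpg_id]
    vt = panel.variant_table.set_index("id")
    weights = pd.DataFrame(
        {
            "variant_id": ids,
            "effect_allele": vt.loc[ids, "effect_allele"].to_numpy(),
            "other_allele": vt.loc[ids, "other_allele"].to_numpy(),
            "weight": eff,
        }
    )
    return models.PredictionModel(cpg_id, "cpg", "chr?", 0, weights,
                                  cv_r2=1.0, lambda_selected=0.0)


def study_oracle_equivalence(n_cpgs: int = 200, n_samples: int = 1500,
                             seed: int = 0) -> float:
    """Max relative |z_summary - z_individual| over simulated CpG models.

    The GWAS is a continuous-trait scan computed on the reference panel
    itself with no covariates, the configuration under which the
    summary-statistic z is algebraically the individual-level score z.
    """
    rng = np.random.default_rng(seed)
    panel = synthio.simulate_genotypes(n_samples, [(20, 0.5)] * 10, seed=seed)
    meth, truth = synthio.simulate_methylome(panel, n_cpgs, 0.3, 2, None,
                                             seed=seed + 1)
    y = rng.standard_normal(n_samples) + 0.05 * panel.dosages[:, 0]
    gwas = mwas.linear_gwas(panel, y)
    worst = 0.0
    for cid in meth.cpg_table["id"]:
        model = truth_model(cid, truth, panel)
        if len(model.weights) == 0:
            continue
        aligned, _ = formats.harmonize_alleles(model.weights, gwas)
        ld = mwas.build_ld_reference(panel, aligned["variant_id"].tolist())
        zs = mwas.summary_association(model, aligned, ld).z
        zi = mwas.individual_level_association(model, panel, y).z
        if np.isfinite(zs) and abs(zi) > 0:
            worst = max(worst, abs(zs - zi) / abs(zi))
    return worst


def study_type1_error(n_tests: int = 20_000, alpha: float = 0.05,
                      seed: int = 0, n_replicates: int = 10,
                      snps_per_feature: int = 3) -> dict:
    """Rejection rate of the summary association under a null disease.

    Disease is independent of all CpGs; per replicate a case-control GWAS is
    simulated and random-weight features over within-block SNP subsets are
    tested against an independent LD reference drawn from the same
    population.
    """
    per_rep = n_tests // n_replicates
    n_blocks, block_size = 50, 20
    rejections = 0
    tested = 0
    zs_all = []
    for rep in range(n_replicates):
        s = seed * 1_000 + rep
        rng = np.random.default_rng(s)
        panel = synthio.simulate_genotypes(
            50, [(block_size, 0.5)] * n_blocks, seed=s
        )
        _, truth = synthio.simulate_methylome(panel, 1, 0.0, 1, None, seed=s + 1)
        synthio.define_disease_model(truth, {}, 0.2)
        gwas = synthio.simulate_gwas_summary(panel, truth, 1500, 1500,
                                             seed=s + 2,
                                             population_multiplier=5)
        ref = synthio.GenotypePanel(
            [f"R{i}" for i in range(2500)],
            panel.variant_table.copy(),
            synthio.draw_dosages(panel, 2500, rng),
            dict(panel.block_corr),
        )
        zl = gwas["BETA"].to_numpy() / gwas["SE"].to_numpy()
        vt = panel.variant_table
        # per-block reference LD, reused across features
        block_ld = {}
        for b in range(n_blocks):
            ids = vt[vt["block"] == b]["id"].tolist()
            block_ld[b] = mwas.build_ld_reference(ref, ids)
        for _ in range(per_rep):
            b = int(rng.integers(0, n_blocks))
            pick = rng.choice(block_size, size=snps_per_feature, replace=False)
            w = rng.standard_normal(snps_per_feature)
            ld = block_ld[b]
            sigma = ld.sd[pick]
            ws = w * sigma
            var_g = float(ws @ ld.corr[np.ix_(pick, pick)] @ ws)
            if var_g <= 0:
                continue
            z = float((ws * zl[b * block_size + pick]).sum() / np.sqrt(var_g))
            zs_all.append(z)
            tested += 1
            if abs(z) > -_norm_ppf(alpha / 2):
                rejections += 1
    return {
        "rate": rejections / tested,
        "n_tests": tested,
        "mean_z2": float(np.mean(np.square(zs_all))),
    }


def _norm_ppf(q):
    from scipy.stats import norm

    return float(norm.ppf(q))


def _mediation_seed(seed: int, independent: bool) -> float:
    """|z_conditional / z_marginal| for one simulated locus."""
    blocks = [(10, 0.8), (10, 0.8)]
    panel = synthio.simulate_genotypes(1000, blocks, seed=seed)
    meth, truth = synthio.simulate_methylome(panel, 40, 0.5, 1, None,
                                             seed=seed + 1)
    tab = meth.cpg_table
    vt = panel.variant_table.set_index("id")
    # tested CpG on chr1; for the independent scenario the index SNP is the
    # causal SNP of a second, chr2 disease CpG
    cand1 = [c for c in tab[tab["chrom"] == "chr1"]["id"]
             if truth.cpg_causal[c][0]]
    cand2 = [c for c in tab[tab["chrom"] == "chr2"]["id"]
             if truth.cpg_causal[c][0]]
    cpg = cand1[0]
    causal = truth.cpg_causal[cpg][0][0]
    if independent:
        other = cand2[0]
        index_snp = truth.cpg_causal[other][0][0]
        effects = {cpg: 0.5, other: 0.5}
    else:
        index_snp = causal
        effects = {cpg: 0.5}
    synthio.define_disease_model(truth, effects, 0.15)
    gwas = synthio.simulate_gwas_summary(panel, truth, 1500, 1500,
                                         seed=seed + 2,
                                         population_multiplier=7)
    # model for the CpG from OLS on three block SNPs other than the index
    snp_pool = [v for v in panel.variant_table[
        panel.variant_table["chrom"] == "chr1"]["id"] if v != index_snp][:3]
    idx = panel.variant_index(snp_pool)
    X = np.column_stack([np.ones(panel.n_samples), panel.dosages[:, idx]])
    cj = pd.Index(tab["id"]).get_loc(cpg)
    w = np.linalg.lstsq(X, meth.betas[:, cj], rcond=None)[0][1:]
    model = models.PredictionModel(
        cpg, "cpg", "chr1", 0,
        pd.DataFrame(
            {
                "variant_id": snp_pool,
                "effect_allele": vt.loc[snp_pool, "effect_allele"].to_numpy(),
                "other_allele": vt.loc[snp_pool, "other_allele"].to_numpy(),
                "weight": w,
            }
        ),
        cv_r2=0.5, lambda_selected=0.0,
    )
    aligned, _ = formats.harmonize_alleles(model.weights, gwas)
    ld = mwas.build_ld_reference(panel, aligned["variant_id"].tolist()
                                 + [index_snp])
    res = condh2.conditional_association(
        model, aligned, ld, index_snp, gwas, significance_threshold=1e-4
    )
    if res.z_marginal == 0:
        return np.nan
    return abs(res.z_conditional) / abs(res.z_marginal)


def study_mediation(n_seeds: int = 100, seed: int = 0) -> dict:
    """Conditional-analysis recovery in full-mediation and independent loci.

    Full mediation (the CpG's only causal SNP is the index risk SNP) should
    collapse the conditional z; an independent signal (index SNP on another
    chromosome) should leave it essentially unchanged.
    """
    full = [_mediation_seed(seed * 10_000 + 2 * k, independent=False)
            for k in range(n_seeds)]
    indep = [_mediation_seed(seed * 10_000 + 2 * k + 1, independent=True)
             for k in range(n_seeds)]
    return {
        "full_mediation_median_ratio": float(np.nanmedian(full)),
        "independent_median_ratio": float(np.nanmedian(indep)),
    }


def study_h2_recovery(h2_values=(0.0, 0.1, 0.3), n_seeds: int = 100,
                      M: int = 500, n_total: float = 140_306.0,
                      seed: int = 0) -> dict:
    """Coverage of the fixed-intercept LD-score heritability estimator.

    Z scores are drawn with E[Z^2] = 1 + x*h2, x = N_T*l/M, and the fraction
    of seeds with |h2_hat - h2| <= 2*SE is reported per h2, along with the
    mean estimate.
    """
    out = {}
    for h2 in h2_values:
        cover = 0
        est = []
        for k in range(n_seeds):
            rng = np.random.default_rng(seed * 100_000 + k * 10 + int(h2 * 10))
            l = 1.0 + rng.exponential(1.0, M)
            x = n_total * l / M
            z = rng.standard_normal(M) * np.sqrt(1.0 + x * h2)
            fit = condh2.estimate_h2_ldsc(z, l, n_total, M)
            est.append(fit.h2)
            if abs(fit.h2 - h2) <= 2.0 * fit.h2_se:
                cover += 1
        out[h2] = {"coverage": cover / n_seeds, "mean_h2": float(np.mean(est))}
    return out


def study_enet_fidelity(n_seeds: int = 100, seed: int = 0) -> dict:
    """Elastic-net model fidelity at the reference scenario scale.

    Signal case: one causal SNP, latent h2 = 0.5, n = 2000 — reports the
    range of cv R^2 and how often the causal SNP carries the largest
    |weight|.  Null case: pure-noise CpG with 50 cis SNPs, n = 500 —
    reports how often cv R^2 < 0.01 (model filtered).
    """
    r2s = []
    hits = 0
    h2 = 0.5
    for k in range(n_seeds):
        s = seed * 100_000 + k
        panel = synthio.simulate_genotypes(2000, [(25, 0.4)], seed=s)
        rng = np.random.default_rng(s + 1)
        ci = int(rng.integers(0, panel.n_variants))
        causal = panel.variant_table["id"][ci]
        g = panel.dosages[:, ci].astype(float)
        g = (g - g.mean()) / g.std() * np.sqrt(h2)
        y = g + rng.normal(0.0, np.sqrt(1.0 - h2), size=panel.n_samples)
        cfg = models.TrainingConfig(seed=s)
        m = models.train_feature_model("cpg_signal", y, panel.dosages,
                                       panel.variant_table, cfg)
        r2s.append(m.cv_r2)
        hit = False
        if len(m.weights):
            top = m.weights.iloc[int(m.weights["weight"].abs().argmax())]
            hit = top["variant_id"] == causal
        hits += hit and 0.35 <= m.cv_r2 <= 0.6
    null_filtered = 0
    for k in range(n_seeds):
        s = seed * 100_000 + 50_000 + k
        panel = synthio.simulate_genotypes(500, [(50, 0.4)], seed=s)
        rng = np.random.default_rng(s)
        y = rng.standard_normal(500)
        m = models.train_feature_model("null", y, panel.dosages,
                                       panel.variant_table,
                                       models.TrainingConfig(seed=s))
        null_filtered += m.cv_r2 < 0.01
    return {
        "cv_r2_mean": float(np.mean(r2s)),
        "cv_r2_min": float(np.min(r2s)),
        "cv_r2_max": float(np.max(r2s)),
        "signal_recovery_rate": hits / n_seeds,
        "null_filtered_rate": null_filtered / n_seeds,
    }
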