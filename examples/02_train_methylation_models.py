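"""Train cis elastic-net methylation prediction models.

Preprocesses the methylome (quantile normalization across samples,
rank-based inverse-normal per CpG, covariate residualization), trains one
elastic-net model per CpG from SNPs within a 2-Mb window, applies the
R^2 >= 0.01 and probe-SNP filters, and prints what survived.
"""

import numpy as np

from methylwas import formats, models, preprocess, synthio

panel = synthio.simulate_genotypes(800, [(40, 0.5)] * 4, seed=7)
cov = synthio.simulate_covariates(panel.sample_ids, seed=8)
meth, truth = synthio.simulate_methylome(panel, 40, (0.05, 0.6), 2, cov, seed=9)

qn = preprocess.quantile_normalize_samples(meth.betas)
rin = preprocess.rank_inverse_normal(qn)
resid = preprocess.residualize(rin, cov)

cfg = models.TrainingConfig(seed=0)  # alpha=0.5, 10-fold CV, 2-Mb window
store = {}
for j, crow in enumerate(meth.cpg_table.itertuples(index=False)):
    cis = models.select_cis_variants(crow.chrom, crow.pos, panel,
                                     cfg.window_halfwidth)
    store[crow.id] = models.train_feature_model(
        crow.id, resid[:, j], panel.dosages[:, cis],
        panel.variant_table.iloc[cis], cfg, chrom=crow.chrom, pos=crow.pos)

retained, counts = models.apply_model_filters(store, meth.cpg_table)
import tempfile
formats.write_model_store(retained, tempfile.mktemp(prefix="models"))

r2 = np.array([m.cv_r2 for m in store.values()])
true_h2 = np.array([truth.cpg_cis_h2[c] for c in store])
print(f"trained {len(store)} models; retained {len(retained)} "
      f"(exclusions: {counts})")
print(f"cv R^2: median {np.median(r2):.3f}, range "
      f"[{r2.min():.3f}, {r2.max():.3f}]")
print(f"corr(cv R^2, true latent cis-h2) = "
      f"{np.corrcoef(r2, true_h2)[0, 1]:.2f} "
      "(models track the simulated heritability)")
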