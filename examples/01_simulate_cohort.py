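"""Simulate a small multi-omics cohort with known ground truth.

Generates LD-structured SNP dosages, covariates, cis-mQTL-driven CpG beta
values, a linked gene, and case-control GWAS summary statistics under a
liability-threshold disease model, then prints a few sanity numbers.
"""

import numpy as np

from methylwas import synthio

panel = synthio.simulate_genotypes(
    n_samples=1000, blocks=[(30, 0.6), (30, 0.2)], seed=1
)
cov = synthio.simulate_covariates(panel.sample_ids, seed=2)
meth, truth = synthio.simulate_methylome(
    panel, n_cpgs=50, cis_h2=0.4, n_causal_per_cpg=2, covariates=cov, seed=3
)
cpg = meth.cpg_table["id"][0]
expr = synthio.simulate_expression(meth, panel, [(cpg, "geneA", 1.2)],
                                   noise_sd=0.3, seed=4)
synthio.define_disease_model(truth, {cpg: 0.4}, prevalence=0.12)
gwas = synthio.simulate_gwas_summary(panel, truth, n_cases=2000,
                                     n_controls=2000, seed=5)

print(f"panel: {panel.n_samples} samples x {panel.n_variants} variants")
print(f"methylome: betas in [{meth.betas.min():.3f}, {meth.betas.max():.3f}]")
print(f"realized cis-h2 of {cpg}: {truth.cpg_cis_h2[cpg]:.3f} (requested 0.4)")
z = gwas["BETA"] / gwas["SE"]
print(f"GWAS: {len(gwas)} variants, mean Z^2 = {(z**2).mean():.3f} "
      "(> 1: the disease CpG's cis SNPs carry real signal)")
print(f"strongest SNP: {gwas.loc[gwas['P'].idxmin(), 'SNP']}, "
      f"causal SNPs of {cpg}: {truth.cpg_causal[cpg][0]}")
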