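"""Associate genetically predicted methylation with disease from GWAS
summary statistics only.

Builds a truth-weighted model for a disease-linked CpG, harmonizes its
alleles against a simulated case-control GWAS, and computes the
summary-statistic z with a reference LD panel — then cross-checks the
Bonferroni threshold used at methylome scale.
"""

from methylwas import formats, mwas, studies, synthio

panel = synthio.simulate_genotypes(1500, [(20, 0.5)] * 3, seed=11)
meth, truth = synthio.simulate_methylome(panel, 12, 0.5, 2, None, seed=12)
cpg = next(c for c in meth.cpg_table["id"] if truth.cpg_causal[c][0])
synthio.define_disease_model(truth, {cpg: 0.5}, prevalence=0.12)
gwas = synthio.simulate_gwas_summary(panel, truth, 3000, 3000, seed=13)

model = studies.truth_model(cpg, truth, panel)
aligned, report = formats.harmonize_alleles(model.weights, gwas)
print(f"harmonization: {report}")

ld = mwas.build_ld_reference(panel, aligned["variant_id"].tolist())
res = mwas.summary_association(model, aligned, ld)
print(f"{cpg}: z = {res.z:.2f}, OR per SD of predicted methylation = "
      f"{res.or_per_sd:.3f}, p = {res.p:.2e} ({res.n_snps_used} SNPs)")
print(f"methylome-wide Bonferroni threshold (77,243 tests): "
      f"{mwas.bonferroni_threshold(77_243):.3g}")
print("significant" if res.p <= mwas.bonferroni_threshold(77_243)
      else "not significant at methylome scale")
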