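# Methods

This note documents the statistical models, conventions and numerical
choices of `methylwas`, and what the synthetic-data generator does and does
not emulate.

## Prediction models

For a CpG at position *p*, predictors are SNP dosages on the same
chromosome with |pos − p| ≤ 1 Mb (a 2-Mb window, bounds inclusive, all
coordinates 1-based).  The fit is the elastic net with mixing α = 0.5 over a
grid of 100 log-spaced penalties from λ_max (the smallest λ with an all-zero
solution) down to 10⁻³ λ_max.  Predictors are standardized internally and
the response is scaled to unit variance during fitting (glmnet's
convention), which makes λ selection and the reported R² invariant to affine
rescaling of the response; stored weights are back-transformed to the
per-allele dosage scale required by the summary statistic.  The coordinate
descent itself is `sklearn.linear_model.enet_path`; the grid, fold loop,
pooled out-of-fold R² and back-transform are ours.

λ is chosen by tenfold cross-validation minimizing mean held-out MSE, with
fold assignment drawn from the seeded generator so training is
deterministic.  The model's prediction R² is the squared Pearson correlation
between pooled out-of-fold predictions and the measured values (pooling is
more stable than per-fold averaging at n in the hundreds).  The final model
is refit on all samples at the selected λ — the fit that maximizes data use
and matches common practice.  Models enter association only when cv R² ≥
0.01 and the probe carries no SNP in its binding site; both checks and their
exclusion counts live in `apply_model_filters`.

Preprocessing order is fixed: quantile normalization across samples (each
sample's sorted values mapped to the across-sample mean of sorted values,
ties receiving the mean of the reference values they span), rank-based
inverse-normal per CpG (Blom offset 3/8, average ranks for ties), then
least-squares residualization on intercept + covariates.  One cell-type
fraction is dropped from the design against the sum-to-one singularity.
Residualizing before the penalized fit (rather than including covariates in
it) keeps the elastic net a pure SNP model.  Rank-normal offset and tie
handling are community defaults, chosen once; other offsets change values in
the third decimal at n ≥ 100.

## Summary-statistic association

For weights w over SNPs with reference dosage SDs σ and LD matrix R,

    z = Σ_l w_l (σ_l/σ_g)(β_l/se_l),   σ_g² = wᵀ diag(σ) R diag(σ) w,
    β_per_SD = Σ_l w_l σ_l² β_l / σ_g .

SNP variances come from the LD reference, not from GWAS allele frequencies
(a config switch allows 2f(1−f)).  Model SNPs absent from the GWAS are
dropped and σ_g recomputed over the survivors.  Two-sided p-values use the
normal, never the t.  The reference correlation matrix is shrunk toward the
identity by ε = 10⁻³ on the off-diagonal only if an eigenvalue falls below
10⁻⁸ (duplicated or collinear reference columns).

The individual-level oracle regresses the phenotype on the standardized
genetic prediction.  For a continuous trait without covariates both the
per-SNP GWAS helper and the oracle use the large-sample score convention
se = sd(y)/(sd(x)√n) with population (ddof 0) SDs throughout; under that
single convention the summary z and the individual-level z are algebraically
identical when the reference panel is the GWAS cohort, which is what the
equivalence test checks to 10⁻⁶ relative.  A consequence of the score
convention is that z is bounded by √n, so a perfectly predicted phenotype
yields z = √n with an astronomically small (but not underflowed) p.  Binary
traits are fit by full logistic MLE (statsmodels).

Multiple testing: the methylome-wide threshold is fwer/n_tests (0.05/77,243
= 6.47 × 10⁻⁷ at the scale such studies run), compared with ≤ on the
unrounded value; gene-level and eQTM analyses use Benjamini–Hochberg FDR
(statsmodels).

## Conditional analysis and heritability

Conditioning on one index risk SNP i uses the classic approximate
single-SNP formula on the z scale, z_{j|i} = (z_j − r_{ji} z_i)/√(1−r_{ji}²),
with the conditional per-SNP effect β_j − r_{ji}(σ_i/σ_j)β_i and the SE set
so β/se reproduces z_{j|i}; the summary association is then re-run on the
conditional statistics.  Any model SNP with |r| > 0.999 to the index marks
the result degenerate (the model is the index signal itself).  Full
multi-SNP stepwise joint analysis is out of scope — one index SNP per locus
matches how the method is used here.  A locus is *novel* when every
same-chromosome risk SNP is strictly more than 500 kb away.

LD scores of predicted methylation are computed on a reference cohort:
l_c = Σ_{c'} r²(ĝ_c, ĝ_{c'}) over the associated set, self term included so
l ≥ 1 (excludable by flag).  Heritability comes from regressing Z² − 1
through the origin on x = N_T·l/M — the intercept is fixed at 1 by default,
with a free-intercept variant available — and the slope's SE is
heteroskedasticity-robust (HC0).  The familial relative risk explained is
h²/0.57, the trait heritability of prostate cancer.  Note the formula is
read with h² as a multiplier of N_T·l/M: the alternative (division) would
make Z² shrink as heritability grows, contradicting the LD-score regression
it derives from.

## Integration and annotation

Candidate CpG–gene pairs use the strand-aware TSS (start for +, end for −)
within ±500 kb, the same radius as the novelty rule; the window is
configurable since "flanking gene" conventions vary.  The eQTM regression
puts raw methylation beta values and the covariates in one OLS design
(equivalent to double residualization by Frisch–Waugh but with correct
standard errors); expression is normalized upstream.  Triads are judged on
point-estimate signs — consistent iff sign(meth→disease) =
sign(eQTM) × sign(expr→disease) — but only reported for triads whose three
legs pass their significance gates (Bonferroni, FDR, FDR); a zero effect is
flagged indeterminate, not consistent.

Region classification uses a refFlat-style transcript table with 1-kb
upstream/downstream flanks and a 2-bp splice margin.  Per-transcript labels
are resolved across overlapping transcripts by fixed precedence
(combination categories, then exonic, UTRs, ncRNA exonic, introns, flanks,
intergenic), so every CpG receives exactly one of the 13 categories.
Enrichment contrasts associated CpGs against the *complement* of the tested
set (disjoint groups are statistically cleaner than comparing against a
superset that contains them; a flag restores the overlapping contrast) with
Pearson chi-square, no continuity correction, and an exact-test fallback
when an expected cell drops below 1.

## Synthetic data

Genotypes: within each block (one block per chromosome label, variants 1 kb
apart from position 10⁶), two haplotypes per sample are drawn by
thresholding equicorrelated standard normals at Φ⁻¹(effect-allele
frequency) and summed.  This yields reproducible LD with a controllable
latent correlation; the realized dosage correlation is attenuated by the
thresholding (latent 0.8 at frequency 0.3 gives dosage r ≈ 0.58, the frozen
Monte-Carlo value used in tests).  Frequencies are uniform on (0.05, 0.5]
by default, imputation quality uniform on (0.9, 1].

Methylation: each CpG anchors near a variant; its latent value is
causal-dosage effects (rescaled so the genetic share of genetic-plus-noise
variance equals the requested cis-h², which may be per-CpG uniform over an
interval), plus covariate effects, plus Gaussian noise; beta values are the
logistic transform of a per-CpG baseline plus the latent.  All truth
statements (causal SNPs, effects, realized h²) live on the latent scale.  A
requested fraction of CpGs (default 5%) is flagged as probe-SNP carriers.

Disease: liability is the effect-weighted sum of CpG latents plus unit
Gaussian residual; cases are the top `prevalence` fraction of a population
`population_multiplier` times the cohort size, from which exactly n_cases /
n_controls are drawn (mimicking consortium case enrichment).  Per-variant
logistic regressions (vectorized IRLS, verified against statsmodels to
machine precision) yield BETA/SE/P; FRQ is the cohort dosage mean over two;
the GWAS cohort is drawn fresh from the stored block structure, independent
of the model-training cohort.  Mean null Z² sits slightly below 1
(≈ 0.96–0.98) — the familiar finite-sample deflation of the Wald statistic
at low minor-allele frequencies — and the z distribution passes
Kolmogorov–Smirnov normality at study sizes.

What the generator does not emulate: coalescent LD decay and haplotype
structure, imputation dosage noise, array probe chemistry and batch
effects, population stratification beyond the covariate PCs, and
non-additive genetic effects.  Passing tests therefore demonstrate the
statistical machinery is correct under the assumed model, not that real
cohorts meet those assumptions.

## Problem sizes and determinism

The validation studies run at the scales their checks are defined at: 200
CpGs for the oracle equivalence; 20,000 feature-tests (10 GWAS replicates ×
2,000 random-weight features over 1,000 SNPs in 50 blocks) for type-I error;
100 seeds each for mediation recovery, heritability coverage (M = 500 per
fit) and elastic-net fidelity (n = 2,000 signal, n = 500 null).  Unit tests
re-run the same studies at reduced seed counts.  The smoke pipeline uses
200 CpGs, 20 genes, 800 training samples, a 4,000-sample GWAS cohort and a
1,200-sample LD reference — small enough to finish in well under a minute
while exercising every stage.  Every public operation takes a seed and
derives all sub-seeds from it; reruns with the same configuration are
checksum-identical.

## Known limitations

- Conditional analysis handles one index SNP per locus; multi-signal loci
  need iterative conditioning the package does not implement.
- The summary statistic assumes the GWAS and reference panel share ancestry;
  no LD mismatch correction is applied.
- External validation compares predictions against measured beta values, so
  its R² is attenuated by the logistic link relative to the latent scale;
  the cross-cohort concordance summary (correlation of training vs external
  R² across models) is unaffected in rank terms.
- The eQTM stage models one CpG per gene at a time; co-methylated CpGs are
  not jointly modeled.
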