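"""Synthetic genotype / methylation / expression / GWAS generator.

The generator emulates the statistical structure of the cohort data the
pipeline is designed for: LD-structured imputed SNP dosages, CpG methylation
beta values driven by cis mQTLs plus covariate and cell-composition effects,
gene expression driven by methylation, and case-control GWAS summary
statistics produced under a liability-threshold disease model.  Every
operation is deterministic given its seed and records its ground truth in a
:class:`TruthBundle` so recovery can be tested.

Genotypes come from thresholding block-equicorrelated latent Gaussians into
two haplotypes per sample and summing them, which gives simple, reproducible
LD with a controllable within-block correlation.  Methylation "truth" lives
on the latent (logit) scale; beta values are the logistic transform of the
latent, which keeps them in [0, 1] while variance fractions stay
well-defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "GenotypePanel",
    "MethylomePanel",
    "ExpressionPanel",
    "TruthBundle",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_methylome",
    "simulate_expression",
    "simulate_gwas_summary",
    "define_disease_model",
    "draw_dosages",
]

GWAS_COLUMNS = ["SNP", "CHR", "POS", "A1", "A2", "FRQ", "BETA", "SE", "P", "N"]

# non strand-ambiguous allele pairs used for simulated variants
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class GenotypePanel:
    """SNP dosages for a set of samples plus per-variant metadata.

    ``variant_table`` columns: chrom, pos (1-based), id, effect_allele,
    other_allele, maf, imputation_quality, block.  ``block_corr`` maps block
    id to the within-block latent correlation so that fresh cohorts with the
    same LD structure can be drawn (:func:`draw_dosages`).
    """

    sample_ids: list[str]
    variant_table: pd.DataFrame
    dosages: np.ndarray
    block_corr: dict[int, float] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_table)

    def variant_index(self, variant_ids) -> np.ndarray:
        pos = pd.Index(self.variant_table["id"])
        return pos.get_indexer(variant_ids)


@dataclass
class MethylomePanel:
    """Methylation beta values (samples x CpGs) with a CpG position table.

    ``cpg_table`` columns: chrom, pos (1-based), id, probe_snp_flag.
    """

    sample_ids: list[str]
    cpg_table: pd.DataFrame
    betas: np.ndarray


@dataclass
class ExpressionPanel:
    """Expression values (samples x genes) with gene coordinates.

    ``gene_table`` columns: chrom, start, end, strand, id, symbol.
    """

    sample_ids: list[str]
    gene_table: pd.DataFrame
    values: np.ndarray


@dataclass
class TruthBundle:
    """Ground truth of a synthetic scenario, all on the latent scale."""

    rng_seed: int
    cpg_causal: dict[str, tuple[list[str], np.ndarray]] = field(default_factory=dict)
    cpg_noise_sd: dict[str, float] = field(default_factory=dict)
    cpg_cis_h2: dict[str, float] = field(default_factory=dict)
    cpg_baseline: dict[str, float] = field(default_factory=dict)
    gene_links: dict[tuple[str, str], float] = field(default_factory=dict)
    liability_effects: dict[str, float] = field(default_factory=dict)
    prevalence: float | None = None
    mediation_map: dict[str, str] = field(default_factory=dict)

    @property
    def has_disease_model(self) -> bool:
        return self.prevalence is not None


def _draw_block_dosages(rng, n_samples, n_variants, corr, thresholds,
                        chunk=2000):
    """Two thresholded equicorrelated Gaussian haplotypes, summed.

    The per-haplotype shared factor is drawn once per block; independent
    noise is generated in variant chunks to bound peak memory on large
    blocks.
    """
    r = np.sqrt(corr)
    s = np.sqrt(1.0 - corr)
    dos = np.zeros((n_samples, n_variants), dtype=np.float64)
    for _ in range(2):  # two haplotypes
        shared = rng.standard_normal((n_samples, 1))
        for j0 in range(0, n_variants, chunk):
            j1 = min(j0 + chunk, n_variants)
            z = r * shared + s * rng.standard_normal((n_samples, j1 - j0))
            dos[:, j0:j1] += z < thresholds[None, j0:j1]
    return dos


def simulate_genotypes(n_samples, blocks, maf_range=(0.05, 0.5), seed=0):
    """Simulate an LD-structured dosage panel.

    Parameters
    ----------
    n_samples : int
        Number of samples (>= 1).
    blocks : list of (n_variants, within_block_corr)
        Each block becomes one chromosome; variants are spaced 1 kb apart
        starting at position 1,000,000, so cis windows are unambiguous.
    maf_range : (low, high)
        Effect-allele frequencies drawn uniformly in this range; must lie in
        (0, 0.5].
    seed : int
        Seed for the generator; identical seeds give identical panels.
    """
    if not blocks:
        raise ConfigurationError("blocks list must be nonempty")
    if n_samples < 1:
        raise ConfigurationError("n_samples must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ConfigurationError("maf_range must be within (0, 0.5]")
    for nv, corr in blocks:
        if not (0.0 <= corr < 1.0):
            raise ConfigurationError("within_block_corr must be in [0, 1)")
        if nv < 1:
            raise ConfigurationError("each block needs at least one variant")

    rng = np.random.default_rng(seed)
    rows = []
    dosage_blocks = []
    block_corr = {}
    vid = 0
    for b, (nv, corr) in enumerate(blocks):
        block_corr[b] = float(corr)
        maf = rng.uniform(lo, hi, size=nv)
        thresholds = norm.ppf(maf)
        dosage_blocks.append(_draw_block_dosages(rng, n_samples, nv, corr, thresholds))
        pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=nv)
        qual = rng.uniform(0.9, 1.0, size=nv)
        for j in range(nv):
            a1, a2 = _ALLELE_PAIRS[pair_idx[j]]
            rows.append(
                {
                    "chrom": f"chr{b + 1}",
                    "pos": 1_000_000 + j * 1_000,
                    "id": f"rs{vid:06d}",
                    "effect_allele": a1,
                    "other_allele": a2,
                    "maf": float(maf[j]),
                    "imputation_quality": float(qual[j]),
                    "block": b,
                }
            )
            vid += 1
    table = pd.DataFrame(rows)
    dosages = np.concatenate(dosage_blocks, axis=1)
    sample_ids = [f"S{i:05d}" for i in range(n_samples)]
    return GenotypePanel(sample_ids, table, dosages, block_corr)


def draw_dosages(panel: GenotypePanel, n_samples: int, rng) -> np.ndarray:
    """Draw a fresh cohort with the panel's LD structure and frequencies."""
    out = []
    for b, sub in panel.variant_table.groupby("block", sort=True):
        thresholds = norm.ppf(sub["maf"].to_numpy())
        out.append(
            _draw_block_dosages(rng, n_samples, len(sub), panel.block_corr[b], thresholds)
        )
    dos = np.concatenate(out, axis=1)
    order = np.argsort(
        pd.concat(
            [sub for _, sub in panel.variant_table.groupby("block", sort=True)]
        ).index.to_numpy()
    )
    return dos[:, order]


def simulate_covariates(sample_ids, seed=0, n_pcs=10):
    """Covariate table: age, sex, six cell-type fractions, genotype PCs.

    Cell fractions are Dirichlet-distributed (neutrophil-dominant, as in
    whole blood) and sum to one per sample.
    """
    rng = np.random.default_rng(seed)
    n = len(sample_ids)
    cols = {
        "age": rng.normal(60.0, 8.0, size=n),
        "sex": rng.integers(0, 2, size=n).astype(float),
    }
    frac = rng.dirichlet([30.0, 10.0, 6.0, 4.0, 3.0, 1.0], size=n)
    for j in range(6):
        cols[f"cell{j + 1}"] = frac[:, j]
    for k in range(n_pcs):
        cols[f"pc{k + 1}"] = rng.standard_normal(n)
    return pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id"))


def simulate_methylome(
    panel: GenotypePanel,
    n_cpgs: int,
    cis_h2: float,
    n_causal_per_cpg: int,
    covariates: pd.DataFrame | None = None,
    seed: int = 0,
    probe_snp_fraction: float = 0.05,
    window_halfwidth: int = 1_000_000,
    covariate_sd: float = 0.3,
):
    """Simulate CpG beta values driven by cis SNPs.

    Each CpG is anchored near a variant; its latent value is
    ``sum(causal dosage * effect) + covariate effects + Gaussian noise`` with
    the genetic fraction of the (genetic + noise) variance equal to
    ``cis_h2``; betas are the logistic transform of a per-CpG baseline plus
    the latent.  The returned :class:`TruthBundle` records causal SNPs,
    effects (post-scaling), noise SDs and the realized latent-scale cis-h2.

    ``cis_h2`` may be a scalar (every CpG gets the same heritability) or a
    ``(low, high)`` pair, in which case each CpG's heritability is drawn
    uniformly from that interval — mirroring the wide spread of cis
    heritabilities seen on methylation arrays.
    """
    if np.ndim(cis_h2) == 0:
        h2_lo = h2_hi = float(cis_h2)
    else:
        h2_lo, h2_hi = map(float, cis_h2)
    if not (0.0 <= h2_lo <= h2_hi < 1.0):
        raise ConfigurationError("cis_h2 must be in [0, 1)")
    rng = np.random.default_rng(seed)
    vt = panel.variant_table
    pos = vt["pos"].to_numpy()
    chroms = vt["chrom"].to_numpy()
    n = panel.n_samples

    cov_effect = np.zeros(n)
    if covariates is not None:
        X = covariates.drop(columns=["cell6"], errors="ignore").to_numpy(float)
        X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        gamma = rng.normal(0.0, covariate_sd, size=X.shape[1])
        cov_effect = X @ gamma

    anchor = rng.integers(0, panel.n_variants, size=n_cpgs)
    offsets = rng.integers(-200, 201, size=n_cpgs)
    truth = TruthBundle(rng_seed=int(seed))
    betas = np.empty((n, n_cpgs))
    rows = []
    n_flagged = int(round(probe_snp_fraction * n_cpgs))
    flagged = set(rng.choice(n_cpgs, size=n_flagged, replace=False).tolist())

    h2_per_cpg = rng.uniform(h2_lo, h2_hi, size=n_cpgs)
    for c in range(n_cpgs):
        cid = f"cg{c:07d}"
        cis_h2 = float(h2_per_cpg[c])
        cchrom = chroms[anchor[c]]
        cpos = int(pos[anchor[c]] + offsets[c])
        in_cis = np.flatnonzero(
            (chroms == cchrom) & (np.abs(pos - cpos) <= window_halfwidth)
        )
        if in_cis.size == 0:
            warnings.warn(f"CpG {cid}: no variants in cis window, simulated as noise")
            g = np.zeros(n)
            causal_ids, eff = [], np.zeros(0)
            noise_sd = 1.0
        elif cis_h2 == 0.0:
            g = np.zeros(n)
            k = min(n_causal_per_cpg, in_cis.size)
            causal = rng.choice(in_cis, size=k, replace=False)
            causal_ids = vt["id"].to_numpy()[causal].tolist()
            eff = np.zeros(k)
            noise_sd = 1.0
        else:
            if in_cis.size < n_causal_per_cpg:
                raise ConfigurationError(
                    f"CpG {cid}: only {in_cis.size} cis variants for "
                    f"{n_causal_per_cpg} causal slots"
                )
            causal = rng.choice(in_cis, size=n_causal_per_cpg, replace=False)
            eff = rng.standard_normal(n_causal_per_cpg)
            g = panel.dosages[:, causal] @ eff
            vg = g.var()
            if vg <= 0:  # monomorphic draw; degrade to noise
                g = np.zeros(n)
                eff = np.zeros(n_causal_per_cpg)
                noise_sd = 1.0
            else:
                scale = np.sqrt(cis_h2 / vg)
                g = g * scale
                eff = eff * scale
                noise_sd = float(np.sqrt(1.0 - cis_h2))
            causal_ids = vt["id"].to_numpy()[causal].tolist()
        e = rng.normal(0.0, noise_sd, size=n)
        latent = g + e
        realized = float(g.var() / latent.var()) if latent.var() > 0 else 0.0
        mu = float(rng.normal(0.0, 1.5))
        betas[:, c] = expit(mu + latent + cov_effect)
        truth.cpg_causal[cid] = (causal_ids, np.asarray(eff, dtype=float))
        truth.cpg_noise_sd[cid] = noise_sd
        truth.cpg_cis_h2[cid] = realized
        truth.cpg_baseline[cid] = mu
        rows.append(
            {"chrom": cchrom, "pos": cpos, "id": cid, "probe_snp_flag": c in flagged}
        )
    cpg_table = pd.DataFrame(rows)
    return MethylomePanel(list(panel.sample_ids), cpg_table, betas), truth


def simulate_expression(
    methylome: MethylomePanel,
    panel: GenotypePanel,
    links,
    noise_sd: float = 1.0,
    seed: int = 0,
    gene_table: pd.DataFrame | None = None,
    truth: TruthBundle | None = None,
):
    """Simulate gene expression as ``slope * beta + Gaussian noise``.

    ``links`` is a list of ``(cpg_id, gene_id, slope)``; each gene is placed
    on its CpG's chromosome with a TSS within 100 kb unless ``gene_table``
    supplies coordinates.  Duplicate (cpg, gene) pairs are rejected.
    """
    seen = set()
    for cpg_id, gene_id, _ in links:
        if (cpg_id, gene_id) in seen:
            raise ConfigurationError(f"duplicate link ({cpg_id}, {gene_id})")
        seen.add((cpg_id, gene_id))
    cpg_index = pd.Index(methylome.cpg_table["id"])
    for cpg_id, gene_id, _ in links:
        if cpg_id not in cpg_index:
            raise ConfigurationError(f"unknown CpG in link: {cpg_id}")

    rng = np.random.default_rng(seed)
    gene_ids = list(dict.fromkeys(g for _, g, _ in links))
    if gene_table is None:
        rows = []
        for gid in gene_ids:
            cpg_id = next(c for c, g, _ in links if g == gid)
            crow = methylome.cpg_table.set_index("id").loc[cpg_id]
            strand = "+" if rng.random() < 0.5 else "-"
            tss = int(crow["pos"] + rng.integers(-100_000, 100_001))
            if strand == "+":
                start, end = tss, tss + 20_000
            else:
                start, end = tss - 20_000, tss
            rows.append(
                {
                    "chrom": crow["chrom"],
                    "start": max(start, 1),
                    "end": max(end, 1),
                    "strand": strand,
                    "id": gid,
                    "symbol": gid.upper(),
                }
            )
        gene_table = pd.DataFrame(rows)

    n = len(methylome.sample_ids)
    values = rng.normal(0.0, noise_sd, size=(n, len(gene_table)))
    gidx = pd.Index(gene_table["id"])
    for cpg_id, gene_id, slope in links:
        c = cpg_index.get_loc(cpg_id)
        j = gidx.get_loc(gene_id)
        values[:, j] += slope * methylome.betas[:, c]
        if truth is not None:
            truth.gene_links[(cpg_id, gene_id)] = float(slope)
    return ExpressionPanel(list(methylome.sample_ids), gene_table, values)


def define_disease_model(truth: TruthBundle, liability_effects, prevalence,
                         mediation_map=None):
    """Attach a liability-threshold disease model to a truth bundle.

    ``liability_effects`` maps CpG id to its effect per latent unit on the
    liability; ``prevalence`` is the population disease fraction.
    """
    if not (0.0 < prevalence < 1.0):
        raise ConfigurationError("prevalence must be in (0, 1)")
    for cid in liability_effects:
        if cid not in truth.cpg_causal:
            raise ConfigurationError(f"unknown CpG in disease model: {cid}")
    truth.liability_effects = dict(liability_effects)
    truth.prevalence = float(prevalence)
    if mediation_map:
        truth.mediation_map = dict(mediation_map)
    return truth


def _logistic_gwas(dosages, status, chunk=256):
    """Per-variant logistic regression (intercept + dosage), vectorized IRLS.

    Returns (beta, se) arrays for the dosage coefficient (Wald).
    """
    n, m = dosages.shape
    y = status.astype(np.float64)
    beta = np.zeros(m)
    se = np.full(m, np.nan)
    base = np.log(y.mean() / (1.0 - y.mean()))
    for s0 in range(0, m, chunk):
        X = dosages[:, s0 : s0 + chunk]
        k = X.shape[1]
        b0 = np.full(k, base)
        b1 = np.zeros(k)
        ok = X.std(axis=0) > 0
        for _ in range(25):
            eta = b0[None, :] + X * b1[None, :]
            p = expit(eta)
            w = p * (1.0 - p)
            r = y[:, None] - p
            g0 = r.sum(axis=0)
            g1 = (X * r).sum(axis=0)
            h00 = w.sum(axis=0)
            h01 = (w * X).sum(axis=0)
            h11 = (w * X * X).sum(axis=0)
            det = h00 * h11 - h01 * h01
            det = np.where(det > 1e-12, det, np.nan)
            d0 = (h11 * g0 - h01 * g1) / det
            d1 = (h00 * g1 - h01 * g0) / det
            d0 = np.nan_to_num(d0)
            d1 = np.nan_to_num(d1)
            b0 += d0
            b1 += d1
            if max(np.abs(d0).max(initial=0), np.abs(d1).max(initial=0)) < 1e-10:
                break
        eta = b0[None, :] + X * b1[None, :]
        p = expit(eta)
        w = p * (1.0 - p)
        h00 = w.sum(axis=0)
        h01 = (w * X).sum(axis=0)
        h11 = (w * X * X).sum(axis=0)
        det = h00 * h11 - h01 * h01
        with np.errstate(invalid="ignore", divide="ignore"):
            se_chunk = np.sqrt(h00 / det)
        beta[s0 : s0 + chunk] = np.where(ok, b1, 0.0)
        se[s0 : s0 + chunk] = np.where(ok, se_chunk, np.nan)
    return beta, se


def simulate_gwas_summary(
    panel: GenotypePanel,
    truth: TruthBundle,
    n_cases: int,
    n_controls: int,
    seed: int = 0,
    population_multiplier: float = 8.0,
):
    """Case-control GWAS summary statistics under the liability model.

    A fresh population with the panel's LD structure is drawn and each CpG's
    latent value recomputed from its recorded causal effects plus fresh
    noise; liability is the effect-weighted sum of latents plus unit
    Gaussian residual, cases are the top ``prevalence`` fraction, and a
    case-enriched cohort of exactly ``n_cases`` / ``n_controls`` is sampled
    (mimicking consortium oversampling).  Per-variant logistic regression of
    status on dosage yields BETA, SE, P (two-sided Wald), the effect-allele
    frequency FRQ (dosage mean / 2 in the cohort) and N.
    """
    if not truth.has_disease_model:
        raise ConfigurationError("truth bundle has no disease model")
    rng = np.random.default_rng(seed)
    n_pop = int(population_multiplier * (n_cases + n_controls))
    dos = draw_dosages(panel, n_pop, rng)
    vidx = pd.Index(panel.variant_table["id"])

    liab = rng.standard_normal(n_pop)  # unit environmental residual
    for cid, eff in truth.liability_effects.items():
        ids, b = truth.cpg_causal[cid]
        g = dos[:, vidx.get_indexer(ids)] @ b if len(ids) else 0.0
        latent = g + rng.normal(0.0, truth.cpg_noise_sd[cid], size=n_pop)
        liab += eff * latent
    thresh = np.quantile(liab, 1.0 - truth.prevalence)
    case_idx = np.flatnonzero(liab > thresh)
    ctrl_idx = np.flatnonzero(liab <= thresh)
    if case_idx.size < n_cases or ctrl_idx.size < n_controls:
        raise ConfigurationError(
            "insufficient cases/controls sampled; increase population_multiplier"
        )
    take = np.concatenate(
        [
            rng.choice(case_idx, size=n_cases, replace=False),
            rng.choice(ctrl_idx, size=n_controls, replace=False),
        ]
    )
    status = np.zeros(take.size)
    status[:n_cases] = 1.0
    X = dos[take]
    beta, se = _logistic_gwas(X, status)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    p = 2.0 * norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    vt = panel.variant_table
    out = pd.DataFrame(
        {
            "SNP": vt["id"].to_numpy(),
            "CHR": vt["chrom"].to_numpy(),
            "POS": vt["pos"].to_numpy(),
            "A1": vt["effect_allele"].to_numpy(),
            "A2": vt["other_allele"].to_numpy(),
            "FRQ": X.mean(axis=0) / 2.0,
            "BETA": beta,
            "SE": se,
            "P": p,
            "N": n_cases + n_controls,
        }
    )
    return out
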