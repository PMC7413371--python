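"""Approximate conditional analysis, LD scores, heritability, and FRR.

Conditional analysis adjusts each model SNP's GWAS statistic for one index
risk SNP using reference LD (the classic single-SNP approximate-conditional
formula), then re-runs the summary association on the conditional
statistics: an association that survives at the significance threshold is
independent of the known risk variant; one that collapses was mediated by
(or confounded with) it.

Heritability explained by a set of associated CpGs uses the LD-score
regression form Z^2 = 1 + (N_T * l / M) * h^2, where l is the LD score of a
CpG's *predicted* methylation (the sum of squared correlations of its
genetic prediction with those of all associated CpGs, self term included)
computed on a reference cohort, N_T the GWAS sample count and M the number
of associated CpGs.  The familial relative risk explained is h^2 divided by
the trait's total heritability (0.57 for prostate cancer).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from .models import PredictionModel, predict
from .mwas import AssociationResult, LdReference, summary_association
from .synthio import GenotypePanel

__all__ = [
    "ConditionalResult",
    "HeritabilityFit",
    "PipelineConfig",
    "conditional_association",
    "classify_locus_novelty",
    "predicted_meth_ld_scores",
    "estimate_h2_ldsc",
    "frr_explained",
]


@dataclass
class PipelineConfig:
    """Shared downstream constants."""

    prca_heritability: float = 0.57
    significance_threshold: float = 0.05 / 77_243
    novel_distance: int = 500_000
    gwas_n_total: int = 140_306


@dataclass
class ConditionalResult:
    feature_id: str
    index_snp_id: str
    z_marginal: float
    z_conditional: float
    p_conditional: float
    classification: str  # novel-independent | independent-of-known | attenuated | degenerate
    distance_to_index: int | None = None


@dataclass
class HeritabilityFit:
    M: int
    N_T: float
    h2: float
    h2_se: float
    frr_explained: float
    ld_scores: np.ndarray | None = None


def conditional_association(
    model: PredictionModel,
    aligned: pd.DataFrame,
    ld_joint: LdReference,
    index_snp_id: str,
    gwas: pd.DataFrame,
    significance_threshold: float,
    marginal: AssociationResult | None = None,
) -> ConditionalResult:
    """Re-test a predicted feature after conditioning on an index risk SNP.

    For each model SNP j with LD r to the index SNP i:
    ``z_j|i = (z_j - r * z_i) / sqrt(1 - r^2)``; the conditional per-SNP beta
    is ``beta_j - r * (sigma_i / sigma_j) * beta_i`` with the SE chosen so
    that beta/se equals the conditional z.  The summary association is then
    re-run on the conditional statistics.  |r| > 0.999 for any model SNP
    marks the result degenerate (the model is the index signal itself).
    """
    ids = list(ld_joint.variant_ids)
    if index_snp_id not in ids:
        raise KeyError(f"index SNP {index_snp_id} absent from joint LD reference")
    grow = gwas.set_index("SNP")
    if index_snp_id not in grow.index:
        raise KeyError(f"index SNP {index_snp_id} absent from GWAS")
    if marginal is None:
        marginal = summary_association(model, aligned, ld_joint.subset(
            aligned["variant_id"].tolist()))
    i = ids.index(index_snp_id)
    z_i = float(grow.loc[index_snp_id, "BETA"] / grow.loc[index_snp_id, "SE"])
    beta_i = float(grow.loc[index_snp_id, "BETA"])
    sigma_i = float(ld_joint.sd[i])

    midx = [ids.index(v) for v in aligned["variant_id"]]
    r = ld_joint.corr[i, midx]
    if np.any(np.abs(r) > 0.999):
        return ConditionalResult(
            model.feature_id, index_snp_id, marginal.z, 0.0, 1.0, "degenerate"
        )
    zj = aligned["beta"].to_numpy(float) / aligned["se"].to_numpy(float)
    z_cond = (zj - r * z_i) / np.sqrt(1.0 - r**2)
    sigma_j = ld_joint.sd[midx]
    beta_cond = aligned["beta"].to_numpy(float) - r * (sigma_i / np.where(
        sigma_j > 0, sigma_j, 1.0)) * beta_i
    with np.errstate(divide="ignore", invalid="ignore"):
        se_cond = np.where(z_cond != 0, beta_cond / z_cond,
                           aligned["se"].to_numpy(float))
    se_cond = np.where(se_cond > 0, se_cond, aligned["se"].to_numpy(float))
    cond_aligned = aligned.copy()
    cond_aligned["beta"] = np.where(z_cond != 0, beta_cond, 0.0)
    cond_aligned["se"] = se_cond
    cond = summary_association(model, cond_aligned,
                               ld_joint.subset(aligned["variant_id"].tolist()))
    classification = (
        "independent-of-known"
        if np.isfinite(cond.p) and cond.p <= significance_threshold
        else "attenuated"
    )
    return ConditionalResult(
        model.feature_id, index_snp_id, marginal.z, cond.z, cond.p, classification
    )


def classify_locus_novelty(feature_chrom, feature_pos,
                           risk_snps: pd.DataFrame,
                           novel_distance: int = 500_000) -> bool:
    """A locus is novel iff every same-chromosome risk SNP is more than
    ``novel_distance`` bp away (risk SNPs on other chromosomes never veto).

    ``risk_snps`` needs columns chrom, pos.
    """
    if len(risk_snps) == 0:
        warnings.warn("empty risk SNP list: every locus is novel")
        return True
    same = risk_snps[risk_snps["chrom"] == feature_chrom]
    if len(same) == 0:
        return True
    return bool((np.abs(same["pos"].to_numpy() - feature_pos) > novel_distance).all())


def predicted_meth_ld_scores(store: dict, panel: GenotypePanel,
                             include_self: bool = True) -> pd.Series:
    """LD score of each CpG's predicted methylation over the associated set.

    Predictions are computed per reference sample; ``l_c`` is the sum of
    squared Pearson correlations of prediction c with every prediction in
    the set (self term included by default, so l >= 1).  CpGs with constant
    predictions are excluded from the sums with a warning.
    """
    ids = list(store)
    if not ids:
        raise ValueError("empty model store")
    preds = np.column_stack([predict(store[f], panel) for f in ids])
    sd = preds.std(axis=0)
    ok = sd > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} CpG(s) with constant predictions excluded "
            "from LD scores"
        )
    Z = np.zeros_like(preds)
    Z[:, ok] = (preds[:, ok] - preds[:, ok].mean(axis=0)) / sd[ok]
    R = (Z.T @ Z) / preds.shape[0]
    R2 = R**2
    if not include_self:
        np.fill_diagonal(R2, 0.0)
    else:
        np.fill_diagonal(R2, np.where(ok, 1.0, 0.0))
    l = R2[:, ok].sum(axis=1)
    l = np.where(ok, l, np.nan)
    return pd.Series(l, index=ids, name="ld_score")


def estimate_h2_ldsc(z_values, ld_scores, n_total, M=None,
                     intercept_fixed: bool = True) -> HeritabilityFit:
    """Heritability from the regression Z^2 = 1 + (N_T * l / M) * h^2.

    With the intercept fixed at 1 (the default, matching the printed form),
    (Z^2 - 1) is regressed through the origin on x = N_T * l / M; the slope
    is the h^2 estimate and its SE is heteroskedasticity-robust (HC0).  A
    free-intercept variant is available.
    """
    z = np.asarray(z_values, dtype=float)
    l = np.asarray(ld_scores, dtype=float)
    if z.shape != l.shape:
        raise ValueError("z and LD-score vectors must have equal length")
    if M is None:
        M = len(z)
    x = n_total * l / M
    y = z**2 - 1.0
    if intercept_fixed:
        sxx = float((x * x).sum())
        if sxx == 0:
            raise ValueError("all LD scores zero")
        h2 = float((x * y).sum() / sxx)
        resid = y - h2 * x
        se = float(np.sqrt((x**2 * resid**2).sum()) / sxx)
    else:
        X = np.column_stack([np.ones_like(x), x])
        if np.ptp(x) == 0:
            raise ValueError("all x equal: free-intercept fit is rank deficient")
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        h2 = float(coef[1])
        resid = y - X @ coef
        bread = np.linalg.inv(X.T @ X)
        meat = X.T @ (X * (resid**2)[:, None])
        cov = bread @ meat @ bread
        se = float(np.sqrt(cov[1, 1]))
    return HeritabilityFit(M=int(M), N_T=float(n_total), h2=h2, h2_se=se,
                           frr_explained=frr_explained(h2), ld_scores=l)


def frr_explained(h2: float, prca_heritability: float = 0.57) -> float:
    """Fraction of familial relative risk explained: h^2 / 0.57."""
    if prca_heritability <= 0:
        raise ValueError("trait heritability must be positive")
    return h2 / prca_heritability
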