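"""CpG-gene integration: eQTM regression, expression association, triads.

Candidate target genes are genes whose transcription start site lies within
a window (default +/- 500 kb) of an associated CpG.  The eQTM regression is
ordinary least squares of normalized expression on raw methylation beta
values with covariates in the same design (equivalent to double
residualization by Frisch-Waugh, but with correct standard errors);
Benjamini-Hochberg FDR < 0.05 across all tested pairs marks candidate
target genes.  Genes then receive their own cis elastic-net expression
models and summary associations, and a triad (CpG, gene) is
direction-consistent when

    sign(meth -> disease) = sign(meth -> expression) * sign(expression -> disease).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .formats import harmonize_alleles
from .models import TrainingConfig, apply_model_filters, select_cis_variants, train_feature_model
from .mwas import AssociationResult, bh_fdr, summary_association
from .preprocess import covariate_design
from .synthio import ExpressionPanel, GenotypePanel, MethylomePanel

logger = logging.getLogger(__name__)

__all__ = [
    "EqtmResult",
    "TriadRecord",
    "pair_cpg_genes",
    "eqtm_regression",
    "expression_models_and_assoc",
    "triad_consistency",
]


@dataclass
class EqtmResult:
    cpg_id: str
    gene_id: str
    coefficient: float
    se: float
    p: float
    q: float
    n_samples: int
    tissue_label: str = "blood"


@dataclass
class TriadRecord:
    cpg_id: str
    gene_id: str
    sign_meth_disease: int
    sign_meth_expr: int
    sign_expr_disease: int
    consistent: bool
    beta_meth_disease: float
    coef_eqtm: float
    beta_expr_disease: float
    p_meth_disease: float
    p_eqtm: float
    p_expr_disease: float
    flag: str = ""


def gene_tss(gene_row) -> int:
    """Strand-aware transcription start: start for +, end for -."""
    return int(gene_row["start"] if gene_row["strand"] == "+" else gene_row["end"])


def pair_cpg_genes(cpg_table: pd.DataFrame, gene_table: pd.DataFrame,
                   pairing_window: int = 500_000) -> pd.DataFrame:
    """Candidate (cpg_id, gene_id) pairs with TSS within the window."""
    rows = []
    for crow in cpg_table.itertuples(index=False):
        for grow in gene_table.to_dict("records"):
            if grow["chrom"] != crow.chrom:
                continue
            tss = gene_tss(grow)
            if abs(tss - crow.pos) <= pairing_window:
                rows.append({"cpg_id": crow.id, "gene_id": grow["id"],
                             "distance": abs(tss - crow.pos)})
    return pd.DataFrame(rows, columns=["cpg_id", "gene_id", "distance"])


def eqtm_regression(methylome: MethylomePanel, expression: ExpressionPanel,
                    covariates: pd.DataFrame | None, pairs: pd.DataFrame,
                    tissue_label: str = "blood") -> list[EqtmResult]:
    """Per-pair OLS slope of expression on methylation beta, with covariates.

    Methylation enters as raw beta values; expression should be normalized
    upstream.  BH q-values are computed across all tested pairs.  Pairs with
    constant methylation are skipped with a log message.
    """
    cpg_index = pd.Index(methylome.cpg_table["id"])
    gene_index = pd.Index(expression.gene_table["id"])
    if covariates is not None:
        C = covariate_design(covariates).to_numpy(float)
    else:
        C = np.ones((len(methylome.sample_ids), 1))
    results = []
    for rec in pairs.itertuples(index=False):
        ci = cpg_index.get_loc(rec.cpg_id)
        gi = gene_index.get_loc(rec.gene_id)
        beta = methylome.betas[:, ci]
        if np.ptp(beta) == 0:
            logger.warning("eqtm: constant methylation for %s, pair skipped",
                           rec.cpg_id)
            continue
        X = np.column_stack([beta, C])
        fit = sm.OLS(expression.values[:, gi], X).fit()
        results.append(
            EqtmResult(rec.cpg_id, rec.gene_id, float(fit.params[0]),
                       float(fit.bse[0]), float(fit.pvalues[0]), np.nan,
                       n_samples=len(beta), tissue_label=tissue_label)
        )
    if results:
        q = bh_fdr([r.p for r in results])
        for r, qv in zip(results, q):
            r.q = float(qv)
    return results


def expression_models_and_assoc(
    expression: ExpressionPanel,
    panel: GenotypePanel,
    gwas: pd.DataFrame,
    ld_panel: GenotypePanel,
    cfg: TrainingConfig | None = None,
    gene_ids=None,
) -> tuple[dict, list[AssociationResult]]:
    """Train cis expression models and run their summary associations.

    Reuses the methylation machinery with a TSS-centered cis window and the
    same R^2 >= 0.01 retention rule; BH FDR is computed across tested genes.
    Returns ``(retained model store, association results)``.
    """
    from .mwas import build_ld_reference

    cfg = cfg or TrainingConfig()
    gt = expression.gene_table
    if gene_ids is not None:
        gt = gt[gt["id"].isin(gene_ids)]
    models = {}
    for j, grow in gt.iterrows():
        tss = gene_tss(grow)
        cis = select_cis_variants(grow["chrom"], tss, panel, cfg.window_halfwidth)
        if cis.size == 0:
            logger.warning("gene %s: no cis variants, skipped", grow["id"])
            continue
        col = expression.gene_table.index.get_loc(j)
        models[grow["id"]] = train_feature_model(
            grow["id"],
            expression.values[:, col],
            panel.dosages[:, cis],
            panel.variant_table.iloc[cis],
            cfg,
            feature_type="gene",
            chrom=grow["chrom"],
            pos=tss,
        )
    retained, _ = apply_model_filters(models, None, cfg.r2_threshold)
    results = []
    for gid, m in retained.items():
        aligned, _ = harmonize_alleles(m.weights, gwas)
        ld = build_ld_reference(ld_panel, aligned["variant_id"].tolist()) \
            if len(aligned) else None
        if ld is None:
            continue
        results.append(summary_association(m, aligned, ld))
    ps = [r.p for r in results if np.isfinite(r.p)]
    qmap = dict(zip([r.feature_id for r in results if np.isfinite(r.p)],
                    bh_fdr(ps))) if ps else {}
    for r in results:
        r.flag = r.flag or ""
        r.q = qmap.get(r.feature_id, np.nan)  # attribute attached dynamically
    return retained, results


def _sign(x: float, tol: float = 1e-12) -> int:
    if not np.isfinite(x) or abs(x) < tol:
        return 0
    return 1 if x > 0 else -1


def triad_consistency(meth_disease: AssociationResult, eqtm: EqtmResult,
                      expr_disease: AssociationResult) -> TriadRecord:
    """Direction-consistency of one CpG-gene-disease triad.

    Consistent iff sign(log OR meth) = sign(eQTM slope) * sign(log OR expr);
    a zero (|effect| < 1e-12) in any leg yields consistent=False with an
    "indeterminate" flag.
    """
    s_md = _sign(meth_disease.beta_per_sd)
    s_me = _sign(eqtm.coefficient)
    s_ed = _sign(expr_disease.beta_per_sd)
    if 0 in (s_md, s_me, s_ed):
        consistent, flag = False, "indeterminate"
    else:
        consistent, flag = s_md == s_me * s_ed, ""
    return TriadRecord(
        cpg_id=eqtm.cpg_id,
        gene_id=eqtm.gene_id,
        sign_meth_disease=s_md,
        sign_meth_expr=s_me,
        sign_expr_disease=s_ed,
        consistent=consistent,
        beta_meth_disease=meth_disease.beta_per_sd,
        coef_eqtm=eqtm.coefficient,
        beta_expr_disease=expr_disease.beta_per_sd,
        p_meth_disease=meth_disease.p,
        p_eqtm=eqtm.p,
        p_expr_disease=expr_disease.p,
        flag=flag,
    )
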