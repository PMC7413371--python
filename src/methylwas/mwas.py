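"""Predicted-feature vs disease association from GWAS summary statistics.

The core statistic tests a weighted SNP score (the genetically predicted
feature) against a trait using only per-SNP GWAS results plus a reference
panel for SNP variances and LD:

    z = sum_l w_l * (sigma_l / sigma_g) * (beta_l / se_l)

with sigma_g^2 = w' diag(sigma) R diag(sigma) w from the reference panel.
The per-SD log-odds is beta_per_sd = sum_l w_l sigma_l^2 beta_l / sigma_g.
An individual-level regression oracle is provided for cross-checks, along
with Bonferroni and Benjamini-Hochberg multiple-testing helpers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .models import PredictionModel
from .synthio import GWAS_COLUMNS, GenotypePanel

__all__ = [
    "LdReference",
    "AssociationResult",
    "build_ld_reference",
    "summary_association",
    "individual_level_association",
    "linear_gwas",
    "bonferroni_threshold",
    "bh_fdr",
]


@dataclass
class LdReference:
    """Reference-panel SNP dosage SDs and correlation matrix."""

    variant_ids: list
    sd: np.ndarray
    corr: np.ndarray
    n_ref: int

    def subset(self, ids):
        idx = pd.Index(self.variant_ids).get_indexer(ids)
        if (idx < 0).any():
            missing = [i for i, j in zip(ids, idx) if j < 0]
            raise KeyError(f"variants absent from LD reference: {missing[:5]}")
        return LdReference(
            list(ids), self.sd[idx], self.corr[np.ix_(idx, idx)], self.n_ref
        )


@dataclass
class AssociationResult:
    """Association of one predicted feature with the trait."""

    feature_id: str
    z: float
    beta_per_sd: float
    p: float
    n_snps_used: int
    sigma_feature: float
    flag: str = ""

    @property
    def or_per_sd(self) -> float:
        return float(np.exp(self.beta_per_sd))


def build_ld_reference(panel: GenotypePanel, variant_ids=None,
                       shrink_eps: float = 1e-3) -> LdReference:
    """SD and correlation of reference dosages, with PSD regularization.

    Monomorphic variants keep sd = 0 and are flagged by downstream callers.
    If the correlation matrix has an eigenvalue below 1e-8, off-diagonals
    are shrunk by (1 - shrink_eps).
    """
    if panel.n_samples < 2:
        raise ValueError("LD reference needs at least 2 samples")
    if variant_ids is None:
        D = panel.dosages
        ids = list(panel.variant_table["id"])
    else:
        idx = panel.variant_index(variant_ids)
        if (idx < 0).any():
            raise KeyError("requested variants absent from panel")
        D = panel.dosages[:, idx]
        ids = list(variant_ids)
    sd = D.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(D)
    Z[:, ok] = (D[:, ok] - D[:, ok].mean(axis=0)) / sd[ok]
    corr = (Z.T @ Z) / D.shape[0]
    np.fill_diagonal(corr, 1.0)
    if np.linalg.eigvalsh(corr).min() < 1e-8:
        off = corr - np.eye(len(ids))
        corr = np.eye(len(ids)) + (1.0 - shrink_eps) * off
    return LdReference(ids, sd, corr, panel.n_samples)


def summary_association(model: PredictionModel, aligned: pd.DataFrame,
                        ld: LdReference) -> AssociationResult:
    """Summary-statistic association of a predicted feature with the trait.

    ``aligned`` is the harmonized effect table from
    :func:`methylwas.formats.harmonize_alleles` (columns variant_id, weight,
    beta, se).  Model variants absent from the GWAS are dropped and the
    feature variance recomputed over the survivors.
    """
    fid = model.feature_id
    if len(aligned) == 0:
        return AssociationResult(fid, np.nan, np.nan, np.nan, 0, 0.0,
                                 flag="no-variants")
    sub = ld.subset(aligned["variant_id"].tolist())
    w = aligned["weight"].to_numpy(float)
    sigma = sub.sd
    usable = sigma > 0
    if not usable.all():
        w = w * usable  # monomorphic reference variants contribute nothing
    ws = w * sigma
    var_g = float(ws @ sub.corr @ ws)
    if var_g <= 0 or not np.isfinite(var_g):
        return AssociationResult(fid, np.nan, np.nan, np.nan, int(usable.sum()),
                                 0.0, flag="degenerate-variance")
    sigma_g = np.sqrt(var_g)
    zl = aligned["beta"].to_numpy(float) / aligned["se"].to_numpy(float)
    z = float((w * sigma * zl).sum() / sigma_g)
    beta_per_sd = float(
        (w * sigma**2 * aligned["beta"].to_numpy(float)).sum() / sigma_g
    )
    p = float(2.0 * norm.sf(abs(z)))
    p = max(p, np.finfo(float).tiny)
    return AssociationResult(fid, z, beta_per_sd, p, int(usable.sum()), sigma_g)


def linear_gwas(panel: GenotypePanel, phenotype: np.ndarray) -> pd.DataFrame:
    """Per-variant linear GWAS in the large-sample score convention.

    beta_l is the OLS slope of the phenotype on each dosage; its standard
    error uses the total phenotypic variance, se = sd(y) / (sd(x) sqrt(n))
    (population ddof), the first-order convention of large GWAS.  With this
    convention the summary-statistic z is algebraically identical to the
    individual-level score z when the reference panel is the GWAS cohort.
    """
    D = panel.dosages
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    yc = y - y.mean()
    sd_y = y.std()
    mu = D.mean(axis=0)
    sd_x = D.std(axis=0)
    sd_x_safe = np.where(sd_x > 0, sd_x, 1.0)
    cov = (D - mu).T @ yc / n
    beta = cov / sd_x_safe**2
    se = sd_y / (sd_x_safe * np.sqrt(n))
    with np.errstate(invalid="ignore"):
        z = beta / se
    p = np.clip(2.0 * norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    vt = panel.variant_table
    out = pd.DataFrame(
        {
            "SNP": vt["id"].to_numpy(),
            "CHR": vt["chrom"].to_numpy(),
            "POS": vt["pos"].to_numpy(),
            "A1": vt["effect_allele"].to_numpy(),
            "A2": vt["other_allele"].to_numpy(),
            "FRQ": mu / 2.0,
            "BETA": np.where(sd_x > 0, beta, 0.0),
            "SE": np.where(sd_x > 0, se, np.nan),
            "P": p,
            "N": n,
        }
    )[GWAS_COLUMNS]
    return out


def individual_level_association(model: PredictionModel, panel: GenotypePanel,
                                 phenotype: np.ndarray, family: str = "continuous",
                                 covariates: pd.DataFrame | None = None
                                 ) -> AssociationResult:
    """Individual-level oracle: regress the phenotype on the standardized
    genetic prediction (plus caller-supplied covariates).

    For ``family="continuous"`` without covariates the z statistic uses the
    score convention (se from total phenotypic variance, population ddof) so
    that it matches :func:`summary_association` exactly on shared data; with
    covariates an OLS fit is used.  ``family="binary"`` fits a logistic
    regression by MLE.
    """
    from .models import predict

    y = np.asarray(phenotype, dtype=float)
    g = predict(model, panel)
    if np.std(g) == 0:
        raise ValueError("degenerate predictor: constant genetic prediction")
    gs = (g - g.mean()) / g.std()
    if family == "continuous" and covariates is None:
        n = len(y)
        r = float(np.dot(gs, y - y.mean()) / (n * y.std()))
        beta = r * y.std()
        se = y.std() / np.sqrt(n)
        z = beta / se
    else:
        X = np.column_stack([np.ones_like(gs), gs])
        names = ["const", "pred"]
        if covariates is not None:
            X = np.column_stack([X, covariates.to_numpy(float)])
            names += list(covariates.columns)
        if family == "continuous":
            fit = sm.OLS(y, X).fit()
        elif family == "binary":
            fit = sm.Logit(y, X).fit(disp=0)
        else:
            raise ValueError(f"unknown family {family!r}")
        beta = float(fit.params[1])
        se = float(fit.bse[1])
        z = beta / se
    p = max(float(2.0 * norm.sf(abs(z))), np.finfo(float).tiny)
    return AssociationResult(model.feature_id, float(z), float(beta), p,
                             len(model.weights), float(np.std(g)))


def bonferroni_threshold(n_tests: int, fwer: float = 0.05) -> float:
    """Family-wise threshold fwer / n_tests (0.05/77,243 = 6.47e-7)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return fwer / n_tests


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone nondecreasing in p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]
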