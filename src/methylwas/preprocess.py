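"""Matrix normalization, covariate residualization, and variant filters.

The fixed order of operations before model training is: quantile
normalization across samples (bringing every sample's methylation profile to
the same scale), rank-based inverse-normal transformation per CpG, then
least-squares residualization on covariates (age, sex, cell-type fractions
with one dropped against the sum-to-one constraint, genotype principal
components).  The elastic net then sees only SNP predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.stats import norm, rankdata

from .synthio import GenotypePanel

__all__ = [
    "VariantFilterConfig",
    "quantile_normalize_samples",
    "rank_inverse_normal",
    "covariate_design",
    "residualize",
    "compute_pcs",
    "filter_variants",
]


@dataclass
class VariantFilterConfig:
    """Variant inclusion thresholds applied before model training."""

    min_imputation_r2: float = 0.8
    min_maf: float = 0.05
    require_panel_subset: list | None = None
    drop_strand_ambiguous: bool = True


_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


def quantile_normalize_samples(matrix: np.ndarray) -> np.ndarray:
    """Quantile-normalize rows (samples) to a common reference distribution.

    The reference is the across-sample mean of the sorted values; each
    sample's values are replaced by the reference evaluated at their
    (average, for ties) ranks, so tied entries receive the mean of the
    reference values they span.
    """
    matrix = np.asarray(matrix, dtype=float)
    n, m = matrix.shape
    if n == 1:
        warnings.warn("single-sample matrix: quantile normalization is the identity")
        return matrix.copy()
    reference = np.sort(matrix, axis=1).mean(axis=0)
    out = np.empty_like(matrix)
    grid = np.arange(1, m + 1, dtype=float)
    for i in range(n):
        ranks = rankdata(matrix[i], method="average")
        out[i] = np.interp(ranks, grid, reference)
    return out


def rank_inverse_normal(matrix: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform of each column (feature).

    ``value_i = Phi^-1((rank_i - offset) / (n - 2*offset + 1))`` with average
    ranks for ties; the default offset 3/8 is the Blom convention.  Constant
    columns become all zeros with a warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    n, m = matrix.shape
    if n < 3:
        raise ValueError("rank_inverse_normal needs at least 3 samples")
    out = np.empty_like(matrix)
    denom = n - 2.0 * offset + 1.0
    n_const = 0
    for j in range(m):
        col = matrix[:, j]
        if np.ptp(col) == 0:
            out[:, j] = 0.0
            n_const += 1
            continue
        ranks = rankdata(col, method="average")
        out[:, j] = norm.ppf((ranks - offset) / denom)
    if n_const:
        warnings.warn(f"rank_inverse_normal: {n_const} constant feature(s) set to zero")
    return out


def covariate_design(covariates: pd.DataFrame, drop_cell: str = "cell6") -> pd.DataFrame:
    """Design matrix from a covariate table: intercept + covariates.

    One cell-type fraction column is dropped to avoid the sum-to-one
    singularity.
    """
    X = covariates.drop(columns=[drop_cell], errors="ignore").copy()
    X.insert(0, "intercept", 1.0)
    return X


def _collinear_columns(X: np.ndarray, names) -> list:
    r = np.linalg.matrix_rank(X)
    if r == X.shape[1]:
        return []
    _, _, piv = qr(X, mode="economic", pivoting=True)
    return [names[i] for i in sorted(piv[r:])]


def residualize(matrix: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """Replace each feature by its least-squares residual on the covariates.

    The design is intercept + covariates (see :func:`covariate_design`);
    residuals are orthogonal to every design column.  A rank-deficient
    design raises an error naming the collinear columns.
    """
    matrix = np.asarray(matrix, dtype=float)
    X = covariate_design(covariates)
    names = list(X.columns)
    Xv = X.to_numpy(float)
    bad = _collinear_columns(Xv, names)
    if bad:
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    Q, _ = np.linalg.qr(Xv)
    return matrix - Q @ (Q.T @ matrix)


def compute_pcs(panel: GenotypePanel, k: int) -> pd.DataFrame:
    """Top-k genotype principal components (unit variance, orthogonal).

    Columns are the leading left singular directions of the
    column-standardized dosage matrix.
    """
    if k == 0:
        return pd.DataFrame(index=pd.Index(panel.sample_ids, name="sample_id"))
    D = panel.dosages
    if k > min(D.shape):
        raise ValueError("k exceeds min(n_samples, n_variants)")
    mu = D.mean(axis=0)
    sd = D.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (D - mu) / sd
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    pcs = U[:, :k]
    pcs = pcs / pcs.std(axis=0)
    return pd.DataFrame(
        pcs,
        index=pd.Index(panel.sample_ids, name="sample_id"),
        columns=[f"pc{i + 1}" for i in range(k)],
    )


def filter_variants(panel: GenotypePanel, cfg: VariantFilterConfig) -> GenotypePanel:
    """Apply imputation-quality, MAF, panel-subset and strand filters.

    Per-criterion exclusion counts are attached to the returned panel's
    variant table attrs under ``"filter_counts"``.  Raises if no variant
    survives.
    """
    vt = panel.variant_table
    keep = np.ones(len(vt), dtype=bool)
    counts = {}
    m = vt["imputation_quality"].to_numpy() >= cfg.min_imputation_r2
    counts["imputation_quality"] = int((~m & keep).sum())
    keep &= m
    maf = vt["maf"].to_numpy()
    maf = np.minimum(maf, 1.0 - maf)
    m = maf >= cfg.min_maf
    counts["maf"] = int((~m & keep).sum())
    keep &= m
    if cfg.require_panel_subset is not None:
        m = vt["id"].isin(cfg.require_panel_subset).to_numpy()
        counts["panel_subset"] = int((~m & keep).sum())
        keep &= m
    if cfg.drop_strand_ambiguous:
        amb = np.array(
            [
                frozenset((str(a).upper(), str(b).upper())) in _AMBIGUOUS
                for a, b in zip(vt["effect_allele"], vt["other_allele"])
            ]
        )
        counts["strand_ambiguous"] = int((amb & keep).sum())
        keep &= ~amb
    if not keep.any():
        raise ValueError("no variants survive filtering; cannot train any model")
    new_table = vt[keep].reset_index(drop=True)
    new_table.attrs["filter_counts"] = counts
    return GenotypePanel(
        list(panel.sample_ids),
        new_table,
        panel.dosages[:, keep],
        dict(panel.block_corr),
    )
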