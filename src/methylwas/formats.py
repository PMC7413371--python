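"""On-disk formats: GWAS summary tables, model stores, coordinate tables.

All positions are 1-based inclusive (build-37 convention).  The canonical
GWAS dialect is the tab-separated header ``SNP CHR POS A1 A2 FRQ BETA SE P
N`` (A1 = effect allele); foreign dialects are mapped through a column-name
dictionary.  Prediction models persist as a diff-friendly TSV pair: one
weights row per (feature, variant) plus a per-feature extras table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthio import GWAS_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "HarmonizationReport",
    "read_gwas_summary",
    "write_gwas_summary",
    "harmonize_alleles",
    "write_model_store",
    "read_model_store",
    "write_cpg_table",
    "read_cpg_table",
]

_REQUIRED = ["SNP", "A1", "A2", "BETA", "SE", "P"]
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


class SchemaError(ValueError):
    """A required column could not be resolved in an input table."""


@dataclass
class HarmonizationReport:
    """Outcome counts of aligning model variants against a GWAS table."""

    matched: int = 0
    sign_flipped: int = 0
    strand_ambiguous_dropped: int = 0
    allele_mismatch_dropped: int = 0
    absent_from_gwas: int = 0
    duplicate_dropped: int = 0

    @property
    def total(self) -> int:
        return (
            self.matched
            + self.sign_flipped
            + self.strand_ambiguous_dropped
            + self.allele_mismatch_dropped
            + self.absent_from_gwas
        )


def read_gwas_summary(path, dialect_config: dict | None = None) -> pd.DataFrame:
    """Read a GWAS summary-statistics TSV into the canonical dialect.

    ``dialect_config`` maps canonical column names (``SNP``, ``CHR``,
    ``POS``, ``A1``, ``A2``, ``FRQ``, ``BETA``, ``SE``, ``P``, ``N``) to the
    names used in the file.  Rows with missing beta/se, nonpositive se or p
    outside (0, 1] are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str})
    if dialect_config:
        rename = {v: k for k, v in dialect_config.items()}
        df = df.rename(columns=rename)
    for col in _REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} not found in {path}")
    for col in ["FRQ", "N", "CHR", "POS"]:
        if col not in df.columns:
            df[col] = np.nan
    df = df[[c for c in GWAS_COLUMNS if c in df.columns]]
    n0 = len(df)
    df = df.dropna(subset=["BETA", "SE"])
    df = df[(df["SE"] > 0) & (df["P"] > 0) & (df["P"] <= 1)]
    dropped = n0 - len(df)
    if dropped:
        logger.warning("read_gwas_summary: dropped %d invalid rows", dropped)
    return df.reset_index(drop=True)


def write_gwas_summary(gwas: pd.DataFrame, path) -> None:
    gwas.to_csv(path, sep="\t", index=False, float_format="%.8g")


def _is_ambiguous(a1, a2) -> bool:
    return frozenset((str(a1).upper(), str(a2).upper())) in _AMBIGUOUS


def harmonize_alleles(model_weights: pd.DataFrame, gwas: pd.DataFrame,
                      drop_ambiguous: bool = True):
    """Align GWAS effects to model effect alleles.

    ``model_weights`` needs columns variant_id, effect_allele, other_allele,
    weight.  Variants are matched by id first (falling back to chrom:pos when
    both tables carry coordinates).  When the GWAS alleles are swapped
    relative to the model, beta is sign-flipped and freq becomes 1 - freq;
    A/T and C/G pairs are dropped when ``drop_ambiguous``; other mismatches
    are dropped.  Returns ``(aligned table, HarmonizationReport)`` where the
    aligned table has columns variant_id, effect_allele, other_allele,
    weight, beta, se, p, freq, n.
    """
    g = gwas.drop_duplicates(subset="SNP", keep="first")
    if len(g) < len(gwas):
        logger.warning(
            "harmonize_alleles: %d duplicate GWAS ids dropped after the first",
            len(gwas) - len(g),
        )
    g = g.set_index("SNP")
    report = HarmonizationReport(duplicate_dropped=len(gwas) - len(g))
    rows = []
    for rec in model_weights.itertuples(index=False):
        m_a1 = str(rec.effect_allele).upper()
        m_a2 = str(rec.other_allele).upper()
        if drop_ambiguous and _is_ambiguous(m_a1, m_a2):
            report.strand_ambiguous_dropped += 1
            continue
        if rec.variant_id not in g.index:
            report.absent_from_gwas += 1
            continue
        grow = g.loc[rec.variant_id]
        g_a1 = str(grow["A1"]).upper()
        g_a2 = str(grow["A2"]).upper()
        beta = float(grow["BETA"])
        freq = float(grow["FRQ"]) if "FRQ" in g.columns else np.nan
        if (g_a1, g_a2) == (m_a1, m_a2):
            report.matched += 1
        elif (g_a1, g_a2) == (m_a2, m_a1):
            beta = -beta
            freq = 1.0 - freq if np.isfinite(freq) else freq
            report.sign_flipped += 1
        else:
            report.allele_mismatch_dropped += 1
            continue
        rows.append(
            {
                "variant_id": rec.variant_id,
                "effect_allele": m_a1,
                "other_allele": m_a2,
                "weight": float(rec.weight),
                "beta": beta,
                "se": float(grow["SE"]),
                "p": float(grow["P"]),
                "freq": freq,
                "n": float(grow["N"]) if "N" in g.columns else np.nan,
            }
        )
    cols = ["variant_id", "effect_allele", "other_allele", "weight",
            "beta", "se", "p", "freq", "n"]
    aligned = pd.DataFrame(rows, columns=cols)
    return aligned, report


# ---------------------------------------------------------------------------
# model store


def write_model_store(store: dict, prefix) -> None:
    """Persist models as ``<prefix>.weights.tsv`` + ``<prefix>.extra.tsv``.

    ``store`` maps feature_id to a :class:`~methylwas.models.PredictionModel`
    (or any object with the same attributes).  Features are written in
    sorted id order for stable diffs.
    """
    prefix = Path(prefix)
    wrows, erows = [], []
    for fid in sorted(store):
        m = store[fid]
        for rec in m.weights.itertuples(index=False):
            wrows.append(
                {
                    "feature_id": fid,
                    "variant_id": rec.variant_id,
                    "effect_allele": rec.effect_allele,
                    "other_allele": rec.other_allele,
                    "weight": repr(float(rec.weight)),
                }
            )
        erows.append(
            {
                "feature_id": fid,
                "feature_type": m.feature_type,
                "chrom": m.chrom,
                "pos": m.pos,
                "cv_r2": repr(float(m.cv_r2)),
                "lambda_selected": repr(float(m.lambda_selected)),
                "n_snps": len(m.weights),
                "passed_filters": m.passed_filters,
                "filter_reasons": ";".join(m.filter_reasons) or ".",
            }
        )
    wcols = ["feature_id", "variant_id", "effect_allele", "other_allele", "weight"]
    ecols = ["feature_id", "feature_type", "chrom", "pos", "cv_r2",
             "lambda_selected", "n_snps", "passed_filters", "filter_reasons"]
    pd.DataFrame(wrows, columns=wcols).to_csv(
        Path(str(prefix) + ".weights.tsv"), sep="\t", index=False
    )
    pd.DataFrame(erows, columns=ecols).to_csv(
        Path(str(prefix) + ".extra.tsv"), sep="\t", index=False
    )


def read_model_store(prefix) -> dict:
    """Reload a model store written by :func:`write_model_store`."""
    from .models import PredictionModel  # deferred to avoid a cycle

    prefix = Path(prefix)
    try:
        wdf = pd.read_csv(Path(str(prefix) + ".weights.tsv"), sep="\t")
        edf = pd.read_csv(Path(str(prefix) + ".extra.tsv"), sep="\t")
    except (pd.errors.ParserError, OSError) as exc:
        raise ValueError(f"cannot parse model store at {prefix}: {exc}") from exc
    store = {}
    groups = dict(iter(wdf.groupby("feature_id"))) if len(wdf) else {}
    for rec in edf.itertuples(index=False):
        w = groups.get(
            rec.feature_id,
            pd.DataFrame(columns=["variant_id", "effect_allele", "other_allele", "weight"]),
        )
        store[rec.feature_id] = PredictionModel(
            feature_id=rec.feature_id,
            feature_type=rec.feature_type,
            chrom=rec.chrom,
            pos=int(rec.pos),
            weights=w[["variant_id", "effect_allele", "other_allele", "weight"]]
            .astype({"weight": float})
            .reset_index(drop=True),
            cv_r2=float(rec.cv_r2),
            lambda_selected=float(rec.lambda_selected),
            passed_filters=bool(rec.passed_filters),
            filter_reasons=[]
            if rec.filter_reasons == "."
            else str(rec.filter_reasons).split(";"),
        )
    return store


def write_cpg_table(cpg_table: pd.DataFrame, path) -> None:
    """BED-like CpG coordinate file with an explicit 1-based position column."""
    with open(path, "w") as fh:
        fh.write("# pos_1based: positions are 1-based inclusive, not half-open BED\n")
        cpg_table.rename(columns={"pos": "pos_1based"}).to_csv(
            fh, sep="\t", index=False
        )


def read_cpg_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.rename(columns={"pos_1based": "pos"})
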