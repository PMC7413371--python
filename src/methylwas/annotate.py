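"""Genomic-region classification of CpG sites and category enrichment.

CpGs are assigned exactly one of 13 region categories from a refFlat-style
transcript model: exonic, splicing, ncRNA_exonic, ncRNA_intronic, UTR5,
UTR3, intronic, upstream, downstream, upstream;downstream, UTR5;UTR3,
exonic;splicing, intergenic.  All coordinates are 1-based inclusive.

Per-transcript labels are resolved across overlapping transcripts with a
fixed precedence (combination categories first, then exonic, UTRs, introns,
then flanking regions, then intergenic), so the assignment is deterministic.
Category enrichment between associated and non-associated tested CpGs uses
a per-category 2x2 Pearson chi-square without continuity correction, with an
exact-test fallback when an expected cell drops below 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "AnnotationRecord",
    "classify_region",
    "annotate_cpgs",
    "category_enrichment",
    "make_gene_model",
]

CATEGORIES = [
    "exonic", "intronic", "intergenic", "upstream", "UTR3", "UTR5",
    "ncRNA_intronic", "ncRNA_exonic", "splicing", "downstream",
    "upstream;downstream", "UTR5;UTR3", "exonic;splicing",
]

# resolution order across transcripts (first match wins)
_PRECEDENCE = [
    "exonic;splicing", "splicing", "exonic", "UTR5;UTR3", "UTR5", "UTR3",
    "ncRNA_exonic", "intronic", "ncRNA_intronic",
    "upstream;downstream", "upstream", "downstream", "intergenic",
]


@dataclass
class AnnotationRecord:
    cpg_id: str
    category: str


def make_gene_model(rows) -> pd.DataFrame:
    """Transcript table from dict rows.

    Required keys: chrom, strand, tx_start, tx_end, cds_start, cds_end,
    exon_starts (list), exon_ends (list), gene_id, coding_flag.  For
    non-coding transcripts set cds_start > cds_end (empty CDS).
    """
    df = pd.DataFrame(rows)
    for rec in df.itertuples(index=False):
        for s, e in zip(rec.exon_starts, rec.exon_ends):
            if not (rec.tx_start <= s <= e <= rec.tx_end):
                raise ValueError(f"exon [{s},{e}] outside transcript bounds")
    return df


def _transcript_label(pos, tx, flank, splice_margin):
    """Label of one position relative to one transcript (or None)."""
    s, e = tx.tx_start, tx.tx_end
    if pos < s - flank or pos > e + flank:
        return None
    if pos < s:
        return "upstream" if tx.strand == "+" else "downstream"
    if pos > e:
        return "downstream" if tx.strand == "+" else "upstream"
    exons = list(zip(tx.exon_starts, tx.exon_ends))
    in_exon = None
    for es, ee in exons:
        if es <= pos <= ee:
            in_exon = (es, ee)
            break
    coding = bool(tx.coding_flag) and tx.cds_start <= tx.cds_end
    # splice-site proximity uses internal exon boundaries only
    internal = []
    for k, (es, ee) in enumerate(exons):
        if k > 0:
            internal.append(es)
        if k < len(exons) - 1:
            internal.append(ee)
    near_splice = any(abs(pos - b) <= splice_margin for b in internal)
    if in_exon is not None:
        if not coding:
            return "ncRNA_exonic"
        if near_splice:
            return "exonic;splicing"
        if pos < tx.cds_start:
            return "UTR5" if tx.strand == "+" else "UTR3"
        if pos > tx.cds_end:
            return "UTR3" if tx.strand == "+" else "UTR5"
        return "exonic"
    # intron
    if not coding:
        return "ncRNA_intronic"
    if near_splice:
        return "splicing"
    return "intronic"


def classify_region(cpg_id, chrom, pos, gene_model: pd.DataFrame,
                    flank: int = 1000, splice_margin: int = 2) -> AnnotationRecord:
    """Assign exactly one of the 13 region categories to a CpG."""
    labels = set()
    model_chroms = set(gene_model["chrom"])
    if chrom not in model_chroms:
        logger.warning("CpG %s: contig %s absent from gene model", cpg_id, chrom)
        return AnnotationRecord(cpg_id, "intergenic")
    for tx in gene_model[gene_model["chrom"] == chrom].itertuples(index=False):
        lab = _transcript_label(pos, tx, flank, splice_margin)
        if lab is not None:
            labels.add(lab)
    if {"upstream", "downstream"} <= labels:
        labels.add("upstream;downstream")
    if {"UTR5", "UTR3"} <= labels:
        labels.add("UTR5;UTR3")
    if {"exonic", "splicing"} <= labels:
        labels.add("exonic;splicing")
    for cat in _PRECEDENCE:
        if cat in labels:
            return AnnotationRecord(cpg_id, cat)
    return AnnotationRecord(cpg_id, "intergenic")


def annotate_cpgs(cpg_table: pd.DataFrame, gene_model: pd.DataFrame,
                  flank: int = 1000, splice_margin: int = 2) -> pd.DataFrame:
    recs = [
        classify_region(r.id, r.chrom, r.pos, gene_model, flank, splice_margin)
        for r in cpg_table.itertuples(index=False)
    ]
    return pd.DataFrame({"cpg_id": [r.cpg_id for r in recs],
                         "category": [r.category for r in recs]})


def category_enrichment(associated: pd.DataFrame, tested: pd.DataFrame,
                        disjoint: bool = True) -> pd.DataFrame:
    """Per-category 2x2 chi-square of associated vs tested CpGs.

    ``associated`` and ``tested`` are annotation frames (cpg_id, category)
    with associated a subset of tested.  By default the contrast is
    associated vs the complement (tested minus associated), which keeps the
    two groups disjoint; ``disjoint=False`` contrasts against the full
    tested set as a whole.  Pearson chi-square without continuity
    correction; if any expected cell is below 1 an exact test is used and
    logged.
    """
    assoc_ids = set(associated["cpg_id"])
    if not assoc_ids <= set(tested["cpg_id"]):
        raise ValueError("associated CpGs must be a subset of tested CpGs")
    if disjoint:
        other = tested[~tested["cpg_id"].isin(assoc_ids)]
    else:
        other = tested
    n_a, n_o = len(associated), len(other)
    rows = []
    for cat in CATEGORIES:
        a = int((associated["category"] == cat).sum())
        o = int((other["category"] == cat).sum())
        table = np.array([[a, n_a - a], [o, n_o - o]])
        if table.sum() == 0 or a + o == 0:
            chi2, p = 0.0, 1.0
        else:
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            if expected.min() < 1:
                _, p = fisher_exact(table)
                chi2 = np.nan
                logger.info("category %s: exact test fallback", cat)
            else:
                chi2, p, _, _ = chi2_contingency(table, correction=False)
        rows.append(
            {"category": cat, "n_assoc": a, "n_other": o,
             "prop_assoc": a / n_a if n_a else 0.0,
             "prop_tested": o / n_o if n_o else 0.0,
             "chi2": chi2, "p": p}
        )
    return pd.DataFrame(rows)
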