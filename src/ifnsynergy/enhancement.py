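"""Enhancement scores for GAF/ISGF3 synergy and quartile comparisons.

The Enhancement score of a gene from the mixing experiment (low-dose IFN-β,
low-dose IFN-γ, and their mixture) is

    ES = (RPKM_mixed + 1) / ((RPKM_beta + 1) + (RPKM_gamma + 1))

with the 1 RPKM pseudocount added to each term independently, so that the
additive null (mixed response = sum of the single-stimulus responses) maps
to ES ≈ 1 and supra-additive (synergistic) induction gives ES > 1.  ISGs are
partitioned into TOP/BOTTOM quartiles of ES (q = ceil(n/4) genes each) and
the quartiles are compared on basal expression, promoter GC content and
promoter-peak presence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ifnsynergy.errors import ValidationError
from ifnsynergy.io import FastaStore, GC_WINDOW
from ifnsynergy.stats import TestResult, fisher_exact, rank_sum_test


def enhancement_score(rpkm_mixed, rpkm_beta, rpkm_gamma, pseudocount: float = 1.0):
    """ES = (mixed + c) / ((beta + c) + (gamma + c)); vectorized."""
    return (rpkm_mixed + pseudocount) / (
        (rpkm_beta + pseudocount) + (rpkm_gamma + pseudocount)
    )


def quartile_partition(scores: pd.Series) -> tuple[pd.Series, dict[str, float]]:
    """Assign TOP / BOTTOM / MID quartile labels by Enhancement score.

    q = ceil(n/4) genes in each of TOP (highest scores) and BOTTOM (lowest);
    ties break by gene id.  Returns the labels and the boundary thresholds
    (lowest TOP score, highest BOTTOM score).
    """
    n = len(scores)
    if n < 4:
        raise ValidationError("quartile partition requires >= 4 records")
    if not np.isfinite(scores.to_numpy(dtype=float)).all():
        raise ValidationError("scores must be finite")
    q = math.ceil(n / 4)
    # two-key sort: ascending score, ties by gene id
    order = scores.iloc[np.lexsort((scores.index.astype(str), scores.to_numpy(dtype=float)))]
    labels = pd.Series("MID", index=scores.index, name="quartile")
    bottom_ids = order.index[:q]
    top_ids = order.index[-q:]
    labels.loc[bottom_ids] = "BOTTOM"
    labels.loc[top_ids] = "TOP"
    thresholds = {
        "top": float(order.iloc[-q]),
        "bottom": float(order.iloc[q - 1]),
    }
    return labels, thresholds


def gc_content(seq: str) -> float:
    """(G + C) / (A + C + G + T); Ns excluded from both counts; NaN if all N."""
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        return float("nan")
    return gc / acgt


def promoter_gc(
    genome: FastaStore,
    tss_table: pd.DataFrame,
    window: tuple[int, int] = GC_WINDOW,
) -> pd.Series:
    """GC fraction of the window around each TSS (clipped at chromosome ends).

    The window is symmetric in the defaults (-300..+300) and GC content is
    strand-symmetric, so genomic coordinates are used directly.
    """
    lo, hi = window
    out = {}
    for row in tss_table.itertuples():
        length = genome.length(row.chrom)
        start = max(0, int(row.tss) + lo)
        end = min(length, int(row.tss) + hi)
        out[row.gene_id] = gc_content(genome.subsequence(row.chrom, start, end))
    return pd.Series(out, name="promoter_gc")


@dataclass
class QuartileComparison:
    """TOP vs BOTTOM quartile comparison report."""

    basal_test: TestResult | None
    gc_test: TestResult | None
    promoter_fisher: TestResult
    promoter_counts: tuple[int, int, int, int]  # top with, top total, bottom with, bottom total
    promoter_fractions: tuple[int, int]  # nearest-int percent (top, bottom)
    induced_by_dose: dict[str, tuple[float, float]]


def compare_quartiles(
    top: pd.DataFrame,
    bottom: pd.DataFrame,
    fold_columns: tuple[str, ...] = (),
) -> QuartileComparison:
    """Compare TOP vs BOTTOM quartile genes.

    Expects columns ``rpkm_basal``, ``promoter_gc`` and
    ``has_promoter_peak`` where available.  Continuous covariates use a
    two-sided rank-sum test; promoter-peak presence uses a two-sided Fisher
    exact test on the 2x2 table.  ``fold_columns`` name per-dose induction
    columns whose medians are reported per group.
    """
    if top.empty or bottom.empty:
        raise ValidationError("both quartile groups must be non-empty")

    def continuous(col: str) -> TestResult | None:
        if col not in top or col not in bottom:
            return None
        a = top[col].dropna().to_numpy(dtype=float)
        b = bottom[col].dropna().to_numpy(dtype=float)
        if a.size == 0 or b.size == 0:
            return None
        return rank_sum_test(a, b, alternative="two_sided")

    t_with = int(top["has_promoter_peak"].sum())
    b_with = int(bottom["has_promoter_peak"].sum())
    t_n, b_n = len(top), len(bottom)
    fisher = fisher_exact(
        [[t_with, t_n - t_with], [b_with, b_n - b_with]], alternative="two_sided"
    )
    from ifnsynergy.expression import percent

    induced = {}
    for col in fold_columns:
        if col in top and col in bottom:
            induced[col] = (
                float(np.median(top[col].dropna())),
                float(np.median(bottom[col].dropna())),
            )
    return QuartileComparison(
        basal_test=continuous("rpkm_basal"),
        gc_test=continuous("promoter_gc"),
        promoter_fisher=fisher,
        promoter_counts=(t_with, t_n, b_with, b_n),
        promoter_fractions=(percent(t_with, t_n), percent(b_with, b_n)),
        induced_by_dose=induced,
    )


@dataclass
class ESByMotif:
    """Enhancement scores split by promoter-peak motif class (BOTH vs ISRE)."""

    es_both: np.ndarray
    es_isre: np.ndarray
    median_both: float
    median_isre: float
    test: TestResult | None
    skipped: bool = False


def es_by_promoter_motif(records: pd.DataFrame) -> ESByMotif:
    """Compare ES of genes with BOTH-motif vs ISRE-only promoter peaks.

    ``records`` needs columns ``es``, ``has_promoter_peak`` and
    ``promoter_peak_category``.  One-sided rank-sum tests BOTH > ISRE.  If a
    group is empty the comparison is skipped and flagged.
    """
    prom = records[records["has_promoter_peak"]]
    both = prom.loc[prom["promoter_peak_category"] == "BOTH", "es"].to_numpy(dtype=float)
    isre = prom.loc[prom["promoter_peak_category"] == "ISRE", "es"].to_numpy(dtype=float)
    if both.size == 0 or isre.size == 0:
        return ESByMotif(
            es_both=both,
            es_isre=isre,
            median_both=float(np.median(both)) if both.size else float("nan"),
            median_isre=float(np.median(isre)) if isre.size else float("nan"),
            test=None,
            skipped=True,
        )
    return ESByMotif(
        es_both=both,
        es_isre=isre,
        median_both=float(np.median(both)),
        median_isre=float(np.median(isre)),
        test=rank_sum_test(both, isre, alternative="greater"),
    )


def build_enhancement_records(
    rpkm: pd.DataFrame,
    mixed_cols: list[str],
    beta_cols: list[str],
    gamma_cols: list[str],
    basal_cols: list[str],
    genes: pd.Index | list[str],
    gene_table: pd.DataFrame | None = None,
    genome: FastaStore | None = None,
    tss_table: pd.DataFrame | None = None,
    pseudocount: float = 1.0,
    gc_window: tuple[int, int] = GC_WINDOW,
) -> pd.DataFrame:
    """Per-gene Enhancement records for an ISG set.

    Replicate columns are averaged per condition before scoring.  Promoter-
    peak presence and category come from the unique peak->gene table; GC
    content from the genome when given.
    """
    genes = pd.Index(genes)
    sub = rpkm.loc[genes]
    rec = pd.DataFrame(index=genes)
    rec.index.name = "gene_id"
    rec["rpkm_mixed"] = sub[mixed_cols].mean(axis=1)
    rec["rpkm_beta"] = sub[beta_cols].mean(axis=1)
    rec["rpkm_gamma"] = sub[gamma_cols].mean(axis=1)
    rec["rpkm_basal"] = sub[basal_cols].mean(axis=1)
    rec["es"] = enhancement_score(
        rec["rpkm_mixed"], rec["rpkm_beta"], rec["rpkm_gamma"], pseudocount
    )
    labels, _ = quartile_partition(rec["es"])
    rec["quartile"] = labels
    if gene_table is not None:
        in_table = rec.index.isin(gene_table.index)
        prom = pd.Series(False, index=rec.index)
        cat = pd.Series(pd.NA, index=rec.index, dtype="object")
        sel = rec.index[in_table]
        prom.loc[sel] = gene_table.loc[sel, "promoter"].astype(bool)
        cat.loc[sel] = gene_table.loc[sel, "category"]
        rec["has_promoter_peak"] = prom
        rec["promoter_peak_category"] = cat.where(prom, pd.NA)
    else:
        rec["has_promoter_peak"] = False
        rec["promoter_peak_category"] = pd.NA
    if genome is not None and tss_table is not None:
        gc = promoter_gc(genome, tss_table[tss_table["gene_id"].isin(genes)], gc_window)
        rec["promoter_gc"] = gc.reindex(genes)
    return rec
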