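"""Peak-to-gene linkage: nearest expressed gene, promoter calls, distances.

Each peak is linked to the closest expressed gene on its chromosome by the
distance from the peak reference point (summit when known, else midpoint) to
the gene's TSS.  The signed distance is strand-aware (positive = downstream
of the TSS) and a peak is a promoter peak when the signed distance falls in
the window -1000..+100 bp (inclusive).  When several peaks link to one gene
the promoter link wins, then the nearest; the kept link's motif category
labels the gene.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ifnsynergy.errors import ValidationError
from ifnsynergy.io import GenomicInterval, PROMOTER_WINDOW


def peak_reference_point(peak: GenomicInterval) -> int:
    """Summit when provided, else the floor of the interval midpoint."""
    if peak.summit is not None:
        return peak.summit
    return (peak.start + peak.end) // 2


def _signed_distance(ref: int, tss: int, strand: str) -> int:
    d = ref - tss
    return d if strand == "+" else -d


def link_peak(
    peak: GenomicInterval,
    annotations: pd.DataFrame,
    expressed: set[str] | Sequence[str],
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
) -> dict:
    """Link one peak to its nearest expressed gene.

    ``annotations`` is the TSS table (gene_id, chrom, tss, strand).  Ties on
    absolute distance are broken by lexicographic gene_id.  A peak on a
    chromosome with no expressed gene is returned with ``unassigned=True``.
    """
    expressed = set(expressed)
    ref = peak_reference_point(peak)
    cand = annotations[
        (annotations["chrom"] == peak.chrom) & annotations["gene_id"].isin(expressed)
    ]
    pid = peak.name
    if cand.empty:
        return {
            "peak_id": pid,
            "gene_id": None,
            "signed_distance": None,
            "abs_distance": None,
            "promoter": False,
            "unassigned": True,
        }
    dist = (cand["tss"] - ref).abs()
    best = dist.min()
    ties = cand.loc[dist == best].sort_values("gene_id")
    row = ties.iloc[0]
    signed = _signed_distance(ref, int(row["tss"]), str(row["strand"]))
    lo, hi = promoter_window
    return {
        "peak_id": pid,
        "gene_id": row["gene_id"],
        "signed_distance": int(signed),
        "abs_distance": int(best),
        "promoter": bool(lo <= signed <= hi),
        "unassigned": False,
    }


def link_peaks(
    peaks: Sequence[GenomicInterval],
    annotations: pd.DataFrame,
    expressed: set[str] | Sequence[str],
    categories: Mapping[str, str] | pd.Series | None = None,
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
) -> pd.DataFrame:
    """Link every peak to its nearest expressed gene (vectorized per chrom).

    Returns one row per peak with the signed strand-aware distance, promoter
    flag and (when ``categories`` is given) the peak's motif category.
    Cross-chromosome linkage is never performed.
    """
    expressed = set(expressed)
    ann = annotations[annotations["gene_id"].isin(expressed)]
    if ann.empty:
        raise ValidationError("no expressed genes in the annotation")
    by_chrom: dict[str, pd.DataFrame] = {
        chrom: grp.sort_values(["tss", "gene_id"]).reset_index(drop=True)
        for chrom, grp in ann.groupby("chrom")
    }
    rows = []
    for i, peak in enumerate(peaks):
        pid = peak.name or f"peak_{i}"
        ref = peak_reference_point(peak)
        grp = by_chrom.get(peak.chrom)
        if grp is None:
            rows.append(
                {
                    "peak_id": pid,
                    "gene_id": None,
                    "signed_distance": np.nan,
                    "abs_distance": np.nan,
                    "promoter": False,
                    "unassigned": True,
                }
            )
            continue
        tss = grp["tss"].to_numpy()
        j = int(np.searchsorted(tss, ref))
        cand_idx = [k for k in (j - 1, j, j + 1) if 0 <= k < len(tss)]
        dists = np.abs(tss[cand_idx] - ref)
        best = dists.min()
        best_rows = grp.iloc[[k for k, d in zip(cand_idx, dists) if d == best]]
        row = best_rows.sort_values("gene_id").iloc[0]
        signed = _signed_distance(ref, int(row["tss"]), str(row["strand"]))
        lo, hi = promoter_window
        rows.append(
            {
                "peak_id": pid,
                "gene_id": row["gene_id"],
                "signed_distance": float(signed),
                "abs_distance": float(best),
                "promoter": bool(lo <= signed <= hi),
                "unassigned": False,
            }
        )
    links = pd.DataFrame(rows)
    if categories is not None:
        cat = pd.Series(categories)
        links["category"] = links["peak_id"].map(cat)
    return links


def unique_gene_table(links: pd.DataFrame) -> pd.DataFrame:
    """Collapse peak links to one link per gene.

    For a gene with several linked peaks: keep the nearest promoter link when
    any exists, otherwise the nearest link overall; ties break by peak_id.
    The kept link's category labels the gene.
    """
    assigned = links[~links["unassigned"]].copy()
    if assigned.empty:
        return assigned.set_index("gene_id") if "gene_id" in assigned else assigned
    assigned = assigned.sort_values(
        ["gene_id", "promoter", "abs_distance", "peak_id"],
        ascending=[True, False, True, True],
    )
    table = assigned.groupby("gene_id", sort=True).first()
    return table


def link_summary(gene_table: pd.DataFrame) -> pd.DataFrame:
    """Counts of uniquely linked genes by category x promoter/distal."""
    table = gene_table.copy()
    table["location"] = np.where(table["promoter"], "promoter", "distal")
    if "category" not in table:
        table["category"] = "ALL"
    out = (
        table.groupby(["category", "location"]).size().unstack(fill_value=0).astype(int)
    )
    for col in ("promoter", "distal"):
        if col not in out:
            out[col] = 0
    out["total"] = out["promoter"] + out["distal"]
    return out[["promoter", "distal", "total"]]


def distance_distribution(links: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-category absolute peak-to-TSS distances (bp)."""
    assigned = links[~links["unassigned"]]
    if "category" not in assigned:
        return {"ALL": assigned["abs_distance"].to_numpy(dtype=float)}
    return {
        str(cat): grp["abs_distance"].to_numpy(dtype=float)
        for cat, grp in assigned.groupby("category")
    }


def distance_summary(links: pd.DataFrame) -> pd.DataFrame:
    """Median absolute distance and count per category."""
    dist = distance_distribution(links)
    rows = [
        {"category": cat, "n": len(v), "median_distance": float(np.median(v)) if len(v) else np.nan}
        for cat, v in sorted(dist.items())
    ]
    return pd.DataFrame(rows).set_index("category")
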