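"""RNA-seq normalization, expression filtering, ISG calling, induced fractions.

Counts are normalized to CPM (counts per million, optionally with TMM
effective library sizes) and RPKM (reads per kilobase per million).  Genes
below 2 CPM in all samples are excluded from downstream analysis.
Interferon-stimulated genes (ISGs) are called against the unstimulated
condition at FDR < 0.05 and fold-change > 2, with a 1 RPKM pseudocount in
every ratio.  The differential test is a Welch t-test on log2(RPKM + 1)
replicates with Benjamini-Hochberg adjustment; the published analysis used a
negative-binomial framework, and the test is pluggable, but the quantity
being reproduced here is the thresholding pipeline rather than the test
itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ifnsynergy.errors import ValidationError
from ifnsynergy.stats import bh_fdr


def percent(numerator: int, denominator: int) -> int:
    """Nearest-integer percentage (e.g. 10/238 -> 4, 25/45 -> 56)."""
    if denominator == 0:
        raise ValidationError("percent of an empty set is undefined")
    return int(round(100.0 * numerator / denominator))


@dataclass
class NormalizedExpression:
    """Counts with CPM/RPKM layers and the per-sample scaling factors."""

    counts: pd.DataFrame
    lengths: pd.Series
    factors: pd.Series
    cpm: pd.DataFrame
    rpkm: pd.DataFrame
    method: str


def _tmm_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> float:
    """Trimmed mean of M-values factor of one sample against the reference.

    M (log ratio) values are trimmed by 30% on each side, A (absolute
    intensity) values by 5% on each side; the remaining M values are averaged
    with inverse delta-method variance weights.
    """
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    if np.allclose(M, 0.0, atol=1e-10):
        return 1.0
    n = M.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = sps.rankdata(M)
    rank_a = sps.rankdata(A)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(M[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return float(2**f)


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """TMM scaling factors, renormalized to geometric mean 1.

    The reference sample is the one whose 75th count-fraction percentile is
    closest to the mean across samples.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValidationError("zero library size")
    frac75 = counts.div(lib, axis=1).quantile(0.75, axis=0)
    ref_col = (frac75 - frac75.mean()).abs().idxmin()
    ref = counts[ref_col].to_numpy(dtype=float)
    lib_ref = float(lib[ref_col])
    factors = pd.Series(
        {
            col: _tmm_factor(counts[col].to_numpy(dtype=float), ref, float(lib[col]), lib_ref)
            for col in counts.columns
        }
    )
    factors /= np.exp(np.log(factors).mean())
    return factors


def normalize(
    counts: pd.DataFrame, lengths: pd.Series, method: str = "tmm"
) -> NormalizedExpression:
    """Compute CPM and RPKM layers from raw counts.

    CPM_gs = count_gs / effective_library_s * 1e6;
    RPKM_gs = CPM_gs * 1e3 / length_g.  With ``method="libsize"`` the
    effective library size is the raw column sum; with ``"tmm"`` it is scaled
    by the trimmed-mean factor.
    """
    if method not in ("libsize", "tmm"):
        raise ValidationError(f"unknown normalization method {method!r}")
    if counts.shape[1] < 1:
        raise ValidationError("need >= 1 sample")
    counts = counts.astype(float)
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValidationError("every gene needs a length")
    if (lengths <= 0).any():
        raise ValidationError("gene lengths must be > 0")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValidationError("zero library size")
    if method == "tmm":
        factors = tmm_factors(counts)
    else:
        factors = pd.Series(1.0, index=counts.columns)
    effective = lib * factors
    cpm = counts.div(effective, axis=1) * 1e6
    rpkm = cpm.mul(1e3 / lengths, axis=0)
    return NormalizedExpression(
        counts=counts, lengths=lengths, factors=factors, cpm=cpm, rpkm=rpkm, method=method
    )


def filter_expressed(norm: NormalizedExpression, cpm_threshold: float = 2.0) -> pd.Index:
    """Genes with CPM >= threshold in at least one sample.

    A gene below the threshold in every sample is excluded.
    """
    keep = (norm.cpm >= cpm_threshold).any(axis=1)
    return norm.cpm.index[keep]


def fold_change(rpkm_stim, rpkm_basal, pseudocount: float = 1.0):
    """(stim + c) / (basal + c); works on scalars, arrays and Series."""
    return (rpkm_stim + pseudocount) / (rpkm_basal + pseudocount)


def max_fold_change(
    rpkm: pd.DataFrame,
    stim_groups: Mapping[str, Sequence[str]],
    basal_cols: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene maximum fold-change over stimulated condition groups.

    Replicate columns in each group are averaged before the ratio; the basal
    level is the mean of ``basal_cols``.
    """
    if not stim_groups:
        raise ValidationError("need at least one stimulated group")
    basal = rpkm[list(basal_cols)].mean(axis=1)
    folds = pd.DataFrame(
        {
            name: fold_change(rpkm[list(cols)].mean(axis=1), basal, pseudocount)
            for name, cols in stim_groups.items()
        }
    )
    out = folds.max(axis=1)
    out.name = "max_fold"
    return out


def _welch_log_rpkm(stim: np.ndarray, basal: np.ndarray) -> float:
    """Two-sided Welch t-test p on log2(RPKM + 1) replicate values."""
    a = np.log2(stim + 1.0)
    b = np.log2(basal + 1.0)
    if np.allclose(a.std(ddof=1), 0) and np.allclose(b.std(ddof=1), 0):
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def _moderated_t_log_rpkm(
    stim: np.ndarray, basal: np.ndarray, prior_df: float
) -> np.ndarray:
    """Moderated two-sample t on log2(RPKM + 1), limma-style.

    Per-gene pooled variances are shrunk toward the mean residual variance
    across genes with ``prior_df`` prior degrees of freedom, and p-values use
    a t distribution with residual + prior df.  This stabilizes the test at
    the low replicate numbers typical of these experiments, standing in for
    the negative-binomial framework of the original analysis.

    ``stim``/``basal`` are (genes x replicates) arrays; returns two-sided p.
    """
    a = np.log2(stim + 1.0)
    b = np.log2(basal + 1.0)
    n1, n2 = a.shape[1], b.shape[1]
    df_res = n1 + n2 - 2
    ss = a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df_res
    s2_prior = float(np.mean(s2)) if np.any(s2 > 0) else 0.0
    s2_mod = (prior_df * s2_prior + df_res * s2) / (prior_df + df_res)
    diff = a.mean(axis=1) - b.mean(axis=1)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2.0 * sps.t.sf(np.abs(t), df_res + prior_df)
    # zero moderated variance: all values identical everywhere
    p = np.where(se == 0, np.where(diff == 0, 1.0, 0.0), p)
    return p


def call_isgs(
    rpkm: pd.DataFrame,
    stim_groups: Mapping[str, Sequence[str]],
    basal_cols: Sequence[str],
    fdr: float = 0.05,
    fold: float = 2.0,
    pseudocount: float = 1.0,
    fold_only: bool = False,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Call interferon-stimulated genes against the unstimulated condition.

    Membership requires BH-adjusted FDR < ``fdr`` AND maximum fold-change
    over the stimulated groups > ``fold``.  The test compares the replicates
    of the strongest-responding group against basal replicates on
    log2(RPKM + 1), with per-gene variances moderated toward the global mean
    using ``prior_df`` prior degrees of freedom (``prior_df=0`` gives a plain
    Welch t-test).  With fewer than 2 replicates per condition the test is
    impossible; pass ``fold_only=True`` to call on fold-change alone (FDR
    reported as NaN).

    Returns a DataFrame indexed by gene with max_fold, p_value, fdr, isg.
    """
    basal_cols = list(basal_cols)
    maxfc = max_fold_change(rpkm, stim_groups, basal_cols, pseudocount)
    if fold_only:
        out = pd.DataFrame(
            {"max_fold": maxfc, "p_value": np.nan, "fdr": np.nan, "isg": maxfc > fold}
        )
        return out
    if len(basal_cols) < 2 or any(len(cols) < 2 for cols in stim_groups.values()):
        raise ValidationError(
            "need >= 2 replicates per condition for the test; "
            "pass fold_only=True to call ISGs on fold-change alone"
        )
    basal = rpkm[basal_cols].to_numpy(dtype=float)
    group_means = {
        name: rpkm[list(cols)].mean(axis=1) for name, cols in stim_groups.items()
    }
    best_group = pd.DataFrame(group_means).idxmax(axis=1)
    if prior_df > 0:
        pvals = np.empty(len(rpkm))
        for name, cols in stim_groups.items():
            sel = (best_group == name).to_numpy()
            if not sel.any():
                continue
            stim = rpkm.loc[sel, list(cols)].to_numpy(dtype=float)
            pvals[sel] = _moderated_t_log_rpkm(stim, basal[sel], prior_df)
    else:
        pvals = np.empty(len(rpkm))
        for i, gene in enumerate(rpkm.index):
            cols = list(stim_groups[best_group.loc[gene]])
            pvals[i] = _welch_log_rpkm(
                rpkm.loc[gene, cols].to_numpy(dtype=float), basal[i]
            )
    adjusted = bh_fdr(pvals)
    out = pd.DataFrame(
        {
            "max_fold": maxfc,
            "p_value": pvals,
            "fdr": adjusted,
            "isg": (adjusted < fdr) & (maxfc > fold),
        },
        index=rpkm.index,
    )
    return out


def induced_fraction(
    genes: Sequence[str], max_fold: pd.Series, fold_threshold: float = 2.0
) -> tuple[float, int, int]:
    """Fraction (and count) of ``genes`` with max fold-change > threshold."""
    genes = list(genes)
    if not genes:
        raise ValidationError("induced_fraction of an empty gene set")
    missing = [g for g in genes if g not in max_fold.index]
    if missing:
        raise ValidationError(f"genes missing from the fold table: {missing[:5]}")
    values = max_fold.loc[genes]
    induced = int((values > fold_threshold).sum())
    return induced / len(genes), induced, len(genes)
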