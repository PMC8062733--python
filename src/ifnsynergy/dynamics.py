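"""Inducible-peak detection, kinetic clustering and dose-sensitivity tests.

A peak is inducible when its depth-normalized signal reaches at least a
fold threshold over the basal condition in a minimum number of timepoints
(defaults: two-fold in at least two timepoints).  Replicate columns at the
same (stimulus, dose, time) are averaged before the test, and a pseudocount
stabilizes ratios at low tag counts.  Kinetic classes are found by k-means on
row-scaled log2 signal with the number of clusters chosen by mean silhouette
width; cluster 1 is always the class with the earlier signal-weighted mean
time (early = GAF-like, late = ISGF3-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from ifnsynergy.errors import ValidationError
from ifnsynergy.io import ConditionMeta, condition_metadata
from ifnsynergy.stats import TestResult, rank_sum_test


def _grouped_stimulated(
    signal: pd.DataFrame,
    meta: Mapping[str, ConditionMeta | None],
    exclude_cols: Sequence[str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Replicate-averaged stimulated columns and the mean basal column.

    Basal columns are those with time == 0; stimulated columns are grouped by
    (stimulus, dose, time).  Columns without parseable metadata are ignored.
    """
    excluded = set(exclude_cols)
    basal_cols = [
        c for c in signal.columns if meta.get(c) is not None and meta[c].time == 0
    ]
    if not basal_cols:
        raise ValidationError("no basal (time 0) column in signal matrix")
    groups: dict[tuple[str, float, float], list[str]] = {}
    for c in signal.columns:
        m = meta.get(c)
        if m is None or m.time == 0 or c in excluded:
            continue
        groups.setdefault((m.stimulus, m.dose, m.time), []).append(c)
    if not groups:
        raise ValidationError("no stimulated columns remain after exclusion")
    stim = pd.DataFrame(
        {key: signal[cols].mean(axis=1) for key, cols in sorted(groups.items())}
    )
    basal = signal[basal_cols].mean(axis=1)
    return stim, basal


def find_inducible(
    signal: pd.DataFrame,
    fold: float = 2.0,
    min_timepoints: int = 2,
    exclude_cols: Sequence[str] = (),
    pseudocount: float = 1.0,
    meta: Mapping[str, ConditionMeta | None] | None = None,
) -> pd.Series:
    """Flag peaks with >= ``fold`` induction over basal in >= ``min_timepoints``.

    The ratio is (value + c) / (basal + c) with c = ``pseudocount``;
    replicates at the same (stimulus, dose, time) are averaged first.
    """
    if fold <= 1:
        raise ValidationError("induction fold threshold must be > 1")
    if signal.lt(0).any().any():
        raise ValidationError("signal matrix must be non-negative")
    if meta is None:
        meta = condition_metadata(signal.columns)
    stim, basal = _grouped_stimulated(signal, meta, exclude_cols)
    ratios = stim.add(pseudocount).div(basal + pseudocount, axis=0)
    flags = (ratios >= fold).sum(axis=1) >= min_timepoints
    flags.name = "inducible"
    return flags


def scale_rows(values: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-row z-scores of log2(value + c); constant rows map to zeros.

    Uses the population standard deviation, so a two-point row maps to
    (-1, +1).  Row scaling is invariant to multiplying a row by a positive
    constant (a log2 shift removed by centering).
    """
    if values.shape[1] < 2:
        raise ValidationError("row scaling requires >= 2 columns")
    logv = np.log2(values + pseudocount)
    centered = logv.sub(logv.mean(axis=1), axis=0)
    sd = logv.std(axis=1, ddof=0)
    scaled = centered.div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    return scaled


@dataclass
class KineticClusters:
    """K-means kinetic clustering result.

    ``labels`` are 1-based; cluster 1 has the earlier signal-weighted mean
    time.  ``silhouette_by_k`` holds the mean silhouette width per candidate
    k and ``inertia_by_k`` the within-cluster sum of squares (elbow data,
    reported but not used for selection).
    """

    labels: pd.Series
    chosen_k: int
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    inertia_by_k: dict[int, float] = field(default_factory=dict)
    degenerate: bool = False


def _signal_weighted_mean_time(profile: np.ndarray, times: np.ndarray) -> float:
    w = profile - profile.min()
    if w.sum() <= 0:
        return float(times.mean())
    return float((w * times).sum() / w.sum())


def cluster_kinetics(
    scaled: pd.DataFrame,
    times: Sequence[float] | None = None,
    k_candidates: Sequence[int] = (2, 3, 4, 5, 6),
    seed: int = 0,
    n_init: int = 10,
) -> KineticClusters:
    """Cluster row-scaled kinetic profiles; choose k by mean silhouette.

    ``times`` gives the time (hours) of each column (parsed from column names
    when omitted).  All-identical rows are degenerate: silhouette is
    undefined and the result is flagged with every peak in cluster 1.
    """
    if any(k < 2 for k in k_candidates):
        raise ValidationError("k candidates must all be >= 2")
    if scaled.shape[0] < max(k_candidates) + 1:
        raise ValidationError("need more rows than the largest candidate k")
    if times is None:
        meta = condition_metadata(scaled.columns)
        if any(meta[c] is None for c in scaled.columns):
            raise ValidationError("times not given and column names are not parseable")
        times = [meta[c].time for c in scaled.columns]
    times = np.asarray(times, dtype=float)
    X = scaled.to_numpy()
    if np.allclose(X, X[0], atol=1e-12):
        labels = pd.Series(1, index=scaled.index, name="cluster")
        return KineticClusters(labels=labels, chosen_k=1, degenerate=True)

    sil: dict[int, float] = {}
    inertia: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in sorted(set(k_candidates)):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        raw = km.fit_predict(X)
        fits[k] = raw
        inertia[k] = float(km.inertia_)
        sil[k] = float(silhouette_score(X, raw)) if len(np.unique(raw)) > 1 else float("nan")
    chosen_k = max(sorted(sil), key=lambda k: (np.nan_to_num(sil[k], nan=-2.0), -k))
    raw = fits[chosen_k]

    # canonicalize: cluster 1 = earliest signal-weighted mean time
    order = sorted(
        np.unique(raw),
        key=lambda c: _signal_weighted_mean_time(X[raw == c].mean(axis=0), times),
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=scaled.index, name="cluster")
    return KineticClusters(
        labels=labels, chosen_k=chosen_k, silhouette_by_k=sil, inertia_by_k=inertia
    )


def log2_fold_changes(
    signal: pd.DataFrame,
    dose: float,
    time: float,
    stimulus: str | None = None,
    pseudocount: float = 1.0,
    meta: Mapping[str, ConditionMeta | None] | None = None,
) -> pd.Series:
    """Per-peak log2((signal + c) / (basal + c)) at one (dose, time).

    Replicates are averaged; basal is the mean of all time-0 columns.
    """
    if meta is None:
        meta = condition_metadata(signal.columns)
    stim, basal = _grouped_stimulated(signal, meta, exclude_cols=())
    cols = [
        key
        for key in stim.columns
        if key[1] == dose and key[2] == time and (stimulus is None or key[0] == stimulus)
    ]
    if not cols:
        raise ValidationError(f"no stimulated columns at dose {dose}, time {time}")
    value = stim[cols].mean(axis=1)
    return np.log2((value + pseudocount) / (basal + pseudocount))


@dataclass
class DoseComparison:
    """Rank-sum tests for dose sensitivity of one peak set."""

    high_vs_low: TestResult
    low_vs_basal: TestResult | None = None
    high_vs_basal: TestResult | None = None


def dose_comparison(
    low_lfc: Sequence[float],
    high_lfc: Sequence[float],
    basal_signal: Sequence[float] | None = None,
    low_signal: Sequence[float] | None = None,
    high_signal: Sequence[float] | None = None,
) -> DoseComparison:
    """One-sided rank-sum test that high-dose induction exceeds low-dose.

    ``low_lfc``/``high_lfc`` are per-peak log2 fold-changes over basal at the
    two doses.  When raw signal vectors are also given, each dose is
    additionally tested against basal (one-sided, dose > basal).
    """
    low = np.asarray(low_lfc, dtype=float)
    high = np.asarray(high_lfc, dtype=float)
    if low.size == 0 or high.size == 0:
        raise ValidationError("dose comparison requires non-empty samples")
    result = DoseComparison(high_vs_low=rank_sum_test(high, low, alternative="greater"))
    if basal_signal is not None and low_signal is not None:
        result.low_vs_basal = rank_sum_test(low_signal, basal_signal, alternative="greater")
    if basal_signal is not None and high_signal is not None:
        result.high_vs_basal = rank_sum_test(high_signal, basal_signal, alternative="greater")
    return result
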