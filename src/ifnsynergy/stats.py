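"""Self-contained statistical primitives: rank-sum, Fisher exact, BH-FDR.

These are written from first principles so every p-value in the pipeline is
reproducible bit-for-bit and verifiable against brute-force enumeration
oracles.  The rank-sum test uses exact enumeration (via the Mann-Whitney
counting recursion) when both samples have at most 10 observations and no
ties, and otherwise a tie-corrected normal approximation with continuity
correction.  Fisher's exact test enumerates the hypergeometric distribution
with exact rational arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Sequence

import numpy as np

from ifnsynergy.errors import ValidationError

ALTERNATIVES = ("two_sided", "greater", "less")

EXACT_MAX_N = 10  # per-sample size cap for the exact rank-sum path


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test."""

    statistic: float
    p_value: float
    alternative: str
    method: str
    n1: int
    n2: int
    degenerate: bool = False


def _check_alternative(alternative: str) -> None:
    if alternative not in ALTERNATIVES:
        raise ValidationError(f"alternative must be one of {ALTERNATIVES}")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum / Mann-Whitney


@lru_cache(maxsize=None)
def _mw_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Number of rank arrangements with U = u, for u = 0..n1*n2.

    Standard recursion: N(u; n1, n2) = N(u - n2; n1-1, n2) + N(u; n1, n2-1).
    """
    if n1 == 0 or n2 == 0:
        return (1,) + (0,) * (n1 * n2)
    a = _mw_counts(n1 - 1, n2)
    b = _mw_counts(n1, n2 - 1)
    out = []
    for u in range(n1 * n2 + 1):
        total = 0
        if u - n2 >= 0 and u - n2 < len(a):
            total += a[u - n2]
        if u < len(b):
            total += b[u]
        out.append(total)
    return tuple(out)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for x: #(x_i > y_j) + 0.5 * #(x_i == y_j)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test of x versus y.

    ``alternative="greater"`` tests whether x tends to exceed y.  Exact
    enumeration is used when both n <= 10 and there are no ties; otherwise a
    tie-corrected normal approximation with continuity correction.  When the
    tie-corrected variance is zero (all observations identical) the one-sided
    p is 0.5 and the two-sided p is 1.0 by convention.
    """
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank_sum_test requires non-empty samples")
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size

    if not has_ties and n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        counts = _mw_counts(n1, n2)
        total = math.comb(n1 + n2, n1)
        ui = int(round(u))
        p_ge = sum(counts[ui:]) / total
        p_le = sum(counts[: ui + 1]) / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return TestResult(u, float(p), alternative, "rank_sum_exact", n1, n2)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        p = 1.0 if alternative == "two_sided" else 0.5
        return TestResult(u, p, alternative, "rank_sum_normal", n1, n2, degenerate=True)
    sd = math.sqrt(var)

    def sf(z: float) -> float:
        return 0.5 * math.erfc(z / math.sqrt(2.0))

    # continuity correction: shrink |u - mu| by 0.5
    z_greater = (u - mu - 0.5) / sd
    z_less = (u - mu + 0.5) / sd
    if alternative == "greater":
        p = sf(z_greater)
    elif alternative == "less":
        p = 1.0 - sf(z_less)
    else:
        p = min(1.0, 2.0 * min(sf(z_greater), 1.0 - sf(z_less)))
    return TestResult(u, float(p), alternative, "rank_sum_normal", n1, n2)


# ---------------------------------------------------------------------------
# Fisher's exact test


def fisher_exact(
    table: Sequence[Sequence[int]], alternative: str = "two_sided"
) -> TestResult:
    """Fisher's exact test on a 2x2 table [[a, b], [c, d]].

    Enumerates the hypergeometric distribution over all tables with the
    observed margins using exact rational arithmetic.  The two-sided p-value
    sums the probabilities of tables no more probable than the observed one
    (within relative tolerance 1e-7).  A table with an empty margin is
    degenerate and reports p = 1.
    """
    _check_alternative(alternative)
    (a, b), (c, d) = table
    cells = (a, b, c, d)
    if any(int(v) != v or v < 0 for v in cells):
        raise ValidationError("fisher_exact requires non-negative integer cells")
    a, b, c, d = (int(v) for v in cells)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        return TestResult(float(a), 1.0, alternative, "fisher_exact", r1, r2, degenerate=True)

    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)

    def pmf(k: int) -> Fraction:
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)

    p_obs = pmf(a)
    if alternative == "greater":
        p = sum(pmf(k) for k in range(a, hi + 1))
    elif alternative == "less":
        p = sum(pmf(k) for k in range(lo, a + 1))
    else:
        cutoff = p_obs * (1 + Fraction(1, 10**7))
        p = sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= cutoff)
    return TestResult(float(a), float(min(Fraction(1), p)), alternative, "fisher_exact", r1, r2)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted_(i) = min_{j >= i} (m / j) * p_(j), capped at 1, returned in the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted
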