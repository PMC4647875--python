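"""Statistical tests used throughout the analysis.

Cohort sizes in this kind of xenograft study are tiny (five animals per
tumour line), so the nonparametric tests are computed *exactly* by
enumeration wherever the enumeration is affordable, rather than by normal
approximations that are invalid at n = 5.

Two-sided p-values for the exact tests follow the convention
``p = min(1, 2 * min(lower_tail, upper_tail))`` where each tail includes
the observed point probability.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "pearson_t_p",
    "wilcoxon_matched_pairs_exact",
    "mann_whitney_u",
    "spearman_rho",
]

_TINY_P = 5e-324  # smallest positive float; keeps p strictly positive


@dataclass(frozen=True)
class TestResult:
    """Outcome of a statistical test."""

    statistic: float
    pvalue: float
    method: str  # "exact" or "approximate"
    n: int
    flagged: bool = False


def _two_sided(lower: float, upper: float) -> float:
    return float(min(1.0, 2.0 * min(lower, upper)))


def pearson_t_p(x, y) -> TestResult:
    """Pearson correlation with a two-sided p from the t transform.

    ``t = r * sqrt((n - 2) / (1 - r^2))`` with n - 2 degrees of freedom.
    Degenerate (constant) input is flagged and reported as p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be matching 1D arrays")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if x.std() == 0 or y.std() == 0:
        return TestResult(np.nan, 1.0, "approximate", n, flagged=True)
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    if abs(r) >= 1.0:
        return TestResult(r, _TINY_P, "approximate", n)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return TestResult(r, max(float(p), _TINY_P), "approximate", n)


def _signed_rank_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of 2*W+ over all sign assignments (polynomial convolution)."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        nxt = counts.copy()
        nxt[r:] += counts[: total + 1 - r]
        counts = nxt
    return counts


def wilcoxon_matched_pairs_exact(differences, exact_limit: int = 20) -> TestResult:
    """Wilcoxon signed-rank (matched-pairs) test on paired differences.

    Zero differences are dropped (and noted); tied magnitudes receive
    mid-ranks.  For n <= ``exact_limit`` the two-sided p-value is exact,
    from the full distribution of the positive-rank sum over all 2^n sign
    assignments; beyond that a normal approximation with tie correction is
    used.  The reported statistic is W = min(W+, W-).
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1:
        raise ValueError("differences must be 1D")
    if (d == 0).all():
        warnings.warn("all differences are zero; test is degenerate")
        return TestResult(0.0, 1.0, "exact", 0, flagged=True)
    if (d == 0).any():
        warnings.warn("dropping zero differences (Wilcoxon convention)")
        d = d[d != 0]
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 non-zero differences")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= exact_limit:
        doubled = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_distribution(doubled)
        denom = 2.0**n
        w2 = int(round(2 * w_plus))
        lower = counts[: w2 + 1].sum() / denom
        upper = counts[w2:].sum() / denom
        return TestResult(w, _two_sided(lower, upper), "exact", n)
    # Normal approximation with tie correction.
    mean = n * (n + 1) / 4.0
    ties = np.unique(np.abs(d), return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (ties**3 - ties).sum() / 48.0
    z = (w_plus - mean) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(w, min(1.0, float(p)), "approximate", n)


def mann_whitney_u(a, b, exact_limit: int = 12) -> TestResult:
    """Mann-Whitney U test between two independent groups.

    For total sample size <= ``exact_limit`` the two-sided p is exact, by
    enumerating every assignment of the pooled observations to the two
    groups; otherwise the normal approximation with tie correction is used.
    The reported statistic is U = min(U_a, U_b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    u_b = na * nb - u_a
    u = min(u_a, u_b)
    if na + nb <= exact_limit:
        us = np.array(
            [
                ranks[list(idx)].sum() - na * (na + 1) / 2.0
                for idx in itertools.combinations(range(na + nb), na)
            ]
        )
        eps = 1e-9
        lower = float((us <= u_a + eps).mean())
        upper = float((us >= u_a - eps).mean())
        return TestResult(u, _two_sided(lower, upper), "exact", na + nb)
    mean = na * nb / 2.0
    n = na + nb
    ties = np.unique(pooled, return_counts=True)[1]
    tie_term = ((ties**3 - ties).sum()) / (n * (n - 1))
    var = na * nb / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return TestResult(u, 1.0, "approximate", n, flagged=True)
    z = (u_a - mean) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(u, min(1.0, float(p)), "approximate", n)


def spearman_rho(x, y, exact_limit: int = 8) -> TestResult:
    """Spearman's rank correlation with exact small-sample p-values.

    rho is the Pearson correlation of mid-ranks.  For n <= ``exact_limit``
    the two-sided p is exact, by enumerating all n! orderings of one rank
    vector; otherwise the t approximation with n - 2 degrees of freedom is
    used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be matching 1D arrays")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return TestResult(np.nan, 1.0, "approximate", n, flagged=True)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_limit:
        rxc = (rx - rx.mean()) / (rx.std() * np.sqrt(n))
        ryc = (ry - ry.mean()) / (ry.std() * np.sqrt(n))
        rhos = np.array(
            [float(rxc @ ryc[list(perm)]) for perm in itertools.permutations(range(n))]
        )
        eps = 1e-9
        lower = float((rhos <= rho + eps).mean())
        upper = float((rhos >= rho - eps).mean())
        return TestResult(rho, _two_sided(lower, upper), "exact", n)
    if abs(rho) >= 1.0:
        return TestResult(rho, _TINY_P, "approximate", n)
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return TestResult(rho, max(float(p), _TINY_P), "approximate", n)
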