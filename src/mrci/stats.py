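"""Rank-based and parametric statistics used by the grading evaluation.

The per-class comparison of log class-ratios between low- and high-grade
groups uses an exact two-sided Wilcoxon–Mann–Whitney test with a
permutation confidence interval for the location shift and the effect size
r = |Z|/sqrt(N); significance is Bonferroni-corrected at alpha/K. AUCs
across different K are compared by one-way ANOVA with Tukey HSD.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np
from scipy import stats as sps

from .errors import EmptyInputError

#: switch from full-enumeration null distribution to Monte-Carlo permutations
ENUMERATION_LIMIT = 200_000


@dataclass
class WMWResult:
    """Exact (or Monte-Carlo) Wilcoxon–Mann–Whitney test result."""

    U: float
    p_two_sided: float
    r: float
    ci: tuple[float, float]
    n1: int
    n2: int
    method: str  # "exact" or "monte-carlo"


@dataclass
class AnovaTukeyResult:
    """One-way ANOVA F test plus all-pairs Tukey HSD."""

    F: float
    df: tuple[int, int]
    p: float
    pairwise: dict[tuple[int, int], tuple[float, float]]  # (i,j) -> (mean diff, p adj)


@lru_cache(maxsize=256)
def _ranksum_null(doubled_ranks: tuple[int, ...], n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the group-1 rank sum (ranks doubled to ints).

    Dynamic program over (number chosen, doubled rank sum); equivalent to full
    enumeration of all C(n, n1) group assignments, including tied midranks.
    Returns (support of doubled rank sums, counts).
    """
    total = sum(doubled_ranks)
    # table[j] = counts over doubled-sum for choosing j items
    table = [np.zeros(total + 1, dtype=np.float64) for _ in range(n1 + 1)]
    table[0][0] = 1.0
    for r2 in doubled_ranks:
        for j in range(min(n1, len(doubled_ranks)), 0, -1):
            shifted = np.zeros(total + 1)
            shifted[r2:] = table[j - 1][: total + 1 - r2]
            table[j] += shifted
    counts = table[n1]
    support = np.nonzero(counts)[0]
    return support, counts[support]


def _tie_corrected_z(U: float, ranks: np.ndarray, n1: int, n2: int) -> float:
    n = n1 + n2
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0
    return (U - n1 * n2 / 2.0) / np.sqrt(var)


def _shift_ci_exact(
    a: np.ndarray, b: np.ndarray, alpha: float
) -> tuple[float, float]:
    """Exact CI for the location shift by inverting the permutation test.

    The CI bounds are order statistics of the n1*n2 pairwise differences
    a_i - b_j, at the depth where the exact null distribution of U first
    exceeds alpha/2 in each tail (the classical exact construction).
    """
    n1, n2 = len(a), len(b)
    diffs = np.sort((a[:, None] - b[None, :]).ravel())
    m = n1 * n2
    # null distribution of U for continuous data (no ties among differences assumed)
    ranks = np.arange(1, n1 + n2 + 1, dtype=float)
    support, counts = _ranksum_null(tuple((2 * ranks).astype(int)), n1)
    u_support = support / 2.0 - n1 * (n1 + 1) / 2.0
    cdf = np.cumsum(counts) / counts.sum()
    # largest u with P(U <= u) <= alpha/2
    ok = np.nonzero(cdf <= alpha / 2.0)[0]
    k = int(u_support[ok[-1]]) if ok.size else -1
    if k < 0:
        return float(diffs[0]), float(diffs[-1])
    # 1-indexed bounds [D_(k+1), D_(m-k)]
    return float(diffs[k]), float(diffs[m - k - 1])


def wmw_exact(
    a,
    b,
    seed: int = 0,
    n_mc: int = 100_000,
    ci_level: float = 0.95,
    enumeration_limit: int = ENUMERATION_LIMIT,
) -> WMWResult:
    """Two-sided Wilcoxon–Mann–Whitney test with exact p when feasible.

    The exact two-sided p is computed from the full permutation distribution
    of the rank sum whenever C(n1+n2, n1) <= ``enumeration_limit``; beyond
    that a seeded Monte-Carlo permutation p with >= ``n_mc`` draws is used.
    Ties are handled with midranks (tie-corrected variance for the normal
    approximation behind the effect size r = |Z|/sqrt(N)). The CI is for the
    location shift of ``a`` relative to ``b``, by permutation inversion.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise EmptyInputError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    R1 = float(ranks[:n1].sum())
    U = R1 - n1 * (n1 + 1) / 2.0
    mu_R = n1 * (n1 + n2 + 1) / 2.0
    obs_dev = abs(R1 - mu_R)

    n_arrangements = comb(n1 + n2, n1)
    if n_arrangements <= enumeration_limit:
        doubled = tuple(np.rint(2 * ranks).astype(int))
        support, counts = _ranksum_null(doubled, n1)
        dev = np.abs(support / 2.0 - mu_R)
        p = float(counts[dev >= obs_dev - 1e-9].sum() / counts.sum())
        method = "exact"
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_mc):
            perm = rng.permutation(ranks)
            if abs(perm[:n1].sum() - mu_R) >= obs_dev - 1e-9:
                hits += 1
        p = (hits + 1) / (n_mc + 1)
        method = "monte-carlo"

    z = _tie_corrected_z(U, ranks, n1, n2)
    r = abs(z) / np.sqrt(n1 + n2)
    if n1 * n2 > 0 and comb(n1 + n2, n1) <= enumeration_limit:
        ci = _shift_ci_exact(a, b, 1.0 - ci_level)
    else:
        # normal-approximation depth for the pairwise-difference order statistics
        zc = sps.norm.ppf((1.0 - ci_level) / 2.0)
        k = int(np.floor(n1 * n2 / 2.0 + zc * np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)))
        diffs = np.sort((a[:, None] - b[None, :]).ravel())
        k = max(k, 0)
        ci = (float(diffs[k]), float(diffs[len(diffs) - 1 - k]))
    return WMWResult(U=float(U), p_two_sided=min(p, 1.0), r=float(r), ci=ci, n1=n1, n2=n2, method=method)


def bonferroni(p_values, alpha: float = 0.05, K: int = 1) -> np.ndarray:
    """Per-test significance flags at the Bonferroni-corrected level alpha/K."""
    if K < 1:
        raise ValueError("K must be >= 1")
    return np.asarray(p_values, dtype=float) < alpha / K


def anova_tukey(samples: list[np.ndarray] | dict) -> AnovaTukeyResult:
    """One-way fixed-effects ANOVA followed by Tukey HSD over all pairs.

    ``samples`` is a list of per-group value arrays (e.g. per-repeat AUCs for
    each K). Pairwise keys in the result are (i, j) group indices with i < j.
    """
    if isinstance(samples, dict):
        samples = [np.asarray(v) for v in samples.values()]
    groups = [np.asarray(g, dtype=float) for g in samples]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise EmptyInputError("need >= 2 groups with >= 2 values each")
    F, p = sps.f_oneway(*groups)
    if not np.isfinite(F):
        raise ValueError("F undefined: zero within-group variance everywhere")
    k = len(groups)
    N = sum(len(g) for g in groups)
    hsd = sps.tukey_hsd(*groups)
    pairwise: dict[tuple[int, int], tuple[float, float]] = {}
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(np.mean(groups[i]) - np.mean(groups[j]))
            pairwise[(i, j)] = (diff, float(hsd.pvalue[i, j]))
    return AnovaTukeyResult(F=float(F), df=(k - 1, N - k), p=float(p), pairwise=pairwise)
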