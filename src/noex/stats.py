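"""Nonparametric tests with exact small-sample null distributions.

Group comparisons throughout the analysis use two-sided rank tests
(Mann-Whitney U, Wilcoxon signed-rank, Friedman with Kendall's W) and
rank/linear correlations, with Bonferroni correction for families of
comparisons.  For small samples the p-values are computed from the exact
permutation null (full enumeration, with midrank tie handling); beyond the
enumeration thresholds the standard tie-corrected normal/chi-square
approximations from :mod:`scipy.stats` are used.  The thresholds are fixed:

* Mann-Whitney: exact when ``n1 + n2 <= 16``
* Wilcoxon signed-rank: exact when the number of nonzero differences ``<= 20``
* Spearman: exact permutation p when ``n <= 8``
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "friedman_kendall_w",
    "bonferroni",
    "correlation",
    "significance_stars",
]

MANN_WHITNEY_EXACT_MAX_N = 16   # pooled sample size for full enumeration
WILCOXON_EXACT_MAX_N = 20       # nonzero differences for sign-flip enumeration
SPEARMAN_EXACT_MAX_N = 8        # n! permutation enumeration


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one statistical comparison.

    ``direction`` is +1 when the first group/positive differences dominate,
    -1 for the opposite, 0 for an exactly balanced statistic.
    """

    statistic_name: str
    statistic: float
    n: Tuple[int, ...]
    p: float
    exact: bool
    direction: int = 0
    correction: Optional[str] = None
    extra: dict = field(default_factory=dict)

    def stars(self) -> str:
        return significance_stars(self.p)


def significance_stars(p: float) -> str:
    """Significance notation: n/s: p>.05, *: p<.05, **: p<.01, ***: p<.001,
    ****: p<.0001."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 5e-2:
        return "*"
    return "n/s"


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U oriented on the first group: #{a_i > b_j} + 1/2 #{a_i == b_j}."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


@lru_cache(maxsize=512)
def _u_null_distribution(n1: int, pooled_key: Tuple[float, ...]) -> Tuple[np.ndarray, np.ndarray]:
    """Null values of U over all C(n, n1) group-1 assignments of the pooled
    sample (ties included), with multiplicities folded in by enumeration."""
    pooled = np.asarray(pooled_key, dtype=float)
    n = pooled.size
    # G[i, j] = score of pooled[i] vs pooled[j]
    diff = pooled[:, None] - pooled[None, :]
    G = (diff > 0).astype(float) + 0.5 * (diff == 0)
    np.fill_diagonal(G, 0.0)
    rowsum = G.sum(axis=1)
    us = []
    for comb in itertools.combinations(range(n), n1):
        idx = np.fromiter(comb, dtype=int, count=n1)
        # U = sum_{i in c, j not in c} G_ij
        us.append(rowsum[idx].sum() - G[np.ix_(idx, idx)].sum())
    values, counts = np.unique(np.asarray(us), return_counts=True)
    return values, counts


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> ComparisonResult:
    """Two-sided Mann-Whitney U test, U oriented on the first group.

    Exact p by full enumeration of group labelings when ``n1 + n2 <= 16``,
    otherwise the tie-corrected normal approximation (scipy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = a.size, b.size
    u = _u_statistic(a, b)
    mu = n1 * n2 / 2.0
    direction = int(np.sign(u - mu))
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return ComparisonResult("U", u, (n1, n2), 1.0, True, 0)
    if n1 + n2 <= MANN_WHITNEY_EXACT_MAX_N:
        # key on midranks so the cache collapses instances with the same
        # tie structure
        ranks = np.sort(sps.rankdata(pooled))
        values, counts = _u_null_distribution(n1, tuple(ranks.tolist()))
        # ranks give the same U null as raw values (U depends on order only)
        dev = np.abs(values - mu)
        p = counts[dev >= abs(u - mu) - 1e-12].sum() / counts.sum()
        return ComparisonResult("U", u, (n1, n2), float(p), True, direction)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return ComparisonResult("U", u, (n1, n2), float(res.pvalue), False, direction)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

@lru_cache(maxsize=512)
def _wilcoxon_null_cdf(scaled_ranks: Tuple[int, ...]) -> np.ndarray:
    """Counts of W+ over all 2^n sign assignments, by polynomial convolution.

    ``scaled_ranks`` are the (possibly midrank) absolute-value ranks times 2,
    so they are integers; index k of the returned array is the count of sign
    vectors with 2*W+ == k.
    """
    total = sum(scaled_ranks)
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in scaled_ranks:
        new = dist.copy()
        new[r:] += dist[: total + 1 - r]
        dist = new
    return dist


def wilcoxon_signed_rank(diffs: Sequence[float]) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    W is the smaller of the positive/negative rank sums.  Zero differences
    are dropped before ranking.  Exact p by full sign-flip enumeration when
    the number of nonzero differences is <= 20.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    direction = int(np.sign(w_pos - w_neg))
    if n <= WILCOXON_EXACT_MAX_N:
        scaled = tuple(sorted(int(round(2 * r)) for r in ranks))
        counts = _wilcoxon_null_cdf(scaled)
        total = counts.sum()
        k = int(round(2 * w))
        s = len(counts) - 1  # 2 * sum of ranks
        # two-sided: both tails at least as extreme; null of W+ is symmetric
        p = (counts[: k + 1].sum() + counts[s - k:].sum()) / total
        p = min(1.0, float(p))
        return ComparisonResult("W", w, (n,), p, True, direction)
    res = sps.wilcoxon(d, alternative="two-sided", correction=True,
                       method="approx")
    return ComparisonResult("W", w, (n,), float(res.pvalue), False, direction)


# ---------------------------------------------------------------------------
# Friedman / Kendall's W
# ---------------------------------------------------------------------------

def friedman_kendall_w(table: np.ndarray) -> ComparisonResult:
    """Friedman chi-square over an animals x conditions table, with Kendall's
    W = chi2 / (n (k - 1)) as the concordance effect size.

    Within-animal midranks; the standard tie correction is applied.  A table
    whose rows are all constant carries no rank information: chi2 = 0, W = 0,
    p = 1.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 animals (rows) and >= 2 conditions (columns)")
    n, k = x.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, x)
    col_sums = ranks.sum(axis=0)
    ssbn = float(np.sum(col_sums ** 2))
    # per-row tie correction: sum over rows of sum(t^3 - t)
    ties = 0.0
    for row in x:
        _, t = np.unique(row, return_counts=True)
        ties += float(np.sum(t ** 3 - t))
    c = 1.0 - ties / (n * (k ** 3 - k))
    if c <= 0:
        chi2 = 0.0
        w = 0.0
        p = 1.0
    else:
        chi2 = (12.0 * ssbn / (n * k * (k + 1)) - 3.0 * n * (k + 1)) / c
        chi2 = max(chi2, 0.0)
        w = chi2 / (n * (k - 1))
        p = float(sps.chi2.sf(chi2, k - 1))
    return ComparisonResult("friedman_chi2", chi2, (n, k), p, False,
                            extra={"kendall_w": w})


# ---------------------------------------------------------------------------
# Bonferroni
# ---------------------------------------------------------------------------

def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """p_adj = min(1, m * p); ``m`` defaults to the number of p-values."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, m * p)


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def correlation(x: Sequence[float], y: Sequence[float],
                method: str = "pearson") -> ComparisonResult:
    """Pearson's r or Spearman's rho with a two-sided p.

    Pearson p comes from the t distribution; Spearman p is exact by full
    permutation enumeration for n <= 8, scipy's approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    n = x.size
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
        return ComparisonResult("r", float(r), (n,), float(p), False,
                                int(np.sign(r)))
    if method != "spearman":
        raise ValueError(f"unknown method {method!r}")
    rho = float(sps.spearmanr(x, y).statistic)
    if n <= SPEARMAN_EXACT_MAX_N:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        rx_c = rx - rx.mean()
        denom = np.sqrt(np.sum(rx_c ** 2))
        perms = np.array(list(itertools.permutations(ry)))
        pc = perms - perms.mean(axis=1, keepdims=True)
        rhos = (pc @ rx_c) / (denom * np.sqrt(np.sum(pc ** 2, axis=1)))
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return ComparisonResult("rho", rho, (n,), p, True, int(np.sign(rho)))
    p = float(sps.spearmanr(x, y).pvalue)
    return ComparisonResult("rho", rho, (n,), p, False, int(np.sign(rho)))
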