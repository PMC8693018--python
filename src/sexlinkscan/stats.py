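"""Statistical tests shared by the CNV and SNV association scans.

The Mann-Whitney U test here uses the *exact* permutation distribution of U
including ties (dynamic programming over midrank half-units), because the
copy-number data are heavily tied (values live on the {0, 0.5, 1} grid) and
the large-sample normal approximation is poor in the far tail where the
Bonferroni decision is made.  scipy's exact method does not handle ties, so
the distribution is computed here and scipy supplies only the asymptotic
fallback for large panels.
"""

from __future__ import annotations

from math import comb
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps

#: panels up to this total size use the exact tie-aware distribution
EXACT_MWU_LIMIT = 40


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for group x: #{x_i > y_j} + 0.5 * #{x_i == y_j}."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _exact_u_distribution(values: np.ndarray, n1: int) -> np.ndarray:
    """Counts of permutations achieving each U (in half-units) when n1 of
    ``values`` are assigned to group 1, all C(n, n1) assignments equally
    likely.  Ties handled exactly.  Returned array c has c[u2] = number of
    assignments with 2*U == u2.

    DP over distinct values in ascending order; counts fit in float64
    exactly for the panel sizes used (C(31,15) < 2^53).
    """
    n = values.size
    n2 = n - n1
    umax2 = 2 * n1 * n2
    _, mults = np.unique(values, return_counts=True)
    # state: dp[a, u2] = #ways to assign processed items with a in group 1
    dp = np.zeros((n1 + 1, umax2 + 1))
    dp[0, 0] = 1.0
    below = 0  # items strictly below the current value
    for m in mults:
        m = int(m)
        new = np.zeros_like(dp)
        for j in range(0, m + 1):
            w = float(comb(m, j))
            # choosing j of this group into group 1:
            # each beats every group-2 item below (2 half-units each) and
            # ties with the m-j same-value group-2 items (1 half-unit each)
            for a in range(0, min(n1, below) + 1):
                if a + j > n1:
                    continue
                row = dp[a]
                if not row.any():
                    continue
                shift = 2 * j * (below - a) + j * (m - j)
                if shift > umax2:
                    # infeasible partial assignment (more group-2 items
                    # below than group 2 holds); can never complete
                    continue
                if shift == 0:
                    new[a + j] += w * row
                else:
                    new[a + j, shift:] += w * row[:umax2 + 1 - shift]
        dp = new
        below += m
    return dp[n1]


def mwu_exact(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Exact two-sided Mann-Whitney U test with ties.

    Returns (U, p) where U is the statistic for group x and the two-sided p
    is min(1, 2 * min(P(U <= u), P(U >= u))) under the exact permutation
    distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    u = _u_statistic(x, y)
    u2 = int(round(2 * u))
    dist = _exact_u_distribution(np.concatenate([x, y]), x.size)
    total = dist.sum()
    p_le = dist[: u2 + 1].sum() / total
    p_ge = dist[u2:].sum() / total
    return u, float(min(1.0, 2.0 * min(p_le, p_ge)))


def mwu_sex_test(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, str]:
    """Two-sided rank-sum test of group x (males) vs group y (females).

    Exact permutation distribution when the panel is small enough
    (n1 + n2 <= EXACT_MWU_LIMIT), otherwise scipy's normal approximation
    with tie and continuity correction.  Returns (U, p, direction) with
    direction 'male>female', 'female>male' or 'none'.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two samples per group")
    u = _u_statistic(x, y)
    mid = x.size * y.size / 2.0
    direction = ("male>female" if u > mid
                 else "female>male" if u < mid else "none")
    if np.unique(np.concatenate([x, y])).size == 1:
        return u, 1.0, "none"
    if x.size + y.size <= EXACT_MWU_LIMIT:
        _, p = mwu_exact(x, y)
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic")
        p = float(res.pvalue)
    return u, p, direction


def gwa_contingency(genotypes: Sequence[int],
                    sexes: Sequence[str]) -> Tuple[float, int, float]:
    """Pearson chi-square on the sex x genotype contingency table.

    Genotype codes: 0 (hom ref / absent), 1 (het / hemizygous), 2 (hom alt),
    -1 missing (excluded pairwise).  All-zero genotype columns are dropped
    before testing so perfect-association tables stay well defined; with a
    single retained category the site is monomorphic and p = 1.

    Returns (chi2, dof, p).
    """
    g = np.asarray(genotypes)
    s = np.asarray(sexes)
    keep = g >= 0
    g, s = g[keep], s[keep]
    if g.size == 0:
        return 0.0, 0, 1.0
    table = np.zeros((2, 3), dtype=np.int64)
    for row, sex in enumerate(("M", "F")):
        for col in range(3):
            table[row, col] = int(((s == sex) & (g == col)).sum())
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        return 0.0, 0, 1.0
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact test p-value.

    Two-sided by summation of hypergeometric probabilities <= that of the
    observed table (fixed margins); a zero margin gives p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    return alpha / n_tests if n_tests > 0 else np.inf
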