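"""Independent reference implementations used only to check results.

Everything here is deliberately brute-force (full enumeration or
all-position scanning) and shares no code with the package internals it
verifies.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import List, Tuple

import numpy as np


def mwu_enumeration(x, y) -> Tuple[float, float]:
    """Exact two-sided rank-sum p by enumerating every group assignment."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    values = np.concatenate([x, y])
    n, n1 = values.size, x.size

    def ustat(a, b):
        a, b = np.asarray(a), np.asarray(b)
        return float((a[:, None] > b[None, :]).sum()) + \
            0.5 * float((a[:, None] == b[None, :]).sum())

    u_obs = ustat(x, y)
    us = []
    idx = set(range(n))
    for grp in combinations(range(n), n1):
        rest = sorted(idx - set(grp))
        us.append(ustat(values[list(grp)], values[rest]))
    us = np.array(us)
    p = min(1.0, 2.0 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
    return u_obs, p


def fisher_enumeration(table) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration over all
    tables with the observed margins."""
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if min(r1, r2, c1, n - c1) < 0 or n == 0:
        return 1.0

    def prob(k: int) -> float:
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
            return 0.0
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for k in range(0, min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(1.0, total)


def pearson_chi2_2xk(table) -> Tuple[float, int]:
    """Pearson chi-square from the textbook formula sum (O-E)^2 / E."""
    t = np.asarray(table, dtype=float)
    t = t[:, t.sum(axis=0) > 0]
    rows = t.sum(axis=1, keepdims=True)
    cols = t.sum(axis=0, keepdims=True)
    expected = rows * cols / t.sum()
    chi2 = float(((t - expected) ** 2 / expected).sum())
    dof = (t.shape[0] - 1) * (t.shape[1] - 1)
    return chi2, dof


def brute_force_best_alignment(
    read: np.ndarray, reference: dict
) -> Tuple[int, str, int, str, bool] | None:
    """Best ungapped placement of a read by scoring every position on every
    scaffold and strand.  Ties broken by (mismatches, scaffold, start,
    strand '+'<'-'); returns (mismatches, scaffold, start, strand,
    ambiguous) or None if the read is longer than every scaffold."""
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    hits: List[Tuple[int, str, int, str]] = []
    for name in reference:
        codes = reference[name]
        if codes.size < read.size:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, read.size)
        for strand, q in (("+", read), ("-", comp[read[::-1]])):
            mism = (windows != q).sum(axis=1)
            for pos in range(mism.size):
                hits.append((int(mism[pos]), name, pos, strand))
    if not hits:
        return None
    hits.sort()
    best = hits[0]
    ambiguous = len(hits) > 1 and hits[1][0] == best[0]
    return (*best, ambiguous)
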