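"""Exact 2x2 tests and multiple-testing correction shared by the screens.

The two-sided Fisher p-value is computed by summing hypergeometric point
probabilities not exceeding that of the observed table (the usual
"probability method"), with a small relative guard against floating-point
ties.  The implementation is vectorized over tables because the screens
test thousands of events/sites at once.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

_TIE_GUARD = 1e-10  # relative slack when comparing point probabilities


def fisher_exact_2x2(a, b, c, d) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher exact p and sample odds ratio for tables [[a,b],[c,d]].

    Accepts scalars or equal-length arrays of non-negative integers.
    Degenerate tables (an empty row or column) get p = 1.  The odds ratio is
    the plain cross-product ratio: inf when b*c == 0 < a*d, nan when both
    diagonals contain a zero product.
    """
    a = np.atleast_1d(np.asarray(a, dtype=np.int64))
    b = np.atleast_1d(np.asarray(b, dtype=np.int64))
    c = np.atleast_1d(np.asarray(c, dtype=np.int64))
    d = np.atleast_1d(np.asarray(d, dtype=np.int64))
    if np.any((a < 0) | (b < 0) | (c < 0) | (d < 0)):
        raise ValueError("negative cell count")
    n = a + b + c + d
    p = np.ones(a.shape, dtype=float)
    for i in range(a.size):
        p[i] = _fisher_one(int(a[i]), int(b[i]), int(c[i]), int(d[i]))
    with np.errstate(divide="ignore", invalid="ignore"):
        oddsr = (a * d) / (b * c)
        oddsr = np.where((b * c == 0) & (a * d == 0), np.nan, oddsr)
    _ = n
    return p, oddsr


def _fisher_one(a: int, b: int, c: int, d: int) -> float:
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_GUARD)].sum())
    return min(p, 1.0)


def fisher_p_for_margins(r1: int, r2: int, c1: int) -> np.ndarray:
    """Two-sided p for every table with row sums (r1, r2) and first column sum c1.

    Returns the p-value vector indexed by a - lo over the support; useful for
    exhaustive sweeps over small-margin tables.
    """
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        lo = max(0, c1 - r2)
        hi = min(r1, c1)
        return np.ones(hi - lo + 1)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    # p[i] = sum of pmf[j] with pmf[j] <= pmf[i] * (1 + guard)
    order = np.argsort(pmf, kind="stable")
    csum = np.cumsum(pmf[order])
    # for each i, count how many sorted pmf values fall under its guarded threshold
    idx = np.searchsorted(pmf[order], pmf * (1.0 + _TIE_GUARD), side="right")
    p = np.where(idx > 0, csum[np.maximum(idx - 1, 0)], 0.0)
    return np.minimum(p, 1.0)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-tolerant: NaNs stay NaN)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q
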