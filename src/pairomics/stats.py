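"""Shared statistical kernels: paired/unpaired Wilcoxon wrappers and
tie-aware rank correlation (scalar and matrix forms)."""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy import stats as sps

#: sample sizes up to which the signed-rank null is enumerated exactly
SIGNED_RANK_EXACT_MAX = 25
#: sample sizes up to which the Spearman null may be enumerated exactly
SPEARMAN_EXACT_MAX = 9


def signed_rank_test(diffs: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired differences.

    Zero differences are dropped (Wilcoxon's original treatment); an exact
    null is used for n <= 25 when the absolute differences are tie-free,
    otherwise the normal approximation with tie correction. All differences
    zero gives p = 1 by convention.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= SIGNED_RANK_EXACT_MAX and not ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=False, method=method)
    return float(res.pvalue)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value, tie-aware."""
    res = sps.mannwhitneyu(np.asarray(x, float), np.asarray(y, float),
                           alternative="two-sided")
    return float(res.pvalue)


def _midranks(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, method="average", axis=0)


def spearman(x: np.ndarray, y: np.ndarray, method: str = "t") -> tuple[float, float]:
    """Spearman rho (Pearson of mid-ranks) and its two-sided p-value.

    ``method="t"`` uses the t-approximation t = rho*sqrt((n-2)/(1-rho^2));
    ``method="exact"`` enumerates all n! rank permutations (n <= 9 only).
    Constant input is rejected (rho undefined).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 5:
        raise ValueError(f"need at least 5 observations, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman correlation undefined")
    rho = _rank_pearson(_midranks(x), _midranks(y))
    if method == "t":
        p = _t_pvalue(rho, n)
    elif method == "exact":
        if n > SPEARMAN_EXACT_MAX:
            raise ValueError(f"exact enumeration limited to n <= {SPEARMAN_EXACT_MAX}")
        rx = _midranks(x)
        ry = _midranks(y)
        hits = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in permutations(range(n)):
            r = _rank_pearson(rx, ry[list(perm)])
            hits += abs(r) >= target
            total += 1
        p = hits / total
    else:
        raise ValueError(f"unknown method '{method}'")
    return float(rho), float(p)


def _rank_pearson(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx * rx).sum() * (ry * ry).sum())
    return float((rx * ry).sum() / denom)


def _t_pvalue(rho: np.ndarray | float, n: int) -> np.ndarray | float:
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        t = np.where(np.abs(rho) >= 1.0, np.inf * np.sign(rho), t)
    return 2.0 * sps.t.sf(np.abs(t), n - 2)


def rank_correlation_matrix(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs Spearman between columns of X and columns of Y.

    Returns (rho, p, valid_x, valid_y) where rho/p have shape
    (X.shape[1], Y.shape[1]); constant columns are flagged invalid and
    produce NaN rather than an error (callers skip and log them).
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows (subjects)")
    n = X.shape[0]
    if n < 5:
        raise ValueError(f"need at least 5 subjects, got {n}")
    rx = _midranks(X)
    ry = _midranks(Y)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean(axis=0)
    sx = np.sqrt((rx * rx).sum(axis=0))
    sy = np.sqrt((ry * ry).sum(axis=0))
    valid_x = sx > 0
    valid_y = sy > 0
    sx = np.where(valid_x, sx, np.nan)
    sy = np.where(valid_y, sy, np.nan)
    rho = (rx / sx).T @ (ry / sy)
    p = _t_pvalue(rho, n)
    return rho, p, valid_x, valid_y
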