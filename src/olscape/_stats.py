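"""Statistical cores shared across modules.

Vectorized two-sample t statistics with explicit zero-variance conventions,
Benjamini-Hochberg adjustment with missing-value passthrough, pairwise-
complete Pearson correlation, and a rank-sum test that is exact (full
enumeration over group assignments, midranks for ties) at small combined n.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def two_sample_t(
    test: np.ndarray,
    ref: np.ndarray,
    kind: str = "student",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-sided t-test between two groups with missing values.

    Parameters
    ----------
    test, ref : 2d arrays (proteins x replicates), NaN = missing.
    kind : "student" (pooled variance) or "welch".

    Returns
    -------
    (log2fc, p, n_test, n_ref); log2fc = mean(test) - mean(ref) wherever both
    groups have >= 1 value, p only where both have >= 2. Degenerate rows with
    zero variance in both groups get p = 1 when the means agree and p = 0
    when they differ (the limiting behavior of the t statistic).
    """
    test = np.atleast_2d(np.asarray(test, dtype=float))
    ref = np.atleast_2d(np.asarray(ref, dtype=float))
    nt = np.sum(~np.isnan(test), axis=1).astype(float)
    nr = np.sum(~np.isnan(ref), axis=1).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mt = np.where(nt >= 1, np.nanmean(test, axis=1), np.nan)
        mr = np.where(nr >= 1, np.nanmean(ref, axis=1), np.nan)
        vt = _nanvar(test, nt)
        vr = _nanvar(ref, nr)
    diff = mt - mr
    p = np.full(test.shape[0], np.nan)
    ok = (nt >= 2) & (nr >= 2)
    if ok.any():
        if kind == "student":
            with np.errstate(divide="ignore", invalid="ignore"):
                df = nt + nr - 2
                pooled = ((nt - 1) * vt + (nr - 1) * vr) / df
                se2 = pooled * (1 / nt + 1 / nr)
        elif kind == "welch":
            se2 = vt / nt + vr / nr
            with np.errstate(divide="ignore", invalid="ignore"):
                df = se2**2 / (
                    (vt / nt) ** 2 / (nt - 1) + (vr / nr) ** 2 / (nr - 1)
                )
        else:
            raise ValueError(f"unknown test kind {kind!r}")
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = diff / np.sqrt(se2)
            pv = 2.0 * stats.t.sf(np.abs(tstat), df)
        degenerate = ok & (se2 == 0)
        pv = np.where(degenerate & (diff == 0), 1.0, pv)
        pv = np.where(degenerate & (diff != 0), 0.0, pv)
        p[ok] = pv[ok]
    return diff, p, nt.astype(int), nr.astype(int)


def _nanvar(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    out = np.full(x.shape[0], np.nan)
    ok = n >= 2
    if ok.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            v = np.nanvar(x, axis=1, ddof=1)
        out[ok] = v[ok]
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN entries pass through."""
    p = np.asarray(p, dtype=float)
    flat = p.ravel()
    present = ~np.isnan(flat)
    vals = flat[present]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(flat.shape, np.nan)
    if vals.size:
        q[present] = multipletests(vals, method="fdr_bh")[1]
    return q.reshape(p.shape)


def pairwise_complete_corr(
    x: np.ndarray, min_n: int = 2, method: str = "pearson"
) -> tuple[np.ndarray, np.ndarray]:
    """Correlation between columns of ``x`` using pairwise-complete rows.

    Returns (r, n_pairs); cells with fewer than ``min_n`` complete pairs,
    or zero variance in either column over the complete pairs, are NaN.
    """
    x = np.asarray(x, dtype=float)
    k = x.shape[1]
    r = np.full((k, k), np.nan)
    n_pairs = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            mask = ~np.isnan(x[:, i]) & ~np.isnan(x[:, j])
            n = int(mask.sum())
            n_pairs[i, j] = n_pairs[j, i] = n
            if n < max(min_n, 2):
                continue
            a, b = x[mask, i], x[mask, j]
            if method == "spearman":
                a = stats.rankdata(a)
                b = stats.rankdata(b)
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                continue
            rij = float(np.corrcoef(a, b)[0, 1])
            r[i, j] = r[j, i] = min(1.0, max(-1.0, rij))
    return r, n_pairs


def ranksum_test(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 12
) -> tuple[float, float]:
    """Two-sided rank-sum (Mann-Whitney/Wilcoxon) test.

    Exact by full enumeration of group assignments (midranks, so ties are
    handled) when len(x)+len(y) <= ``exact_max_n``; otherwise the normal
    approximation with continuity and tie correction. Returns
    (rank-sum statistic W of ``x``, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w_obs = float(ranks[:nx].sum())
    if nx + ny <= exact_max_n:
        mu = nx * (nx + ny + 1) / 2.0
        obs_dev = abs(w_obs - mu)
        total = 0
        extreme = 0
        for idx in combinations(range(nx + ny), nx):
            total += 1
            w = ranks[list(idx)].sum()
            if abs(w - mu) >= obs_dev - 1e-9:
                extreme += 1
        return w_obs, extreme / total
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return w_obs, float(res.pvalue)
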