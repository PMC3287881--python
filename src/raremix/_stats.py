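"""Vectorized statistical primitives shared across test modules."""

from __future__ import annotations

import numpy as np
from scipy import stats


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; 0 if either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return 0.0
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def corr_matrix(Y: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Correlation of every row of Y (B, n) with every column of S (n, K).

    Constant rows/columns yield correlation 0.  Returns (B, K).
    """
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Sc = S - S.mean(axis=0, keepdims=True)
    ynorm = np.sqrt((Yc * Yc).sum(axis=1))  # (B,)
    snorm = np.sqrt((Sc * Sc).sum(axis=0))  # (K,)
    denom = np.outer(ynorm, snorm)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc @ Sc) / denom
    r[~np.isfinite(r)] = 0.0
    return np.clip(r, -1.0, 1.0)


def ols_scan(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column simple linear regression of y on each column of G.

    Returns (slope, se, two-sided p) arrays; monomorphic columns get
    slope 0, se inf, p 1.  p is from the slope t statistic on n - 2 df.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations")
    gc = G - G.mean(axis=0, keepdims=True)
    yc = y - y.mean()
    sxx = (gc * gc).sum(axis=0)
    sxy = gc.T @ yc
    syy = float(yc @ yc)
    poly = sxx > 0
    slope = np.zeros(G.shape[1])
    se = np.full(G.shape[1], np.inf)
    p = np.ones(G.shape[1])
    if poly.any():
        b = sxy[poly] / sxx[poly]
        rss = np.maximum(syy - b * sxy[poly], 0.0)
        sigma2 = rss / (n - 2)
        se_b = np.sqrt(sigma2 / sxx[poly])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se_b > 0, b / se_b, np.inf * np.sign(b))
        slope[poly] = b
        se[poly] = se_b
        p[poly] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    # guard against exact-fit underflow producing p == 0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return slope, se, p


def chi2_from_p(p: np.ndarray) -> np.ndarray:
    """Map two-sided p-values to 1-df chi-square quantiles (upper-tail)."""
    return stats.chi2.isf(np.asarray(p, dtype=float), df=1)


def p_from_chi2(x: np.ndarray) -> np.ndarray:
    """Upper-tail 1-df chi-square probability."""
    return stats.chi2.sf(np.asarray(x, dtype=float), df=1)


def permutation_matrix(rng: np.random.Generator, y: np.ndarray, B: int) -> np.ndarray:
    """(B, n) matrix of permuted copies of y."""
    n = len(y)
    idx = np.argsort(rng.random((B, n)), axis=1)
    return np.asarray(y, dtype=float)[idx]
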