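"""Common-variant gene tests: per-SNP regression with min-p summary, and
LASSO-path model selection with a Mallows'-Cp analogue.

Both tests operate on the variants of a gene whose MAF is at or above the
rare/common threshold ``T`` (the complement of the strict ``maf < T`` rule
used by the fixed-threshold burden test, so the two sets partition the gene).

* **CV_pmin**: ordinary least squares of the trait on each eligible dosage
  column under an additive model; the gene summary is the minimum two-sided
  p-value, Bonferroni-corrected by the number of polymorphic markers tested.
* **CV_lasso**: the LASSO regularization path (least-angle implementation) on
  the standardized eligible dosages; each breakpoint model k is scored with
  Cp_k = RSS_k / sigma2 - n + 2 df_k, where df_k is the number of nonzero
  coefficients; the minimum-Cp model is refit by unpenalized OLS and its
  overall F-test against the intercept-only model gives the gene p-value,
  corrected by the *total* number of SNPs in the gene (a deliberately
  conservative factor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import lars_path

from ._stats import ols_scan
from .data_model import GeneTestResult, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "SnpRegressionResult",
    "LassoSelection",
    "snp_regression",
    "gene_minp",
    "lasso_cp_path",
    "gene_lasso_pvalue",
    "common_gene_test",
    "common_family_test",
]


@dataclass
class SnpRegressionResult:
    variant_id: str
    slope: float
    se: float
    p: float
    monomorphic: bool = False


@dataclass
class LassoSelection:
    """LASSO path summary: candidate models, their Cp, and the winner."""

    cp: np.ndarray                  # Cp per breakpoint model
    df: np.ndarray                  # nonzero-coefficient count per model
    coef_path: np.ndarray           # (m, n_models) coefficients (standardized scale)
    selected: np.ndarray            # column indices (into the eligible block)
    sigma2: float
    sigma2_fallback: bool = False
    degenerate: bool = False
    extra: dict = field(default_factory=dict)


def snp_regression(g: np.ndarray, y: np.ndarray, variant_id: str = "") -> SnpRegressionResult:
    """OLS of y on one dosage column with intercept; two-sided p from the
    slope t statistic on n - 2 df.  Monomorphic columns yield a flagged
    degenerate result (slope 0, p 1) rather than an error."""
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(g) != len(y):
        raise InputError("dosage and phenotype lengths differ")
    slope, se, p = ols_scan(g[:, None], y)
    mono = bool(np.all(g == g[0]))
    return SnpRegressionResult(variant_id, float(slope[0]), float(se[0]), float(p[0]), mono)


def _eligible(mafs: np.ndarray, T: float) -> np.ndarray:
    """Common-variant eligibility: polymorphic and maf >= T (inclusive)."""
    mafs = np.asarray(mafs, dtype=float)
    return (mafs >= T) & (mafs > 0)


def gene_minp(
    dosage: np.ndarray,
    mafs: np.ndarray,
    y: np.ndarray,
    T: float,
    gene_id: str = "",
) -> GeneTestResult | None:
    """Minimum single-SNP regression p over eligible variants, Bonferroni-
    corrected by the number of markers tested.  Returns None when the gene
    has no eligible variant."""
    keep = _eligible(mafs, T)
    if not keep.any():
        return None
    _, _, p = ols_scan(dosage[:, keep].astype(float), np.asarray(y, dtype=float))
    m = int(keep.sum())
    pmin = float(p.min())
    return GeneTestResult(
        gene_id=gene_id,
        method="CV_pmin",
        threshold=T,
        statistic=pmin,
        p_raw=pmin,
        p_corrected=min(1.0, m * pmin),
        n_markers_used=m,
        extra={"bonferroni_m": m},
    )


def lasso_cp_path(dosage: np.ndarray, y: np.ndarray) -> LassoSelection:
    """LASSO regularization path with Cp model choice on a gene block.

    Predictors are centered and scaled to unit variance before penalization;
    columns that are constant (or collapse to zero variance) are excluded
    from the path.  Ties in Cp go to the smaller model.
    """
    X = np.asarray(dosage, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if m == 0:
        raise InputError("no eligible variants for the LASSO path")
    sd = X.std(axis=0)
    usable = sd > 0
    if not usable.any() or np.std(y) == 0:
        return LassoSelection(
            cp=np.array([0.0]), df=np.array([0]),
            coef_path=np.zeros((m, 1)), selected=np.array([], dtype=int),
            sigma2=float(np.var(y, ddof=1)) if n > 1 else 0.0,
            degenerate=True,
        )
    Xs = (X[:, usable] - X[:, usable].mean(axis=0)) / sd[usable]
    yc = y - y.mean()
    _, _, coefs = lars_path(Xs, yc, method="lasso")
    k_models = coefs.shape[1]
    resid = yc[:, None] - Xs @ coefs
    rss = (resid * resid).sum(axis=0)
    df = (np.abs(coefs) > 0).sum(axis=0)

    m_used = Xs.shape[1]
    if m_used <= n - 2:
        full_rss = rss[-1] if df[-1] == m_used else float(
            ((yc - Xs @ np.linalg.lstsq(Xs, yc, rcond=None)[0]) ** 2).sum()
        )
        dof = n - m_used - 1
        sigma2 = full_rss / dof if dof > 0 else np.nan
        fallback = False
    else:
        dofs = np.maximum(n - df - 1, 1)
        sigma2 = float((rss / dofs).min())
        fallback = True
    if not np.isfinite(sigma2) or sigma2 <= 0:
        # perfect fit: any nonzero model explains everything; pick smallest df
        sigma2 = max(sigma2 if np.isfinite(sigma2) else 0.0, np.finfo(float).tiny)

    cp = rss / sigma2 - n + 2.0 * df
    order = np.lexsort((df, cp))  # min Cp, ties -> smaller df
    best = int(order[0])
    sel_local = np.flatnonzero(np.abs(coefs[:, best]) > 0)
    selected = np.flatnonzero(usable)[sel_local]

    coef_path = np.zeros((m, k_models))
    coef_path[usable, :] = coefs
    return LassoSelection(
        cp=cp, df=df, coef_path=coef_path, selected=selected,
        sigma2=float(sigma2), sigma2_fallback=fallback,
        extra={"best_model": best},
    )


def _ols_ftest(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Overall F-test p of an OLS fit (with intercept) against the intercept-
    only model; rank-deficient designs drop collinear columns (QR pivoting).
    Returns (p, rank of the tested design)."""
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    _, R = np.linalg.qr(Xc, mode="reduced")
    diag = np.abs(np.diag(R))
    keep = diag > max(Xc.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    if not keep.all():
        # re-run on an independent subset chosen greedily
        cols: list[int] = []
        for j in range(Xc.shape[1]):
            trial = Xc[:, cols + [j]]
            if np.linalg.matrix_rank(trial) > len(cols):
                cols.append(j)
        Xc = Xc[:, cols]
    rank = Xc.shape[1]
    beta, _, _, _ = np.linalg.lstsq(Xc, yc, rcond=None)
    rss = float(((yc - Xc @ beta) ** 2).sum())
    tss = float(yc @ yc)
    df_resid = n - rank - 1
    if tss <= 0 or df_resid <= 0:
        return 1.0, rank
    f = ((tss - rss) / rank) / (rss / df_resid) if rss > 0 else np.inf
    p = float(stats.f.sf(f, rank, df_resid))
    return max(p, np.finfo(float).tiny), rank


def gene_lasso_pvalue(
    selection: LassoSelection,
    dosage: np.ndarray,
    y: np.ndarray,
    m_total: int,
    gene_id: str = "",
    T: float | None = None,
) -> GeneTestResult:
    """Refit the minimum-Cp variant set by unpenalized OLS and convert its
    overall F-test into the gene p-value; the Bonferroni factor is the total
    number of SNPs in the gene (all MAFs)."""
    y = np.asarray(y, dtype=float)
    extra: dict = {
        "selected": ",".join(map(str, selection.selected.tolist())) or ".",
        "n_selected": len(selection.selected),
        "sigma2_fallback": selection.sigma2_fallback,
    }
    if len(selection.selected) == 0:
        p_raw, stat = 1.0, 0.0
    else:
        X = np.asarray(dosage, dtype=float)[:, selection.selected]
        p_raw, rank = _ols_ftest(X, y)
        stat = p_raw
        if rank < len(selection.selected):
            extra["rank_deficient"] = True
    return GeneTestResult(
        gene_id=gene_id,
        method="CV_lasso",
        threshold=T,
        statistic=stat,
        p_raw=p_raw,
        p_corrected=min(1.0, m_total * p_raw),
        n_markers_used=len(selection.selected),
        extra=extra,
    )


def common_gene_test(
    dosage: np.ndarray,
    mafs: np.ndarray,
    y: np.ndarray,
    method: str,
    T: float = 0.05,
    gene_id: str = "",
) -> GeneTestResult | None:
    """Run one common-variant test (``pmin`` or ``lasso``) on one gene.
    Returns None when no variant is eligible (maf >= T, polymorphic)."""
    method = method.lower()
    if method == "pmin":
        return gene_minp(dosage, mafs, y, T, gene_id=gene_id)
    if method == "lasso":
        keep = _eligible(mafs, T)
        if not keep.any():
            return None
        sel = lasso_cp_path(dosage[:, keep], y)
        res = gene_lasso_pvalue(sel, dosage[:, keep], y, m_total=dosage.shape[1],
                                gene_id=gene_id, T=T)
        return res
    raise InputError(f"unknown common-variant method {method!r}")


def common_family_test(
    cohort,
    gene_map,
    gene_ids: Sequence[str],
    y: np.ndarray,
    method: str,
    T: float = 0.05,
) -> list[GeneTestResult]:
    """Run one common-variant test over a family of genes; genes with no
    eligible variant are omitted (logged)."""
    out = []
    skipped = 0
    for gid in gene_ids:
        block, mafs = cohort.gene_block(gene_map, gid)
        res = common_gene_test(block, mafs, y, method, T=T, gene_id=gid)
        if res is None:
            skipped += 1
            continue
        out.append(res)
    if skipped:
        logger.info("%d genes had no variant with maf >= %.3g; omitted", skipped, T)
    return out
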