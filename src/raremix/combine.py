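"""Fisher's-method combination of rare and common gene p-values, and
mean-ratio genomic control.

A gene with both rare (maf < T) and common (maf >= T) variants carries two
independent signals in this framework: the fixed-threshold burden test on the
rare subset and a common-variant test (min-p or LASSO/Cp) on the common
subset.  Fisher's statistic U = -2 * sum(ln p_i) refers the pair to a
chi-square with 2n degrees of freedom (n = 2 here); the two variant subsets
are disjoint and exhaustive for the gene, and the simulator draws genotypes
without linkage disequilibrium, so independence holds by construction.

Genomic control maps each raw p-value of a test family to the 1-df chi-square
quantile it implies, estimates the inflation factor lambda as the mean of
those chi-squares (the expected mean under the null is exactly 1), divides
every statistic by lambda, and maps back to p-values.  By default lambda is
floored at 1 (never deflate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from ._stats import chi2_from_p, p_from_chi2
from .data_model import GeneTestResult, InputError
from .rare_tests import rare_gene_test
from .common_tests import common_gene_test

__all__ = [
    "CombinedResult",
    "GCAdjustment",
    "fisher_combine",
    "combined_gene_test",
    "genomic_control",
    "apply_gc_to_results",
]


@dataclass
class CombinedResult:
    p_values: tuple[float, ...]
    U: float
    df: int
    p_comb: float


@dataclass
class GCAdjustment:
    lam: float
    n_tests: int
    mean_chi2: float
    floored: bool
    extra: dict = field(default_factory=dict)


def fisher_combine(p_list: Sequence[float]) -> CombinedResult:
    """U = -2 sum(ln p_i), referred to chi-square with 2n df."""
    p = np.asarray(p_list, dtype=float)
    if p.size < 1:
        raise InputError("need at least one p-value")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise InputError("p-values must lie in (0, 1]")
    U = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    p_comb = float(stats.chi2.sf(U, df))
    return CombinedResult(tuple(p.tolist()), U, df, max(p_comb, np.finfo(float).tiny))


def combined_gene_test(
    dosage: np.ndarray,
    mafs: np.ndarray,
    y: np.ndarray,
    T: float = 0.05,
    common_method: str = "pmin",
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    gene_id: str = "",
    ctx=None,
    p_rare: float | None = None,
    p_common: float | None = None,
) -> GeneTestResult | None:
    """Fisher-combined test for a gene with both rare and common variants.

    The rare component is the FT permutation p on the maf < T subset; the
    common component is the marker-corrected CV p on the maf >= T subset.
    Either component may be passed in pre-computed (e.g. after genomic
    control); missing ones are computed here.  Returns None for genes that
    lack either subset — the combination is only defined for mixed genes.
    """
    mafs = np.asarray(mafs, dtype=float)
    rare_set = mafs < T
    common_set = mafs >= T
    if not rare_set.any() or not common_set.any():
        return None
    if p_rare is None:
        r = rare_gene_test(dosage, mafs, y, "ft", T=T, B=B, seed=seed, ctx=ctx)
        p_rare = r.p_raw
    if p_common is None:
        c = common_gene_test(dosage, mafs, y, common_method, T=T, gene_id=gene_id)
        if c is None:  # common subset entirely monomorphic
            return None
        p_common = c.p_corrected
    comb = fisher_combine((p_rare, p_common))
    return GeneTestResult(
        gene_id=gene_id,
        method="COMB_pmin" if common_method == "pmin" else "COMB_lasso",
        threshold=T,
        statistic=comb.U,
        p_raw=comb.p_comb,
        p_corrected=comb.p_comb,
        n_markers_used=int(dosage.shape[1]),
        extra={"p_rare": p_rare, "p_common": p_common},
    )


def genomic_control(
    p_family: Sequence[float],
    allow_deflation: bool = False,
) -> tuple[GCAdjustment, np.ndarray]:
    """Mean-ratio genomic control on one family of raw p-values.

    Each p is mapped to the 1-df chi-square x with upper tail p; lambda is
    mean(x) / 1; corrected p = upper tail of x / lambda.  lambda is floored
    at 1 unless ``allow_deflation``.
    """
    p = np.asarray(p_family, dtype=float)
    if p.size < 2:
        raise InputError("genomic control needs a family of >= 2 p-values")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise InputError("p-values must lie in (0, 1]")
    x = chi2_from_p(p)
    mean_chi2 = float(x.mean())
    lam = mean_chi2
    floored = False
    if not allow_deflation and lam < 1.0:
        lam, floored = 1.0, True
    corrected = p_from_chi2(x / lam)
    corrected = np.clip(corrected, np.finfo(float).tiny, 1.0)
    adj = GCAdjustment(lam=lam, n_tests=p.size, mean_chi2=mean_chi2, floored=floored)
    return adj, corrected


def apply_gc_to_results(
    results: Sequence[GeneTestResult],
    allow_deflation: bool = False,
    use_corrected: bool = False,
) -> tuple[GCAdjustment, list[GeneTestResult]]:
    """Genomic-control correct one family of GeneTestResults in place of
    their p_corrected field (reading p_raw, or the existing p_corrected when
    ``use_corrected``)."""
    p = [
        (r.p_corrected if use_corrected and r.p_corrected is not None else r.p_raw)
        for r in results
    ]
    adj, corrected = genomic_control(p, allow_deflation=allow_deflation)
    out = []
    for r, pc in zip(results, corrected):
        out.append(
            GeneTestResult(
                gene_id=r.gene_id,
                method=r.method,
                threshold=r.threshold,
                statistic=r.statistic,
                p_raw=r.p_raw,
                p_corrected=float(pc),
                n_markers_used=r.n_markers_used,
                extra={**r.extra, "gc_lambda": adj.lam},
            )
        )
    return adj, out
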