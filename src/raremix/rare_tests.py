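"""Rare-variant collapsing tests for a quantitative trait.

Three gene-level burden tests are provided:

* **FT** (fixed threshold): minor-allele counts of all variants with
  MAF strictly below a threshold ``T`` are summed per individual, unweighted.
* **WE** (weighted): every variant in the gene enters, weighted inversely to
  ``sqrt(n_ref * q * (1 - q))`` where ``q`` is its allele frequency estimated
  with a pseudocount in a reference group (Madsen-Browning weights).  For a
  quantitative trait the default reference group is the individuals with
  phenotype at or below the sample median.
* **VT** (variable threshold): the FT-style score is evaluated at every
  candidate threshold (each distinct observed MAF, inclusion ``maf <= t``) and
  the maximal absolute association is reported together with the optimal
  threshold.

The association statistic underlying all three is the Pearson correlation
between the per-individual burden score and the phenotype; significance comes
from permutation of the phenotype, re-computing the full statistic (threshold
search and reference-group weights included) inside every permutation, with
the (b + 1) / (B + 1) estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._stats import corr_matrix, pearson, permutation_matrix
from .data_model import GeneTestResult, InputError

__all__ = [
    "BurdenScore",
    "PermutationContext",
    "RareTestResult",
    "ft_burden",
    "we_burden",
    "we_weights",
    "reference_mask",
    "burden_statistic",
    "vt_statistic",
    "permutation_pvalue",
    "rare_gene_test",
    "rare_family_test",
]


@dataclass
class BurdenScore:
    """Per-individual collapsed score for one gene."""

    scores: np.ndarray
    weights: np.ndarray
    included_variants: np.ndarray  # boolean over the gene's columns
    threshold: float | str | None
    empty: bool = False


@dataclass
class RareTestResult:
    statistic: float
    p_raw: float
    B: int
    seed: int | None = None
    T_opt: float | None = None
    extra: dict = field(default_factory=dict)


def ft_burden(dosage: np.ndarray, mafs: np.ndarray, T: float) -> BurdenScore:
    """Unweighted fixed-threshold burden: s_i = sum of dosages over variants
    with maf strictly below T."""
    if not (0.0 < T <= 0.5):
        raise InputError(f"threshold T={T} outside (0, 0.5]")
    mafs = np.asarray(mafs, dtype=float)
    include = mafs < T
    s = dosage[:, include].sum(axis=1).astype(float)
    return BurdenScore(
        scores=s,
        weights=np.ones(int(include.sum())),
        included_variants=include,
        threshold=T,
        empty=not include.any(),
    )


def reference_mask(y: np.ndarray, policy: str = "median") -> np.ndarray:
    """Reference-group membership for WE weights.

    ``median``: individuals with phenotype <= sample median (a dichotomized
    stand-in for Madsen-Browning's unaffected group); ``all``: everyone.
    """
    y = np.asarray(y, dtype=float)
    if policy == "median":
        return y <= np.median(y)
    if policy == "all":
        return np.ones(len(y), dtype=bool)
    raise InputError(f"unknown WE reference policy {policy!r}")


def we_weights(counts: np.ndarray, n_ref: int) -> np.ndarray:
    """Madsen-Browning weights from reference minor-allele counts:
    q = (c + 1) / (2 n_ref + 2), w = sqrt(n_ref * q * (1 - q))."""
    if n_ref < 1:
        raise InputError("empty WE reference group")
    q = (np.asarray(counts, dtype=float) + 1.0) / (2.0 * n_ref + 2.0)
    return np.sqrt(n_ref * q * (1.0 - q))


def we_burden(dosage: np.ndarray, ref: np.ndarray) -> BurdenScore:
    """Weighted burden over *all* variants; ``ref`` is the boolean reference-
    group mask used to estimate allele frequencies for the weights."""
    ref = np.asarray(ref, dtype=bool)
    n_ref = int(ref.sum())
    counts = dosage[ref, :].sum(axis=0)
    w = we_weights(counts, n_ref)
    s = (dosage / w).sum(axis=1)
    return BurdenScore(
        scores=s,
        weights=w,
        included_variants=np.ones(dosage.shape[1], dtype=bool),
        threshold="all",
        empty=dosage.shape[1] == 0,
    )


def burden_statistic(scores: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation between burden score and phenotype (signed);
    constant score or phenotype gives 0."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(scores) != len(y):
        raise InputError("score and phenotype lengths differ")
    if len(y) < 3:
        raise InputError("need at least 3 individuals")
    return pearson(scores, y)


def _vt_candidates(mafs: np.ndarray) -> np.ndarray:
    """Distinct observed MAFs of polymorphic variants, ascending."""
    mafs = np.asarray(mafs, dtype=float)
    return np.unique(mafs[mafs > 0])


def _vt_score_matrix(dosage: np.ndarray, mafs: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """(n, K) burden scores at each candidate threshold, inclusion maf <= t."""
    cols = [dosage[:, mafs <= t].sum(axis=1) for t in thresholds]
    return np.column_stack(cols).astype(float)


def vt_statistic(dosage: np.ndarray, mafs: np.ndarray, y: np.ndarray) -> tuple[float, float | None]:
    """Maximum over candidate thresholds of |corr(burden(t), y)|.

    Returns (z_max, T_opt); T_opt is the smallest maximizing threshold.
    A gene with no polymorphic variant yields (0.0, None).
    """
    thresholds = _vt_candidates(mafs)
    if thresholds.size == 0:
        return 0.0, None
    S = _vt_score_matrix(dosage, mafs, thresholds)
    z = np.abs(corr_matrix(np.asarray(y, dtype=float)[None, :], S))[0]
    k = int(np.argmax(z))  # argmax returns the first (smallest-threshold) max
    return float(z[k]), float(thresholds[k])


def permutation_pvalue(
    statistic_fn: Callable[[np.ndarray], float],
    y: np.ndarray,
    B: int,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Generic permutation p-value.

    ``statistic_fn(y_perm)`` must return the (absolute / maximized) statistic
    for an arbitrary phenotype vector; genotypes stay fixed inside it.
    Returns (p, observed statistic) with p = (1 + #{z_b >= z_obs}) / (B + 1).
    """
    if B < 1:
        raise InputError("need B >= 1 permutations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    z_obs = statistic_fn(y)
    exceed = 0
    for _ in range(B):
        if statistic_fn(rng.permutation(y)) >= z_obs:
            exceed += 1
    return (1.0 + exceed) / (B + 1.0), z_obs


# ---------------------------------------------------------------------------
# Vectorized per-gene engines (one shared permutation stream per family)


class PermutationContext:
    """Pre-centered observed + permuted phenotypes shared across the genes of
    a test family.  Row 0 is the observed phenotype, rows 1..B the permuted
    copies; p-values are (1 + #{b >= obs}) / (B + 1)."""

    def __init__(self, y: np.ndarray, Yperm: np.ndarray, ref_policy: str = "median"):
        y = np.asarray(y, dtype=float)
        Y = np.vstack([y[None, :], np.asarray(Yperm, dtype=float)])
        self.B = Y.shape[0] - 1
        self.Yc = Y - Y.mean(axis=1, keepdims=True)
        self.yy = (self.Yc * self.Yc).sum(axis=1)
        if ref_policy == "all":
            self.ref_rows = np.ones_like(Y, dtype=bool)
        else:  # the multiset of y is permutation-invariant, so one median
            self.ref_rows = Y <= np.median(y)
        self.n_ref = int(self.ref_rows[0].sum())

    @classmethod
    def build(cls, y: np.ndarray, B: int, seed: int | np.random.Generator = 0,
              ref_policy: str = "median") -> "PermutationContext":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return cls(y, permutation_matrix(rng, np.asarray(y, dtype=float), B), ref_policy)


def _pvalue_from_batch(z: np.ndarray) -> tuple[float, float]:
    z_obs = float(z[0])
    exceed = int((z[1:] >= z_obs - 1e-12).sum())
    return (1.0 + exceed) / (len(z) - 1 + 1.0), z_obs


def _corr_batch(ctx: PermutationContext, S: np.ndarray) -> np.ndarray:
    """(B+1, K) |correlation| of each context row with each column of S."""
    Sc = S - S.mean(axis=0, keepdims=True)
    snorm2 = (Sc * Sc).sum(axis=0)
    denom = np.sqrt(np.outer(ctx.yy, snorm2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs(ctx.Yc @ Sc) / denom
    r[~np.isfinite(r)] = 0.0
    return np.minimum(r, 1.0)


def _perm_p_fixed_burden(s: np.ndarray, ctx: PermutationContext) -> tuple[float, float]:
    """Permutation p for a phenotype-independent burden score (FT)."""
    return _pvalue_from_batch(_corr_batch(ctx, s[:, None])[:, 0])


def _perm_p_vt(dosage: np.ndarray, mafs: np.ndarray, ctx: PermutationContext
               ) -> tuple[float, float, float | None]:
    thresholds = _vt_candidates(mafs)
    if thresholds.size == 0:
        return 1.0, 0.0, None
    S = _vt_score_matrix(dosage, mafs, thresholds)
    Z = _corr_batch(ctx, S)
    p, _ = _pvalue_from_batch(Z.max(axis=1))
    k = int(np.argmax(Z[0]))
    return p, float(Z[0, k]), float(thresholds[k])


def _we_statistic_batch(dosage: np.ndarray, ctx: PermutationContext) -> np.ndarray:
    """|corr(WE burden, y)| for each context row, recomputing reference-group
    weights from each permuted phenotype."""
    m = dosage.shape[1]
    if m == 0:
        return np.zeros(ctx.B + 1)
    G = dosage.astype(float)
    counts = ctx.ref_rows @ G  # (B+1, m)
    q = (counts + 1.0) / (2.0 * ctx.n_ref + 2.0)
    U = 1.0 / np.sqrt(ctx.n_ref * q * (1.0 - q))  # (B+1, m) inverse weights
    A = ctx.Yc @ G  # (B+1, m) per-variant centered cross-products
    num = (U * A).sum(axis=1)
    Gc = G - G.mean(axis=0, keepdims=True)
    Sigma = Gc.T @ Gc  # (m, m) un-normalized covariance of the columns
    ss = np.einsum("bi,ij,bj->b", U, Sigma, U)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(num) / np.sqrt(ss * ctx.yy)
    z[~np.isfinite(z)] = 0.0
    return z


def _perm_p_we(dosage: np.ndarray, ctx: PermutationContext) -> tuple[float, float]:
    return _pvalue_from_batch(_we_statistic_batch(dosage, ctx))


def rare_gene_test(
    dosage: np.ndarray,
    mafs: np.ndarray,
    y: np.ndarray,
    method: str,
    T: float = 0.05,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    we_reference: str = "median",
    ctx: PermutationContext | None = None,
) -> RareTestResult:
    """Run one rare-variant test (``ft``, ``we`` or ``vt``) on one gene.

    ``ctx`` (a pre-built :class:`PermutationContext`) lets callers share one
    permutation stream across the genes of a family; otherwise ``seed`` and
    ``B`` define a fresh stream.
    """
    y = np.asarray(y, dtype=float)
    if ctx is None:
        ctx = PermutationContext.build(y, B, seed, ref_policy=we_reference)
    method = method.lower()
    if method == "ft":
        sc = ft_burden(dosage, mafs, T)
        p, z = _perm_p_fixed_burden(sc.scores, ctx)
        return RareTestResult(z, p, ctx.B, extra={"empty": sc.empty,
                                                  "n_included": int(sc.included_variants.sum())})
    if method == "we":
        p, z = _perm_p_we(dosage, ctx)
        return RareTestResult(z, p, ctx.B, extra={"n_included": dosage.shape[1]})
    if method == "vt":
        p, z, t_opt = _perm_p_vt(dosage, mafs, ctx)
        return RareTestResult(z, p, ctx.B, T_opt=t_opt,
                              extra={"degenerate": t_opt is None})
    raise InputError(f"unknown rare-variant method {method!r}")


def rare_family_test(
    cohort,
    gene_map,
    gene_ids: Sequence[str],
    y: np.ndarray,
    method: str,
    T: float = 0.05,
    B: int = 1000,
    seed: int = 0,
    we_reference: str = "median",
) -> list[GeneTestResult]:
    """Run one rare-variant test over a family of genes with a single shared
    permutation stream, returning :class:`GeneTestResult` rows."""
    y = np.asarray(y, dtype=float)
    ctx = PermutationContext.build(y, B, seed, ref_policy=we_reference)
    method_name = {"ft": "FT", "we": "WE", "vt": "VT"}[method.lower()]
    out = []
    for gid in gene_ids:
        block, mafs = cohort.gene_block(gene_map, gid)
        r = rare_gene_test(block, mafs, y, method, T=T, B=B,
                           we_reference=we_reference, ctx=ctx)
        extra = dict(r.extra)
        if r.T_opt is not None:
            extra["T_opt"] = r.T_opt
        out.append(
            GeneTestResult(
                gene_id=gid,
                method=method_name,
                threshold=T if method.lower() == "ft" else None,
                statistic=r.statistic,
                p_raw=r.p_raw,
                n_markers_used=int(extra.get("n_included", block.shape[1])),
                extra=extra,
            )
        )
    return out
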