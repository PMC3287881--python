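"""Synthetic exome-cohort simulator.

Generates cohorts that mimic the structure of a sequenced mini-exome panel:
697 unrelated individuals, genes partitioned into a rare-only group (all
variant MAFs < 5%), a mixed rare+common group, and a common-only group, with
per-group SNP counts and MAF distributions matched in the mean to such a
panel (3.155 / 16.336 / 1.106 SNPs per gene; mean rare MAF 0.006).

Population structure is a two-subpopulation Balding-Nichols model: each
variant has an ancestral frequency drawn from the MAF model, and subpopulation
frequencies are Beta-distributed around it with divergence parameter F.  An
ancestry term in the phenotype then acts as a confounder; its strength gamma
is usually set by :func:`calibrate_confounder`, a bisection on gamma targeting
a chosen genomic-inflation factor (lambda ~ 2.3 by default) for per-SNP
association scans on a null trait.

Causal architecture follows the same template: a handful of causal genes in
the rare-only and mixed groups, each with 1-11 trait-increasing causal
variants whose MAFs span 0.0007-0.165.

Every sampled variant is constrained, by rejection, to be polymorphic in the
realized cohort and to fall on the intended side of the 5% sample-MAF split,
so the construction-time gene groups are exactly recoverable from the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special

from ._stats import chi2_from_p, ols_scan
from .data_model import CohortGenotypes, GeneMap, PhenotypeVector, compute_maf, orient_minor

logger = logging.getLogger(__name__)

__all__ = [
    "StudyDesign",
    "CausalModel",
    "simulate_cohort",
    "simulate_phenotype",
    "default_causal_model",
    "calibrate_confounder",
    "rare_maf_mean",
    "write_cohort_files",
]

RARE_SPLIT = 0.05  # sample-MAF boundary between "rare" and "common"


@dataclass
class StudyDesign:
    """Simulator specification.

    Group SNP counts are drawn as ``min + NegBinomial`` with the mean and SD
    matched per group; rare MAFs come from a Beta(a, b) truncated to
    (0, 0.05) whose truncated mean is solved to hit ``rare_maf_mean``; common
    MAFs are uniform on [0.05, 0.45].
    """

    n_individuals: int = 697
    n_genes_per_group: tuple[int, int, int] = (1732, 1142, 331)
    snp_count_mean: tuple[float, float, float] = (3.155, 16.336, 1.106)
    snp_count_sd: tuple[float, float, float] = (4.116, 20.173, 0.387)
    rare_maf_mean: float = 0.006
    rare_maf_a: float = 0.5
    common_maf_range: tuple[float, float] = (0.05, 0.45)
    #: probability that each SNP beyond the guaranteed one-rare-one-common
    #: pair of a mixed gene is common; 0.066 reproduces the observed pooled
    #: mixed-group mean MAF of ~0.035.
    mixed_common_frac: float = 0.066
    n_subpops: int = 2
    divergence: float = 0.05  # Balding-Nichols F
    confounder_effect: float = 0.0  # gamma: phenotype shift per unit ancestry
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_genes_per_group) or self.n_individuals < 2:
            raise ValueError("counts must be positive")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        # solve the Beta b-parameter so the truncated mean matches the target
        a, c, mu = self.rare_maf_a, RARE_SPLIT, self.rare_maf_mean

        def trunc_mean(b: float) -> float:
            return (a / (a + b)) * special.betainc(a + 1, b, c) / special.betainc(a, b, c)

        self._rare_maf_b = float(
            optimize.brentq(lambda b: trunc_mean(b) - mu, 1.0, 5000.0)
        )

    def rare_maf_mean_closed_form(self) -> float:
        """Mean of the truncated-Beta rare-MAF model (equals rare_maf_mean)."""
        a, b, c = self.rare_maf_a, self._rare_maf_b, RARE_SPLIT
        return float((a / (a + b)) * special.betainc(a + 1, b, c) / special.betainc(a, b, c))


def rare_maf_mean(design: StudyDesign) -> float:
    return design.rare_maf_mean_closed_form()


@dataclass
class CausalModel:
    """gene_id -> [(variant_id, beta)]; all effects trait-increasing."""

    causal_genes: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, pairs in self.causal_genes.items():
            if any(beta < 0 for _, beta in pairs):
                raise ValueError(f"gene {g}: causal effects must be non-negative")

    @property
    def causal_gene_ids(self) -> list[str]:
        return list(self.causal_genes)

    def validate_against(self, gene_map: GeneMap) -> None:
        for g, pairs in self.causal_genes.items():
            if g not in gene_map.genes:
                raise ValueError(f"causal gene {g!r} not in gene map")
            members = set(gene_map.genes[g])
            for v, _ in pairs:
                if v not in members:
                    raise ValueError(f"causal variant {v!r} not in gene {g!r}")


# ---------------------------------------------------------------------------
# cohort generation


def _shifted_negbin(rng: np.random.Generator, mean: float, sd: float, minimum: int,
                    size: int) -> np.ndarray:
    """min + NegBinomial with overall mean/SD matched by moments; degenerate
    (underdispersed) parameterizations collapse to the nearest two-point mix."""
    m, v = mean - minimum, sd * sd
    if m <= 0:
        return np.full(size, minimum, dtype=int)
    if v <= m:  # cannot be matched by NB; Bernoulli mix on floor/ceil
        frac = m - np.floor(m)
        return minimum + np.floor(m).astype(int) + (rng.random(size) < frac).astype(int)
    p = m / v
    r = m * m / (v - m)
    return minimum + rng.negative_binomial(r, p, size=size)


def _draw_rare_maf(rng: np.random.Generator, design: StudyDesign, size: int = 1) -> np.ndarray:
    a, b = design.rare_maf_a, design._rare_maf_b
    out = rng.beta(a, b, size=size)
    bad = out >= RARE_SPLIT
    while bad.any():
        out[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = out >= RARE_SPLIT
    return out


def draw_rare_mafs(design: StudyDesign, n: int, seed: int = 0) -> np.ndarray:
    """Expose the rare-MAF model for calibration checks."""
    return _draw_rare_maf(np.random.default_rng(seed), design, size=n)


def _subpop_freqs(rng: np.random.Generator, p0: float, F: float, k: int) -> np.ndarray:
    if F == 0.0:
        return np.full(k, p0)
    a = p0 * (1.0 - F) / F
    b = (1.0 - p0) * (1.0 - F) / F
    return rng.beta(a, b, size=k)


def _draw_variant(rng: np.random.Generator, design: StudyDesign,
                  subpop: np.ndarray, kind: str, max_tries: int = 1000) -> np.ndarray:
    """One oriented dosage column, rejected until polymorphic in the sample
    and on the requested side of the 5% sample-MAF split."""
    lo, hi = design.common_maf_range
    for _ in range(max_tries):
        if kind == "rare":
            p0 = float(_draw_rare_maf(rng, design)[0])
        else:
            p0 = float(rng.uniform(lo, hi))
        freqs = _subpop_freqs(rng, p0, design.divergence, design.n_subpops)
        g = rng.binomial(2, freqs[subpop])
        g, _ = orient_minor(g[:, None])
        maf = float(compute_maf(g)[0])
        if maf <= 0.0:
            continue
        if kind == "rare" and maf < RARE_SPLIT:
            return g[:, 0].astype(np.int8)
        if kind == "common" and maf >= RARE_SPLIT:
            return g[:, 0].astype(np.int8)
    raise RuntimeError(f"could not draw a '{kind}' variant in {max_tries} tries")


def simulate_cohort(design: StudyDesign) -> tuple[CohortGenotypes, GeneMap, np.ndarray]:
    """Generate genotypes, gene map and per-individual ancestry labels.

    Gene ids are prefixed R/M/C for the rare-only, mixed and common-only
    groups; the MAF-based partition recovers the same grouping exactly.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_individuals
    subpop = rng.integers(0, design.n_subpops, size=n)

    n1, n2, n3 = design.n_genes_per_group
    counts1 = _shifted_negbin(rng, design.snp_count_mean[0], design.snp_count_sd[0], 1, n1)
    counts2 = _shifted_negbin(rng, design.snp_count_mean[1], design.snp_count_sd[1], 2, n2)
    counts3 = _shifted_negbin(rng, design.snp_count_mean[2], design.snp_count_sd[2], 1, n3)

    genes: dict[str, list[str]] = {}
    columns: list[np.ndarray] = []
    variant_ids: list[str] = []

    def add_gene(gene_id: str, kinds: list[str]) -> None:
        vids = []
        for j, kind in enumerate(kinds):
            vid = f"{gene_id}_v{j + 1:02d}"
            columns.append(_draw_variant(rng, design, subpop, kind))
            variant_ids.append(vid)
            vids.append(vid)
        genes[gene_id] = vids

    for i, k in enumerate(counts1):
        add_gene(f"R{i + 1:04d}", ["rare"] * int(k))
    for i, k in enumerate(counts2):
        extra = rng.random(int(k) - 2) < design.mixed_common_frac
        kinds = ["rare", "common"] + ["common" if e else "rare" for e in extra]
        rng.shuffle(kinds)
        add_gene(f"M{i + 1:04d}", kinds)
    for i, k in enumerate(counts3):
        add_gene(f"C{i + 1:04d}", ["common"] * int(k))

    if not columns:
        raise ValueError("design generated no variants")
    dosage = np.column_stack(columns)
    sample_ids = [f"ind{i + 1:04d}" for i in range(n)]
    cohort = CohortGenotypes(sample_ids, variant_ids, dosage)
    return cohort, GeneMap(genes), subpop.astype(int)


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotype(
    cohort: CohortGenotypes,
    causal: CausalModel | None,
    ancestry: np.ndarray,
    gamma: float,
    noise_sd: float,
    n_replicates: int = 1,
    seed: int = 0,
) -> list[PhenotypeVector]:
    """y_i = sum_j beta_j g_ij + gamma * ancestry_i + eps_i, eps ~ N(0, sd).

    Replicates redraw the noise only (genotypes and ancestry fixed, the
    phenotype-replicate design of the emulated panel).
    ``causal=None`` gives a pure null-plus-confounder trait.
    """
    rng = np.random.default_rng(seed)
    n = cohort.n_individuals
    ancestry = np.asarray(ancestry, dtype=float)
    if len(ancestry) != n:
        raise ValueError("ancestry length does not match cohort")
    genetic = np.zeros(n)
    if causal is not None:
        lookup = {v: j for j, v in enumerate(cohort.variant_ids)}
        for gene, pairs in causal.causal_genes.items():
            for vid, beta in pairs:
                if vid not in lookup:
                    raise ValueError(f"causal variant {vid!r} absent from cohort")
                genetic += beta * cohort.dosage[:, lookup[vid]]
    out = []
    for r in range(n_replicates):
        eps = rng.normal(0.0, noise_sd, size=n)
        y = genetic + gamma * ancestry + eps
        out.append(PhenotypeVector(list(cohort.sample_ids), y, replicate_label=f"Q1_r{r + 1}"))
    return out


def default_causal_model(
    cohort: CohortGenotypes,
    gene_map: GeneMap,
    rng: np.random.Generator | int = 0,
    n_rare_only: int = 4,
    n_mixed: int = 5,
    max_causal_per_gene: int = 11,
    maf_range: tuple[float, float] = (0.0007, 0.165),
    effect_size: float = 0.5,
) -> CausalModel:
    """Pick causal genes (default 4 rare-only + 5 mixed) and 1-11 causal
    variants each with MAF inside ``maf_range``; constant positive effects."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    lookup = {v: j for j, v in enumerate(cohort.variant_ids)}
    rare_genes = [g for g in gene_map.genes if g.startswith("R")]
    mixed_genes = [g for g in gene_map.genes if g.startswith("M")]
    if len(rare_genes) < n_rare_only or len(mixed_genes) < n_mixed:
        raise ValueError("not enough genes in the requested groups")
    chosen = list(rng.choice(rare_genes, n_rare_only, replace=False)) + \
        list(rng.choice(mixed_genes, n_mixed, replace=False))
    lo, hi = maf_range
    model: dict[str, list[tuple[str, float]]] = {}
    for g in chosen:
        vids = gene_map.genes[g]
        eligible = [v for v in vids if lo <= cohort.maf[lookup[v]] <= hi]
        if not eligible:  # fall back to the gene's most frequent variant
            eligible = [max(vids, key=lambda v: cohort.maf[lookup[v]])]
        k = int(rng.integers(1, min(max_causal_per_gene, len(eligible)) + 1))
        picked = rng.choice(eligible, size=k, replace=False)
        model[g] = [(str(v), float(effect_size)) for v in picked]
    return CausalModel(model)


# ---------------------------------------------------------------------------
# confounder calibration


def scan_lambda(cohort: CohortGenotypes, y: np.ndarray) -> float:
    """Mean-based genomic-inflation factor of the per-SNP regression scan
    (polymorphic variants only)."""
    poly = cohort.maf > 0
    _, _, p = ols_scan(cohort.dosage[:, poly].astype(float), np.asarray(y, dtype=float))
    return float(chi2_from_p(p).mean())


def calibrate_confounder(
    cohort: CohortGenotypes,
    ancestry: np.ndarray,
    target_lambda: float = 2.3,
    noise_sd: float = 1.0,
    n_replicates: int = 12,
    seed: int = 0,
    gamma_hi: float = 16.0,
    tol: float = 0.05,
    max_iter: int = 40,
) -> float:
    """Bisection on the confounder strength gamma so that the per-SNP scan
    of a null trait has mean-based inflation ~ ``target_lambda``."""

    def lam(gamma: float) -> float:
        phenos = simulate_phenotype(cohort, None, ancestry, gamma, noise_sd,
                                    n_replicates=n_replicates, seed=seed)
        return float(np.mean([scan_lambda(cohort, p.values) for p in phenos]))

    lo, hi = 0.0, gamma_hi
    f_hi = lam(hi)
    while f_hi < target_lambda:
        hi *= 2.0
        f_hi = lam(hi)
        if hi > 1e4:
            raise RuntimeError("confounder cannot reach the target inflation; "
                               "increase divergence")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = lam(mid)
        if abs(f_mid - target_lambda) <= tol:
            logger.info("calibrated gamma=%.4f (lambda=%.3f)", mid, f_mid)
            return mid
        if f_mid < target_lambda:
            lo = mid
        else:
            hi = mid
    logger.warning("calibration hit max_iter; returning midpoint")
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# file output


def write_cohort_files(
    cohort: CohortGenotypes,
    gene_map: GeneMap,
    phenotypes: list[PhenotypeVector],
    out_prefix: str | Path,
    causal: CausalModel | None = None,
    ancestry: np.ndarray | None = None,
) -> dict[str, Path]:
    """Write genotype TSV + VCF, phenotype TSV, gene-map TSV and (when a
    causal model is given) a truth table; returns the paths written."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    geno = prefix.with_suffix(".genotypes.tsv")
    pd.DataFrame(cohort.dosage, index=pd.Index(cohort.sample_ids, name="sample_id"),
                 columns=cohort.variant_ids).to_csv(geno, sep="\t")
    paths["genotypes_tsv"] = geno

    vcf = prefix.with_suffix(".genotypes.vcf")
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(cohort.sample_ids) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, vid in enumerate(cohort.variant_ids):
            gts = "\t".join(gt_str[int(g)] for g in cohort.dosage[:, j])
            fh.write(f"1\t{j + 1}\t{vid}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")
    paths["genotypes_vcf"] = vcf

    pheno = prefix.with_suffix(".phenotypes.tsv")
    df = pd.DataFrame({"sample_id": cohort.sample_ids})
    for p in phenotypes:
        df[p.replicate_label] = p.values
    df.to_csv(pheno, sep="\t", index=False)
    paths["phenotypes_tsv"] = pheno

    gmap = prefix.with_suffix(".gene_map.tsv")
    rows = [(v, g) for g, vids in gene_map.genes.items() for v in vids]
    pd.DataFrame(rows, columns=["variant_id", "gene_id"]).to_csv(gmap, sep="\t", index=False)
    paths["gene_map_tsv"] = gmap

    if causal is not None:
        truth = prefix.with_suffix(".truth.tsv")
        rows = [(g, v, b) for g, pairs in causal.causal_genes.items() for v, b in pairs]
        pd.DataFrame(rows, columns=["gene_id", "variant_id", "beta"]).to_csv(
            truth, sep="\t", index=False)
        paths["truth_tsv"] = truth
    if ancestry is not None:
        anc = prefix.with_suffix(".ancestry.tsv")
        pd.DataFrame({"sample_id": cohort.sample_ids, "subpop": ancestry}).to_csv(
            anc, sep="\t", index=False)
        paths["ancestry_tsv"] = anc
    return paths
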