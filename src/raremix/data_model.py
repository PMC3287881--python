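"""Core domain types and file I/O.

The central container is :class:`CohortGenotypes`: an individuals x variants
matrix of minor-allele dosages (0/1/2) with per-variant sample minor-allele
frequencies (MAF).  Genotypes can be loaded from a VCF (GT field, biallelic
sites only) or from a plain TSV dosage matrix.  Variants are keyed by
identifier only; genomic coordinates play no role in any analysis here.

Alleles are oriented per loaded sample set: whenever the coded allele turns
out to be the major allele in the sample, dosages are flipped (g -> 2 - g) so
that every column counts copies of the sample minor allele and maf <= 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Methods a GeneTestResult may carry.
METHODS = ("FT", "WE", "VT", "CV_pmin", "CV_lasso", "COMB_pmin", "COMB_lasso")

RESULT_COLUMNS = [
    "gene_id",
    "method",
    "threshold",
    "statistic",
    "p_raw",
    "p_corrected",
    "n_markers_used",
    "extra",
]


class InputError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class CohortGenotypes:
    """Additive-coded genotypes for a cohort.

    Parameters
    ----------
    sample_ids : ordered unique individual identifiers.
    variant_ids : ordered unique variant identifiers.
    dosage : (n_individuals, n_variants) int8 matrix of minor-allele counts.
    maf : per-variant sample minor-allele frequency, in [0, 0.5].
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosage: np.ndarray
    maf: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        if self.dosage.ndim != 2:
            raise InputError("dosage must be 2-D (individuals x variants)")
        n, m = self.dosage.shape
        if n != len(self.sample_ids) or m != len(self.variant_ids):
            raise InputError("dosage shape does not match identifier lists")
        if len(set(self.sample_ids)) != n:
            raise InputError("duplicate sample_ids")
        if len(set(self.variant_ids)) != m:
            raise InputError("duplicate variant_ids")
        if self.dosage.size and not np.isin(self.dosage, (0, 1, 2)).all():
            raise InputError("dosage entries must be 0, 1 or 2")
        self.dosage = self.dosage.astype(np.int8, copy=False)
        if self.maf is None:
            self.maf = compute_maf(self.dosage)
        else:
            self.maf = np.asarray(self.maf, dtype=float)

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def variant_index(self, variant_ids: Sequence[str]) -> np.ndarray:
        """Column indices of the given variant ids (order preserved)."""
        lookup = {v: j for j, v in enumerate(self.variant_ids)}
        try:
            return np.array([lookup[v] for v in variant_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise InputError(f"unknown variant id {exc.args[0]!r}") from exc

    def gene_block(self, gene_map: "GeneMap", gene_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(dosage submatrix, mafs) for one gene."""
        idx = self.variant_index(gene_map.genes[gene_id])
        return self.dosage[:, idx], self.maf[idx]


def compute_maf(dosage: np.ndarray) -> np.ndarray:
    """Sample minor-allele frequency of each (already oriented) column."""
    n = dosage.shape[0]
    if n == 0:
        return np.zeros(dosage.shape[1])
    return dosage.sum(axis=0) / (2.0 * n)


def orient_minor(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip columns coded on the major allele so every column counts the
    sample minor allele.  Returns (oriented dosage, flipped-column mask).
    Ties (frequency exactly 0.5) are left as coded."""
    freq = dosage.sum(axis=0) / (2.0 * dosage.shape[0])
    flip = freq > 0.5
    out = dosage.copy()
    out[:, flip] = 2 - out[:, flip]
    return out, flip


@dataclass
class GeneMap:
    """Assignment of variants to genes; a variant belongs to at most one gene."""

    genes: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for g, variants in self.genes.items():
            for v in variants:
                if v in seen:
                    raise InputError(
                        f"variant {v!r} assigned to both {seen[v]!r} and {g!r}"
                    )
                seen[v] = g

    def validate_against(self, cohort: CohortGenotypes) -> None:
        known = set(cohort.variant_ids)
        for g, variants in self.genes.items():
            missing = [v for v in variants if v not in known]
            if missing:
                raise InputError(
                    f"gene {g!r} references unknown variants {missing[:3]}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes)


@dataclass
class PhenotypeVector:
    """A quantitative trait aligned to a cohort's sample order."""

    sample_ids: list[str]
    values: np.ndarray
    replicate_label: str = "pheno"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.sample_ids):
            raise InputError("phenotype values must be 1-D and match sample_ids")
        if not np.isfinite(self.values).all():
            raise InputError("phenotype contains non-finite values")


@dataclass
class GeneTestResult:
    """One gene x one method."""

    gene_id: str
    method: str
    statistic: float
    p_raw: float
    p_corrected: float | None = None
    threshold: float | None = None
    n_markers_used: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise InputError(f"unknown method {self.method!r}")
        if not (0.0 < self.p_raw <= 1.0):
            raise InputError(f"p_raw {self.p_raw} outside (0, 1]")
        if self.p_corrected is not None and not (0.0 < self.p_corrected <= 1.0):
            raise InputError(f"p_corrected {self.p_corrected} outside (0, 1]")


@dataclass
class AnalysisConfig:
    """Shared knobs: rare/common MAF threshold, permutations, seed, alpha."""

    rare_threshold: float = 0.05
    n_permutations: int = 1000
    seed: int = 0
    alpha: float = 0.05
    correction: str = "bonferroni"
    gc: bool = True
    we_reference: str = "median"  # or "all"

    def __post_init__(self) -> None:
        if not (0.0 < self.rare_threshold <= 0.5):
            raise InputError("rare_threshold must lie in (0, 0.5]")
        if self.n_permutations < 1:
            raise InputError("need at least one permutation")
        if not (0.0 < self.alpha < 1.0):
            raise InputError("alpha must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Loading


def _load_genotypes_tsv(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        mat = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise InputError(f"non-numeric entry in genotype TSV {path}: {exc}") from exc
    if np.isnan(mat).any():
        i, j = np.argwhere(np.isnan(mat))[0]
        raise InputError(f"missing genotype at row {df.index[i]!r}, column {df.columns[j]!r}")
    if not np.isin(mat, (0, 1, 2)).all():
        raise InputError(f"genotype TSV {path} has entries outside 0/1/2")
    return list(df.index), list(df.columns), mat.astype(np.int8)


def _load_genotypes_vcf(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variant_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_missing = 0
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            raise InputError(
                f"multi-allelic record at line for {rec.CHROM}:{rec.POS}; "
                "split or drop multi-allelic sites before loading"
            )
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = rec.gt_types.copy()
        miss = gt == 2
        n_missing += int(miss.sum())
        dos = np.where(gt == 3, 2, gt)
        dos[miss] = 0  # missing -> 0 minor-allele copies (conservative for burdens)
        variant_ids.append(vid)
        columns.append(dos.astype(np.int8))
    if n_missing:
        logger.info("imputed %d missing genotypes to 0 copies", n_missing)
    if not columns:
        raise InputError(f"VCF {path} contains no records")
    if len(set(variant_ids)) != len(variant_ids):
        raise InputError(f"VCF {path} has duplicate variant identifiers")
    return samples, variant_ids, np.column_stack(columns)


def load_phenotypes(path: str | Path) -> list[PhenotypeVector]:
    """Read a phenotype TSV: sample_id column plus one column per replicate."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise InputError(f"phenotype file {path} needs sample_id plus >=1 value column")
    sample_ids = list(df.iloc[:, 0].astype(str))
    out = []
    for col in df.columns[1:]:
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy()
        if np.isnan(vals).any():
            raise InputError(f"non-numeric phenotype in column {col!r} of {path}")
        out.append(PhenotypeVector(sample_ids, vals, replicate_label=str(col)))
    return out


def load_gene_map(path: str | Path) -> GeneMap:
    """Read a two-column TSV (variant_id, gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"variant_id", "gene_id"} <= set(df.columns):
        raise InputError(f"gene map {path} must have columns variant_id, gene_id")
    genes: dict[str, list[str]] = {}
    for v, g in zip(df["variant_id"], df["gene_id"]):
        genes.setdefault(g, []).append(v)
    return GeneMap(genes)


def load_cohort(
    genotype_source: str | Path,
    phenotype_path: str | Path,
    gene_map_path: str | Path,
) -> tuple[CohortGenotypes, list[PhenotypeVector], GeneMap]:
    """Load genotypes (VCF or TSV matrix), phenotypes and gene map, intersect
    samples, and orient every variant on its sample minor allele.

    Monomorphic variants are retained with maf = 0; they contribute nothing
    to any downstream score.
    """
    genotype_source = Path(genotype_source)
    if genotype_source.suffix in (".vcf", ".gz", ".bcf"):
        samples, variant_ids, dosage = _load_genotypes_vcf(genotype_source)
    else:
        samples, variant_ids, dosage = _load_genotypes_tsv(genotype_source)

    phenos = load_phenotypes(phenotype_path)
    pheno_samples = phenos[0].sample_ids
    common = [s for s in samples if s in set(pheno_samples)]
    if not common:
        raise InputError("no overlapping samples between genotypes and phenotypes")
    if len(common) < len(samples):
        logger.info("dropping %d genotyped samples without phenotype", len(samples) - len(common))

    g_order = {s: i for i, s in enumerate(samples)}
    p_order = {s: i for i, s in enumerate(pheno_samples)}
    dosage = dosage[[g_order[s] for s in common], :]
    dosage, flipped = orient_minor(dosage)
    if flipped.any():
        logger.info("re-oriented %d variants onto the sample minor allele", int(flipped.sum()))
    cohort = CohortGenotypes(common, variant_ids, dosage)

    n_mono = int((cohort.maf == 0).sum())
    if n_mono:
        logger.info("%d variants are monomorphic in the loaded sample", n_mono)

    pidx = [p_order[s] for s in common]
    phenos = [
        PhenotypeVector(list(common), p.values[pidx], p.replicate_label) for p in phenos
    ]

    gene_map = load_gene_map(gene_map_path)
    gene_map.validate_against(cohort)
    return cohort, phenos, gene_map


# ---------------------------------------------------------------------------
# Result tables


def _format_extra(extra: Mapping) -> str:
    if not extra:
        return "."
    return ";".join(f"{k}={v}" for k, v in sorted(extra.items()))


def _parse_extra(text: str) -> dict:
    if text in (".", "", None) or (isinstance(text, float) and np.isnan(text)):
        return {}
    out: dict = {}
    for item in str(text).split(";"):
        k, _, v = item.partition("=")
        try:
            out[k] = float(v)
        except ValueError:
            out[k] = v
    return out


def results_to_frame(results: Iterable[GeneTestResult]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": r.gene_id,
            "method": r.method,
            "threshold": "." if r.threshold is None else r.threshold,
            "statistic": r.statistic,
            "p_raw": r.p_raw,
            "p_corrected": "." if r.p_corrected is None else r.p_corrected,
            "n_markers_used": r.n_markers_used,
            "extra": _format_extra(r.extra),
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return df.sort_values(["gene_id", "method"], kind="mergesort").reset_index(drop=True)


def write_results(results: Sequence[GeneTestResult], path: str | Path) -> None:
    """Write one row per (gene, method), sorted by (gene_id, method)."""
    if not results:
        raise InputError("refusing to write an empty result table")
    results_to_frame(results).to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> list[GeneTestResult]:
    """Inverse of :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "method": str})
    out = []
    for _, row in df.iterrows():
        thr = row["threshold"]
        pc = row["p_corrected"]
        out.append(
            GeneTestResult(
                gene_id=row["gene_id"],
                method=row["method"],
                threshold=None if str(thr) == "." else float(thr),
                statistic=float(row["statistic"]),
                p_raw=float(row["p_raw"]),
                p_corrected=None if str(pc) == "." else float(pc),
                n_markers_used=int(row["n_markers_used"]),
                extra=_parse_extra(row["extra"]),
            )
        )
    return out
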