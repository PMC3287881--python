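"""Gene partitioning, power / type-I estimation, QQ tables, and the
end-to-end pipeline.

The analysis strategy mirrors the gene-group design: the rare-only group is
analyzed with the collapsing tests only; the mixed group additionally gets
the common-variant tests and the Fisher-combined tests.  Genomic control is
estimated per method family and per phenotype replicate, and the combined
test is built from components that were genomic-control corrected within
their own family (Fisher's chi-square reference needs null-uniform inputs).

Power counts a causal gene as detected when its corrected p-value beats a
Bonferroni threshold over the genes tested in its group; the type I error
rate is the plain per-test rate at alpha among non-causal genes — the same
asymmetric convention used in the comparison this harness reproduces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .combine import apply_gc_to_results, fisher_combine
from .common_tests import common_family_test
from .data_model import (
    CohortGenotypes,
    GeneMap,
    GeneTestResult,
    InputError,
    PhenotypeVector,
    results_to_frame,
)
from .rare_tests import PermutationContext, rare_gene_test
from .simulate import (
    CausalModel,
    StudyDesign,
    calibrate_confounder,
    default_causal_model,
    simulate_cohort,
    simulate_phenotype,
    write_cohort_files,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GenePartition",
    "EvaluationReport",
    "PipelineConfig",
    "partition_genes",
    "estimate_power_type1",
    "qq_table",
    "rank_causal_genes",
    "analyze_replicate",
    "run_pipeline",
]


@dataclass
class GenePartition:
    group1: list[str]  # rare-only
    group2: list[str]  # mixed
    group3: list[str]  # common-only
    threshold: float = 0.05

    def group_of(self, gene_id: str) -> int | None:
        for i, grp in enumerate((self.group1, self.group2, self.group3), start=1):
            if gene_id in grp:
                return i
        return None


def partition_genes(cohort: CohortGenotypes, gene_map: GeneMap, T: float = 0.05
                    ) -> GenePartition:
    """Split genes by variant MAF at T: all < T -> group 1 (rare-only);
    all >= T -> group 3 (common-only); otherwise group 2 (mixed).
    Genes with zero variants are excluded with a warning."""
    g1, g2, g3 = [], [], []
    for gid, vids in gene_map.genes.items():
        if not vids:
            logger.warning("gene %s has no variants; excluded from partition", gid)
            continue
        mafs = cohort.maf[cohort.variant_index(vids)]
        if (mafs < T).all():
            g1.append(gid)
        elif (mafs >= T).all():
            g3.append(gid)
        else:
            g2.append(gid)
    return GenePartition(g1, g2, g3, threshold=T)


def estimate_power_type1(
    results_by_replicate: Sequence[Sequence[GeneTestResult]],
    truth: set[str] | Sequence[str],
    alpha: float,
    n_genes_in_group: int | None = None,
) -> dict[str, float]:
    """Power and per-test type I error over replicates of one method family.

    Power: fraction of (causal gene, replicate) pairs with corrected
    p < alpha / N, N = number of genes tested in the group (Bonferroni).
    Type I error: fraction of non-causal gene results with corrected
    p < alpha (no multiplicity correction — a per-test rate).
    """
    truth = set(truth)
    gene_sets = [frozenset(r.gene_id for r in rep) for rep in results_by_replicate]
    if len(set(gene_sets)) > 1:
        raise InputError("replicates tested different gene sets")
    n_genes = n_genes_in_group or len(gene_sets[0])
    bonf = alpha / n_genes if n_genes else alpha

    causal_trials = causal_hits = 0
    null_trials = null_hits = 0
    for rep in results_by_replicate:
        for r in rep:
            p = r.p_corrected if r.p_corrected is not None else r.p_raw
            if r.gene_id in truth:
                causal_trials += 1
                causal_hits += p < bonf
            else:
                null_trials += 1
                null_hits += p < alpha
    return {
        "power": causal_hits / causal_trials if causal_trials else float("nan"),
        "type1": null_hits / null_trials if null_trials else float("nan"),
        "n_causal_trials": causal_trials,
        "n_null_trials": null_trials,
        "bonferroni_threshold": bonf,
    }


def qq_table(p_family: Sequence[float]) -> pd.DataFrame:
    """Ordered (expected, observed) -log10 p pairs; expected quantiles are
    the (k - 0.5)/N midpoints."""
    p = np.sort(np.asarray(p_family, dtype=float))
    if p.size == 0:
        raise InputError("empty p-value family")
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({
        "expected_neglog10": -np.log10(expected),
        "observed_neglog10": -np.log10(p),
    })


def rank_causal_genes(
    results: Sequence[GeneTestResult],
    truth: Sequence[str],
) -> list[dict]:
    """Rank of each causal gene by ascending corrected p (average-rank ties);
    untested truth genes are reported with rank None."""
    p = np.array([
        r.p_corrected if r.p_corrected is not None else r.p_raw for r in results
    ])
    ranks = stats.rankdata(p, method="average")
    by_gene = {r.gene_id: (float(p[i]), float(ranks[i])) for i, r in enumerate(results)}
    out = []
    for g in truth:
        if g in by_gene:
            pv, rk = by_gene[g]
            out.append({"gene_id": g, "p": pv, "rank": rk})
        else:
            out.append({"gene_id": g, "p": None, "rank": None})
    return out


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Configuration for the end-to-end run.

    Either ``design`` (simulate) or the three input paths must be given.
    ``gamma='calibrate'`` runs the confounder calibration before simulating
    phenotypes; a float uses that value directly.
    """

    design: StudyDesign | None = None
    genotype_path: str | None = None
    phenotype_path: str | None = None
    gene_map_path: str | None = None

    n_replicates: int = 2
    causal: str | CausalModel | None = None  # None, "default", or a model
    gamma: float | str = 0.0
    target_lambda: float = 2.3
    effect_size: float = 0.5

    rare_threshold: float = 0.05
    partition_threshold: float = 0.05
    B: int = 1000
    alpha: float = 0.05
    seed: int = 0
    gc: bool = True
    common_methods: tuple[str, ...] = ("pmin", "lasso")
    rare_methods: tuple[str, ...] = ("ft", "we", "vt")
    we_reference: str = "median"
    out_dir: str | None = None


@dataclass
class EvaluationReport:
    power: pd.DataFrame           # method x group power / type1 table
    lambdas: pd.DataFrame         # per replicate x method family
    ranks: pd.DataFrame           # causal-gene ranks, replicate 1
    qq: dict[str, pd.DataFrame]   # method -> QQ table (replicate 1, pre-GC)
    results: dict = field(default_factory=dict)  # (replicate, family) -> results


def analyze_replicate(
    cohort: CohortGenotypes,
    gene_map: GeneMap,
    partition: GenePartition,
    y: np.ndarray,
    cfg: PipelineConfig,
    rep_seed: int,
) -> dict[str, list[GeneTestResult]]:
    """All test families for one phenotype replicate, before genomic control.

    Families: '<method>_g1' over group 1, '<method>_g2' over group 2 for the
    rare tests; 'CV_<m>' over group 2; 'FTcomp' = FT on the rare subset of
    each group-2 gene (the combined test's rare component).
    """
    ctx = PermutationContext.build(np.asarray(y, dtype=float), cfg.B, rep_seed,
                                   ref_policy=cfg.we_reference)
    T = cfg.rare_threshold
    fam: dict[str, list[GeneTestResult]] = {}

    for method in cfg.rare_methods:
        name = method.upper()
        for glabel, genes in (("g1", partition.group1), ("g2", partition.group2)):
            rows = []
            for gid in genes:
                block, mafs = cohort.gene_block(gene_map, gid)
                r = rare_gene_test(block, mafs, y, method, T=T, ctx=ctx,
                                   we_reference=cfg.we_reference)
                rows.append(GeneTestResult(
                    gene_id=gid, method=name,
                    threshold=T if method == "ft" else None,
                    statistic=r.statistic, p_raw=r.p_raw,
                    n_markers_used=int(r.extra.get("n_included", block.shape[1])),
                    extra={k: v for k, v in r.extra.items() if k != "n_included"},
                ))
            if rows:
                fam[f"{name}_{glabel}"] = rows

    for cm in cfg.common_methods:
        rows = common_family_test(cohort, gene_map, partition.group2, y, cm, T=T)
        if rows:
            fam[f"CV_{cm}"] = rows

    # FT on the rare subset only, for the combined test's rare component
    rows = []
    for gid in partition.group2:
        block, mafs = cohort.gene_block(gene_map, gid)
        rare_cols = mafs < T
        r = rare_gene_test(block[:, rare_cols], mafs[rare_cols], y, "ft", T=T,
                           ctx=ctx)
        rows.append(GeneTestResult(
            gene_id=gid, method="FT", threshold=T, statistic=r.statistic,
            p_raw=r.p_raw, n_markers_used=int(rare_cols.sum()),
        ))
    if rows:
        fam["FTcomp"] = rows
    return fam


def _combine_families(
    ft_component: Sequence[GeneTestResult],
    cv_family: Sequence[GeneTestResult],
    method_name: str,
    threshold: float,
) -> list[GeneTestResult]:
    """Fisher-combine matched (gene) pairs of corrected component p-values."""
    cv = {r.gene_id: r for r in cv_family}
    out = []
    for fr in ft_component:
        if fr.gene_id not in cv:
            continue
        cr = cv[fr.gene_id]
        p_rare = fr.p_corrected if fr.p_corrected is not None else fr.p_raw
        p_common = cr.p_corrected if cr.p_corrected is not None else cr.p_raw
        comb = fisher_combine((p_rare, p_common))
        out.append(GeneTestResult(
            gene_id=fr.gene_id, method=method_name, threshold=threshold,
            statistic=comb.U, p_raw=comb.p_comb, p_corrected=comb.p_comb,
            n_markers_used=fr.n_markers_used + cr.n_markers_used,
            extra={"p_rare": p_rare, "p_common": p_common},
        ))
    return out


def run_pipeline(cfg: PipelineConfig) -> EvaluationReport:
    """simulate/load -> partition -> per-group tests -> genomic control ->
    combine -> power/type-I evaluation.  Fully seeded and deterministic."""
    if cfg.design is not None:
        cohort, gene_map, ancestry = simulate_cohort(cfg.design)
        gamma = cfg.gamma
        if gamma == "calibrate":
            gamma = calibrate_confounder(cohort, ancestry, cfg.target_lambda,
                                         noise_sd=cfg.design.noise_sd,
                                         seed=cfg.seed + 101)
        causal = cfg.causal
        if causal == "default":
            causal = default_causal_model(cohort, gene_map,
                                          rng=np.random.default_rng(cfg.seed + 7),
                                          effect_size=cfg.effect_size)
        phenos = simulate_phenotype(cohort, causal, ancestry, float(gamma),
                                    cfg.design.noise_sd, cfg.n_replicates,
                                    seed=cfg.seed + 1)
    else:
        from .data_model import load_cohort

        if not (cfg.genotype_path and cfg.phenotype_path and cfg.gene_map_path):
            raise InputError("config must give a design or all three input paths")
        cohort, phenos, gene_map = load_cohort(cfg.genotype_path, cfg.phenotype_path,
                                               cfg.gene_map_path)
        phenos = phenos[: cfg.n_replicates]
        causal = cfg.causal if isinstance(cfg.causal, CausalModel) else None

    partition = partition_genes(cohort, gene_map, T=cfg.partition_threshold)
    logger.info("partition: %d rare-only, %d mixed, %d common-only genes",
                len(partition.group1), len(partition.group2), len(partition.group3))

    truth = set(causal.causal_gene_ids) if isinstance(causal, CausalModel) else set()

    per_rep_families: list[dict[str, list[GeneTestResult]]] = []
    lam_rows = []
    for rep, pheno in enumerate(phenos):
        fam = analyze_replicate(cohort, gene_map, partition, pheno.values, cfg,
                                rep_seed=cfg.seed + 1000 + rep)
        if cfg.gc:
            corrected = {}
            lam_row: dict[str, float] = {"replicate": rep + 1}
            for name, rows in fam.items():
                use_corr = name.startswith("CV_")  # CV families: marker-corrected p
                adj, rows_c = apply_gc_to_results(rows, use_corrected=use_corr)
                corrected[name] = rows_c
                lam_row[name] = adj.lam
            fam = corrected
            lam_rows.append(lam_row)
        else:
            for name, rows in fam.items():
                for r in rows:
                    if r.p_corrected is None:
                        r.p_corrected = r.p_raw
        for cm in cfg.common_methods:
            cv_name = f"CV_{cm}"
            if "FTcomp" in fam and cv_name in fam:
                fam[f"COMB_{cm}"] = _combine_families(
                    fam["FTcomp"], fam[cv_name],
                    "COMB_pmin" if cm == "pmin" else "COMB_lasso",
                    cfg.rare_threshold,
                )
        per_rep_families.append(fam)

    power_rows = []
    family_names = sorted({k for fam in per_rep_families for k in fam})
    group_sizes = {"g1": len(partition.group1), "g2": len(partition.group2)}
    for name in family_names:
        if name == "FTcomp":
            continue
        reps = [fam[name] for fam in per_rep_families if name in fam]
        if len(reps) != len(per_rep_families):
            continue
        n_group = group_sizes.get(name[-2:], len(partition.group2))
        est = estimate_power_type1(reps, truth, cfg.alpha, n_genes_in_group=n_group)
        power_rows.append({"family": name, **est})
    power = pd.DataFrame(power_rows)

    lambdas = pd.DataFrame(lam_rows) if lam_rows else pd.DataFrame()

    rank_rows = []
    if truth:
        for name in family_names:
            if name == "FTcomp" or name not in per_rep_families[0]:
                continue
            for entry in rank_causal_genes(per_rep_families[0][name], sorted(truth)):
                rank_rows.append({"family": name, **entry})
    ranks = pd.DataFrame(rank_rows)

    qq = {}
    first = per_rep_families[0]
    for name, rows in first.items():
        if name == "FTcomp":
            continue
        qq[name] = qq_table([r.p_raw for r in rows])

    report = EvaluationReport(power=power, lambdas=lambdas, ranks=ranks, qq=qq,
                              results={"per_replicate": per_rep_families})

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        power.to_csv(out / "power_type1.tsv", sep="\t", index=False)
        if not lambdas.empty:
            lambdas.to_csv(out / "lambdas.tsv", sep="\t", index=False)
        if not ranks.empty:
            ranks.to_csv(out / "causal_ranks.tsv", sep="\t", index=False)
        for name, tab in qq.items():
            tab.to_csv(out / f"qq_{name}.tsv", sep="\t", index=False)
        for rep, fam in enumerate(per_rep_families):
            allrows = [r for name, rows in fam.items() if name != "FTcomp"
                       for r in rows]
            results_to_frame(allrows).to_csv(out / f"results_rep{rep + 1}.tsv",
                                             sep="\t", index=False)
        if cfg.design is not None:
            write_cohort_files(cohort, gene_map, phenos, out / "cohort",
                               causal=causal if isinstance(causal, CausalModel) else None,
                               ancestry=ancestry)
    return report
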