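# Methods

`raremix` tests genes for association with a quantitative trait in exome
sequence data by combining rare-variant collapsing tests with common-variant
regression summaries, and ships a cohort simulator for studying the power and
type-I behavior of those tests under population-structure confounding.

## Gene groups and analysis strategy

Genes are partitioned at a 5% sample minor-allele-frequency (MAF) split:
group 1 holds genes whose variants are all rare (MAF < 0.05), group 3 genes
whose variants are all common (MAF ≥ 0.05), and group 2 the mixed genes.
Rare-variant collapsing tests are applied to groups 1 and 2; common-variant
tests and the Fisher-combined test are defined on group 2 only, since they
need the common subset (and the combined test needs both subsets).  The
boundary convention is exact and complementary: the fixed-threshold burden
uses strict `maf < T`, common-variant eligibility uses `maf >= T`, so the two
subsets partition every gene — a requirement for treating their p-values as
coming from disjoint data in the combination.

## Rare-variant collapsing tests

All three tests reduce a gene's dosage submatrix `G` (individuals × variants,
minor-allele counts 0/1/2) to a per-individual burden score `s_i` and measure
its association with the phenotype `y`:

* **FT** (fixed threshold): `s_i = Σ_{j: maf_j < T} g_ij`, unweighted.
  An empty inclusion set produces an all-zero score that is flagged and can
  never reach significance (its statistic is defined as 0).
* **WE** (weighted): every variant in the gene contributes `g_ij / w_j` with
  Madsen–Browning weights `w_j = sqrt(n_ref q_j (1−q_j))`,
  `q_j = (c_j + 1) / (2 n_ref + 2)`, where `c_j` is the variant's minor-allele
  count in a reference group.  The original weights use unaffected controls;
  for a quantitative trait the default reference group is the individuals at
  or below the sample median of `y` (option: the full sample).
* **VT** (variable threshold): the FT-style score is evaluated at every
  candidate threshold — the distinct observed MAFs of the gene's polymorphic
  variants, with inclusion `maf ≤ t` so each variant enters at its own MAF —
  and the maximal absolute association over thresholds is the statistic,
  reported with the smallest maximizing threshold `T_opt`.

The association statistic is the Pearson correlation between burden and
phenotype, two-sided via its absolute value.  Correlation is scale-free
(all three tests are invariant to affine transforms of `y`) and orders
permutations identically to the score statistics used by the standard
implementations of these tests, which is all that matters for permutation
significance.  Constant burden or constant phenotype gives a statistic of 0.

Significance is by phenotype permutation with the positively biased
estimator `p = (1 + #{z_b ≥ z_obs}) / (B + 1)`, which can never return 0.
The *entire* statistic is recomputed inside each permutation: VT re-runs its
threshold search, WE re-forms its reference group and weights from the
permuted phenotype.  One permutation stream is shared by all genes of a test
family (a `PermutationContext` of pre-centered permuted phenotypes), which
both speeds the computation up by two orders of magnitude and makes the
family's p-values comparable under genomic control.

## Common-variant tests

* **CV_pmin**: ordinary least squares of `y` on each eligible dosage column
  (additive coding, intercept included); two-sided p from the slope t
  statistic on n−2 df; the gene summary is `min(1, m · min_j p_j)` with `m`
  the number of polymorphic markers tested (Bonferroni).
* **CV_lasso**: the LASSO regularization path on the standardized eligible
  dosages (least-angle implementation), scoring each breakpoint model k with
  the Mallows-Cp analogue `Cp_k = RSS_k / σ̂² − n + 2 df_k`, where `df_k` is
  the number of nonzero coefficients.  `σ̂²` is the residual mean square of
  the unpenalized all-variant OLS fit when `m ≤ n − 2`, else the smallest
  residual mean square along the path (flagged fallback).  Ties in Cp go to
  the smaller model.  The minimum-Cp variant set is refit by unpenalized OLS
  and its overall F-test against the intercept-only model is the gene
  p-value (the F = t² identity makes this coincide with CV_pmin on
  single-variant selections); an empty selection is defined as p = 1.  The
  Bonferroni factor here is the *total* number of SNPs in the gene, a
  deliberately conservative choice given that the selection consumed the
  whole gene.  No post-selection adjustment of the refit F-test is
  attempted; the naive refit is what the conservative correction
  presupposes.

## Combined test

For a mixed gene, the rare signal (FT permutation p on the `maf < T` subset)
and the common signal (marker-corrected CV p on the `maf ≥ T` subset) are
combined with Fisher's method: `U = −2 Σ ln p_i ~ χ²_{2n}` under the null
(n = 2 here).  Independence of the components holds by construction in the
simulator (no linkage disequilibrium) and is an acknowledged approximation
on real data.  When genomic control is active, each component is corrected
*within its own family before* combination, because the chi-square reference
for U requires null-uniform inputs; combining first and correcting after
would leave the combination built from inflated components.

## Genomic control

Each raw p-value in a family is mapped to the 1-df chi-square quantile with
that upper tail; the inflation factor λ is the mean of those chi-squares
(the null expectation is exactly 1); statistics are divided by λ and mapped
back.  λ is estimated per test family and per phenotype replicate, and is
floored at 1 by default (`allow_deflation` disables the floor; all flagged).
The mean ratio rather than the median ratio is used throughout.

Two practical couplings deserve note:

* **Permutation resolution.**  After division by λ, significance at level α
  requires a raw p below `sf(λ · χ²₁(α))`; for λ ≈ 2.5 and α = 0.05 that is
  ≈ 0.0015, so the permutation count must satisfy `1/(B+1) ≪ 0.0015` or
  corrected significance becomes unreachable and measured type-I error
  collapses.  Calibration studies here use B = 2000–8000 for this reason;
  B = 1000 (the default for single analyses) is fine for reporting raw
  permutation p-values but too coarse for GC-corrected tail inference at
  these inflation levels.
* **Family shape.**  Mean-ratio GC is exact for families whose statistics
  are a common scale multiple of χ²₁.  Burden-test families are close to
  that shape under the mean-shift confounder; the CV_pmin family is not
  (a Bonferroni-corrected minimum over markers has a shorter bulk and longer
  tail), so GC overcorrects it and its post-correction type-I error runs
  conservative (~0.03 in our calibration runs, vs ~0.05 for the burden
  families).  This is a property of the method composition, not a defect of
  either piece.

## Synthetic cohorts

The simulator emulates the structure of a mini-exome association panel:
697 unrelated individuals; three gene groups with 1732 / 1142 / 331 genes
and per-gene SNP counts drawn as `min + NegBinomial` moment-matched to means
(SDs) 3.155 (4.116), 16.336 (20.173) and 1.106 (0.387); rare MAFs from a
Beta(0.5, b) truncated to (0, 0.05) with b solved so the truncated mean is
0.006; common MAFs uniform on [0.05, 0.45].  Each SNP of a mixed gene beyond
the guaranteed rare+common pair is common with probability 0.066, which
reproduces the target pooled mixed-group mean MAF of ≈ 0.035 given the rare
and common component means.  Defaults are full scale; tests and examples
pass smaller designs explicitly.

Population structure is a two-subpopulation Balding–Nichols model: ancestral
frequency p₀ per variant, subpopulation frequencies Beta-distributed with
divergence F (default 0.05), Hardy–Weinberg genotype draws within
subpopulation, no linkage disequilibrium.  Every variant is redrawn until it
is polymorphic in the realized sample and on the intended side of the 5%
sample-MAF split, so the construction-time groups are exactly recoverable by
`partition_genes` (and, as in sequenced panels, every "SNP" is actually
variable in the sample).  A side effect worth knowing: the rejection
truncates the most ancestry-divergent rare draws, so common variants end up
carrying more ancestry signal per SNP than rare ones.

Phenotypes follow `y_i = Σ_j β_j g_ij + γ·ancestry_i + ε_i`,
`ε ~ N(0, noise_sd²)`, with replicates redrawing ε only (fixed genotypes,
the replicate structure of the emulated panel).  Causal architectures place
4 rare-only and 5 mixed causal genes by default, each with 1–11 causal
variants of MAF within [0.0007, 0.165] and a constant positive effect
(default β = 0.5 per allele in noise-SD units — a visible but not
overwhelming per-variant signal at n ≈ 700; power studies should scan β
explicitly).  Effects are all trait-increasing because unsigned collapsing
is the regime these tests are built for; mixed-sign architectures would
change power in ways this framework does not model.

The confounder strength γ is set by `calibrate_confounder`: a bisection on γ
targeting a mean-based inflation factor (default 2.3) for the per-SNP
regression scan of a null trait, with λ averaged over 12 phenotype draws.
Targeting the *consequence* (λ) rather than postulating a structure is
deliberate: only the consequence is characterized in the data being
emulated.  Residual cohort-to-cohort variation in realized gene-level
inflation remains (a few hundred variants is a small sample of divergence
draws); calibration-sensitive studies should average several cohort
realizations, as `scripts/acceptance.py` does.

What the simulator deliberately lacks: linkage disequilibrium and haplotype
structure, signed effect mixtures, gene–environment and epistatic terms,
dichotomous traits, relatedness, and sex chromosomes.  Consequently, passing
calibration here shows the statistical machinery is correct under the
declared model; it does not certify behavior under LD (where the combined
test's independence assumption erodes) or under more realistic confounding.

## Evaluation conventions

Power counts a causal gene as detected when its GC-corrected p beats
`α / N_group`, with N the number of genes tested in the same group (groups
are analyzed separately; a flag switches to an all-genes denominator).
Type-I error is the *uncorrected* per-test rate at α among non-causal genes.
The asymmetry is intentional and mirrors the reporting convention of the
comparison this harness reproduces.  Causal-gene ranks use average-rank tie
handling.  QQ tables pair sorted observed p-values with (k − ½)/N expected
quantiles on the −log10 scale.

## Numerical details

* Monomorphic variants are kept with maf = 0 and contribute to nothing;
  monomorphic regression columns return a flagged degenerate result (p = 1)
  rather than raising.
* Permutation tie comparison uses a 1e-12 absolute slack so bit-level noise
  cannot drop exact ties.
* p-values are clipped away from 0 (never below the smallest positive
  double); permutation p-values are bounded below by 1/(B+1) by
  construction.
* Missing VCF genotypes (./.) are imputed to 0 minor-allele copies with a
  logged count — conservative for burden scores.  Multi-allelic records are
  rejected, not split.
* The LASSO path excludes zero-variance columns; rank-deficient refits drop
  collinear columns greedily and are flagged.
* Seeds: every stochastic component (cohort, phenotypes, permutations,
  calibration) takes an explicit seed; equal seeds give byte-identical
  outputs end to end.
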