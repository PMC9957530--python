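# Methods

This note documents the models, estimators, conventions and numerical
choices behind pcitnet, and what the synthetic-data experiments do and do
not demonstrate about real data.

## Design and data model

The pipeline assumes a two-group bulk RNA-seq design: an integer gene ×
sample count matrix with each sample labeled fertile (`FH`) or subfertile
(`SFH`). The canonical scale is counts per million,
CPM(g, s) = count(g, s) / library(s) × 10⁶, computed on raw library
sizes (no TMM or upper-quartile factors). Genes with CPM below 1 in more
than half the samples are removed before any statistic is computed; "half"
is resolved as *keep iff the gene passes in at least ⌈0.5·N⌉ samples*
(8 of 15), and a CPM exactly equal to the threshold counts as expressed.
Filtering is idempotent and preserves gene order.

## Differential expression

A deliberately transparent negative-binomial Wald procedure stands where a
full DESeq2-style analysis would normally sit; every quantity is a closed
formula:

- **Size factors**: median across genes (positive in all samples) of
  count(g, s)/geomean(g), rescaled to geometric mean 1.
- **Dispersion** α per gene by method of moments on normalized counts,
  with the variance pooled *within* groups (denominator n − 2 for two
  groups, so a real mean difference does not masquerade as biological
  variance): α = max(10⁻⁸, (v − m)/m²). The floor absorbs under-dispersed
  genes.
- **Wald test**: with group means m₍FH₎, m₍SFH₎ of normalized counts and
  pseudocount pc = 0.5, log₂FC = log₂(m₍SFH₎ + pc) − log₂(m₍FH₎ + pc)
  (computed as a difference of logarithms so that exchanging the group
  labels negates it bit-for-bit), and
  se = (1/ln 2) · √((1/m₍FH₎ + α)/n₍FH₎ + (1/m₍SFH₎ + α)/n₍SFH₎), the
  delta-method variance of a log NB mean. The p value is two-sided
  normal; BH adjustment (statsmodels) and the DEG call
  padj ≤ 0.05 ∧ |log₂FC| ≥ 0.5 follow, both thresholds inclusive.

**Sign convention.** Positive log₂FC means higher expression in SFH; the
convention is a switch (`positive_group`), and the direction labels follow
it.

**Calibration property.** Because α is re-estimated per gene from the
same 15 samples (13 residual degrees of freedom) and referred to a normal
distribution, the null Wald statistic is t(13)-distributed to first
order. Its p < 0.05 exceedance is 2·P(t₁₃ > 1.96) ≈ 0.0715, not 0.05,
and the extreme tails are correspondingly heavier, so occasional false
DEGs survive BH on a few hundred null genes. The unit suite asserts this
t-reference behavior explicitly. Methods that share dispersion
information across genes (shrinkage toward a trend) avoid this at the
cost of the transparency this package aims for; users who need strict
type-I control at n ≈ 15 should treat borderline padj values with care.

## PCIT co-expression networks

Per group, Pearson correlations are computed across that group's samples
on CPM (log₂(CPM+1) available via `correlation_scale`). Zero-variance
genes yield undefined correlations and are excluded from edge inference.
The PCIT pass then examines every gene trio (x, y, z): the three
first-order partial correlations are formed, the tolerance is the mean
ratio of partial to direct correlation,
ε = ⅓(r₍xy·z₎/r₍xy₎ + r₍xz·y₎/r₍xz₎ + r₍yz·x₎/r₍yz₎), and the pair (x, y)
is eliminated if |r₍xy₎| ≤ |ε·r₍xz₎| and |r₍xy₎| ≤ |ε·r₍yz₎| for some z
(boundary equality eliminates). An edge therefore dies when it is weak
*relative to the two edges joining its endpoints to some third gene* — a
pair whose partial correlation is zero but whose direct correlation
rivals its flanks is retained. Conventions for degenerate trios: a ratio
term with direct correlation exactly 0 is skipped (ε averages the rest;
all three zero → no elimination), and a trio containing |r| = 1 is
non-informative.

The optimized implementation vectorizes one conditioning gene at a time
and performs the same IEEE-754 operations in the same order as the naive
triple loop, so the two masks agree exactly; the suite asserts bit-level
equality on random matrices up to 60 genes. Cost is O(p³) with O(p²)
memory; a guard refuses more than 5,000 genes unless forced.

Edges are reported only if PCIT-significant, |r| ≥ 0.95, correlation
p ≤ 0.05 (two-sided t on n − 2 df, unadjusted), and touching at least one
DEG (anchoring). PCIT runs on the full filtered gene set *before* these
filters. Anchoring is monotone: enlarging the DEG set never removes an
edge.

## Hubs, union network, differential connectivity

Degrees come from the filtered per-group networks. A hub has degree
≥ mean + 2·SD of the degrees in its network; the SD convention defaults
to the sample SD (ddof = 1) with the population SD available
(`sd_denominator: "n"`), ties at the threshold are hubs, and an SD of 0
yields no hubs with a warning. Hub sets are classified as FH-exclusive /
SFH-exclusive / shared by set algebra.

The union (reference) network is the DyNet-style merge: nodes and edges
labeled `FH_only` / `SFH_only` / `both`.

Differential connectivity uses the union gene set (absent genes carry
degree 0): K = k / max(k) per group, DK = K₍SFH₎ − K₍FH₎ ∈ [−1, 1], and
z = (DK − mean DK)/SD(DK) with the empirical mean and sample SD;
|z| ≥ 1.96 is significant. Exchanging the groups negates DK and z exactly
and swaps the hub flags.

**Small-network property.** z standardizes DK against the analyzed gene
universe itself. In a full-scale analysis (thousands of network genes,
~1% rewired) the universe is dominated by stable genes and rewired hubs
stand far outside it. In small DEG-anchored networks — a few dozen genes,
most of them the rewired module — the module is its own reference
distribution: even a gene with the maximal DK of 1.0 rarely exceeds
z ≈ 1.8. Simulated recovery experiments at ~300 genes therefore show
reliably *positive* mean z for planted-module genes but not reliable
per-gene significance calls; significance recovery requires a large
stable background, which is a property of the data regime, not of the
implementation.

## Enrichment and qPCR validation

Over-representation uses the upper-tail hypergeometric law: with universe
M, set size K (after trimming to the universe), query n and overlap k,
p = P(X ≥ k), X ~ Hypergeom(M, K, n); Bonferroni (min(1, m·p)) and BH are
reported side by side. No annotation database is bundled — collections
come from user GMT files and the background universe is the caller's
choice (typically all expressed genes).

qPCR fold changes follow ΔΔCt: ΔCt = Ct₍target₎ − Ct₍reference₎ per
sample, centered on the calibrator group's mean ΔCt (default FH), fold
change = 2^(−ΔΔCt). Group differences are tested per-sample with the
Mann–Whitney U test; for combined n ≤ 20 the null distribution of U is
enumerated completely over all C(n₁+n₂, n₁) assignments of the observed
midranks, with two-sided p = min(1, 2·min(P(U ≤ u), P(U ≥ u))); larger
samples use the normal approximation with tie correction. No
amplification-efficiency correction is applied.

## Synthetic data generator

`simulate_counts` draws NB counts through a Gaussian copula: standard
normals z₍gs₎ are mapped through the NB quantile function with mean
μ₍gs₎ and a common dispersion α, which preserves the NB marginal exactly
while carrying any correlation imposed on the normals. Structure:

- **Baseline abundance** per gene is log-normal
  (`mean_log_expression` = 4.0 natural-log units, spread
  `sigma_log_expression` = 1.0), converted to relative abundances.
- **Library sizes** are uniform over `library_size_range`
  (default 0.5–1.5 M) and enter multiplicatively, so CPM normalization is
  genuinely exercised.
- **DEGs** are the first `n_deg` genes, half up in SFH and half down,
  with the effect split symmetrically (±log₂FC/2 per group) so the group
  mean ratio is exactly 2^log₂FC.
- **Modules**: disjoint gene sets with a per-module, per-sample latent
  factor in the groups where the module is active:
  z = λ·factor + √(1−λ²)·noise, giving latent pairwise correlation λ²
  (slightly less on the count scale after quantile mapping). A module
  active in exactly one group is the planted rewiring.
- **Reproducibility**: one seed; baseline, library, factor and noise
  stages draw from fixed sub-streams, so identical configurations give
  byte-identical counts.

Defaults mirror the target design: 12,000 genes, 8 + 7 samples, 92 DEGs,
dispersion 0.05. Tests and examples run at 100–500 genes so that the
O(p³) network stage stays in seconds; the methods are size-agnostic.

**What the simulations do not emulate**: batch effects, covariates
(weaning age/weight), gene-length effects, varying per-gene dispersion,
count outliers, and background co-expression beyond the planted modules.
Recovery results on this generator demonstrate correctness of the chain
under its own assumptions, not performance on real cohorts.

## Numerical and design choices

- Correlation matrices are symmetrized ((r + rᵀ)/2), clipped to [−1, 1],
  unit diagonal; exact symmetry is validated before PCIT.
- Correlation p at |r| = 1 is defined as 0; r = 0 gives exactly 1.
- log₂FC pseudocount 0.5 stabilizes zero group means; a zero mean gives
  an infinite se and p = 1 rather than an error.
- The DK z-score is 0 with a warning when SD(DK) = 0 (identical
  networks), and nothing is significant.
- All result tables are TSV with a provenance header
  (`# stage=... config_hash=...`); the hash covers analysis parameters
  but not the output directory, so re-running a configuration elsewhere
  yields byte-identical tables.
- The pipeline enforces exactly two group labels (`FH`/`SFH`); stage
  failures abort with the stage name and a remediation hint.

## Known limitations

- O(p³) PCIT limits desk use to a few thousand genes; the guard is
  overridable but the cost is real.
- The Wald test's t(13)-flavored null (above) makes single-gene p values
  near the threshold optimistic at this sample size.
- Exclusive-hub and DK significance calls on networks of only tens of
  genes inherit the small-universe standardization caveat.
- The exact Mann–Whitney enumerates C(n₁+n₂, n₁) assignments; at the
  n = 20 cap this is 184,756 subsets, a second or two.
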