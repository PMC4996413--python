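# Methods

## Signal model and normalization

Methylation at a CpG probe is measured by two channel intensities,
methylated (I_Meth) and unmethylated (I_UnMeth). Three derived
quantities are used throughout:

- β = I_Meth/(I_Meth+I_UnMeth) ∈ [0,1] — the fraction methylated;
- M = log₂(I_Meth/I_UnMeth) — the statistic all tests operate on,
  approximately homoscedastic across the β range; β = 2^M/(2^M+1);
- I = ½·log₂(I_Meth·I_UnMeth) — the average intensity, the axis along
  which technical bias is modeled.

Logs are base 2 (the convention for M-values; the choice only scales
the statistic). Channels below 1 are floored to 1 before logs so M and
I stay finite while preserving order.

Technical bias is estimated from the QC design: one technical control
sample is hybridized repeatedly, at least once per chip, so its
replicate spread is purely technical. Correction runs in two steps.

**Within chip.** The intensity axis is partitioned into percentile bins
(default 100). Bin edges are the percentiles of the *pooled* QC
intensities across all chips, so a probe lands in the same bin on every
chip whenever its intensity is stable; bins holding fewer than three QC
measurements on a chip merge with their neighbor so every bin error
rests on at least three points. For each chip, the mean QC residual
(QC M-value minus the cross-chip QC consensus for that probe) within a
bin is that chip's error at that intensity level, and is subtracted
from every measurement on the chip falling in the bin. Consequences
worth knowing: a constant per-chip offset is absorbed exactly; with
chip-consistent bin assignment the step is idempotent (a second
application is a no-op up to floating point); and the corrected chips
agree with the cross-chip consensus, not with an external truth — a
bias component shared identically by *all* chips is invisible to any
replicate-based method.

**Across probes.** The per-probe sample standard deviation of the
(already within-chip-corrected) QC M-values, σ_QC, is subtracted from
every study sample's M for that probe. The step is a constant shift per
probe: it can never change a paired difference or any between-sample
contrast, so no downstream statistic depends on it. σ_QC is retained
because it is also the denominator of the scaled CV. With a single QC
replicate overall, σ_QC degenerates to 0 with a warning.

## Pre-selection statistics

For each experiment (controls vs one disease, pools restricted to that
cohort):

- **Scaled CV** = (sd/|mean| over the study pool) / (sd/|mean| over the
  QC replicates), per probe. Because M-values cross zero, the raw CV is
  unstable near mean 0: when either |mean| < 1e−8 the ratio falls back
  to the plain sd ratio, and σ_QC = 0 maps to +∞ (trivially passing the
  ScaledCV > 1 criterion — the intent of the criterion is "real
  variability exceeds technical").
- **Paired t** on per-pair (case − control) differences, df = n−1,
  two-sided p from the t distribution. Zero-variance nonzero
  differences receive the smallest positive double with a warning.
- **Sign-flip bootstrap correction.** Under the matched-design null the
  pair differences are symmetric about zero, so flipping their signs
  regenerates the null. B replicates (default 1000) each draw one
  Rademacher vector shared by all probes, preserving the inter-probe
  correlation structure; per probe, p_boot = (1 + #{b : |t*_b| ≥
  |t|})/(B+1), bounded below by 1/(B+1). Because sign flips leave Σd²
  invariant, t* follows from the flipped mean alone and the whole null
  ensemble reduces to one matrix product — 10,000 probes × B = 1000 runs
  in about a second.

Selection keeps the ⌈0.01·P⌉ probes with smallest p_boot (ties broken
by p_raw, then probe id — deterministic and input-order-free),
intersected with ScaledCV > 1; per-experiment sets are unioned with
provenance retained, because the semantic stage later intersects its
probe sets per experiment.

## Evolutionary selection

A chromosome is a boolean mask over the candidate probes with popcount
in [1, D_max]. Fitness is the pooled accuracy of the distance-weighted
12-nn classifier under stratified 3-fold cross-validation restricted to
the masked features; the folds are drawn once per run so all
chromosomes are scored on identical splits (comparable fitness), and
evaluations are cached by mask. Selection is fitness-proportional
roulette (uniform fallback when all fitnesses are zero), crossover is
uniform over consecutive parent pairs with P_c = 0.5, mutation flips
bits with P_m = 1/N, and repair randomly clears surplus bits (or sets
one when empty). One elite chromosome survives unchanged per
generation, making the best fitness non-decreasing and the final
generation's best the global best. Ties are broken toward smaller
cardinality, then lexicographically — parsimony and determinism.

A property of accuracy-driven wrapper selection worth stating plainly:
when a few strong features already saturate CV accuracy, the remaining
informative features are fitness-neutral and drift; and with many
candidates and few samples, chance features can overfit the fixed
folds. The packaged GA-recovery experiment therefore plants one strong
marker per class (10 classes × 15 samples, 500 candidates, 4σ shift),
making every informative feature individually necessary — a scenario
where a correct implementation reliably recovers ≥ 8–10 of 10 markers
within 30 generations at population 100.

## Semantic centrality

Annotations are closed under ancestors (true-path rule); a term's
information content is IC(t) = −ln(n_t/n_root) over the propagated
corpus, and the distance between two terms is d(t₁,t₂) = 1 −
IC(MICA)/IC_max, where MICA is the common ancestor with maximal IC and
IC_max normalizes to the corpus. The relaxation threshold (default
0.15) therefore lives on a fixed [0,1] scale rather than a
corpus-dependent raw-IC scale. A gene's direct terms are pruned
iteratively — while any retained pair lies closer than the relaxation,
the lower-IC (more generic) member of the closest pair is dropped
(closest pair by (distance, term id); equal-IC ties drop the larger
id) — and the retained-term count is the gene's centrality. Pruning
uses direct annotations (a gene's own description), IC uses propagated
ones (corpus frequencies). The bubble expansion collects, per gene, the
genes annotated to its terms and to their parents/children (roots
excluded) — the gene's functional clique. One ontology aspect is
handled per run; multi-aspect use unions gene lists.

## Classifiers and evaluation

- **k-nn (k = 1, 6, 12):** Euclidean distances, vote weight 1/(d+ε)
  with ε = 1e−9 (stable at d = 0: an exact-match neighbor dominates);
  vote ties resolved by the nearest neighbor's class.
- **Tree:** CART with Gini impurity, midpoint thresholds, grown while
  impurity decreases; no pruning (only the split criterion is part of
  the design).
- **ANN:** one hidden layer of ⌊(F+C)/2⌋+1 sigmoid units (floored —
  the formula can be fractional), sigmoid outputs on one-hot targets,
  classic per-sample backprop with momentum (learning rate 0.3,
  momentum 0.2, exactly 1000 epochs), small uniform seeded weight
  initialization, argmax decision. The training loop is numba-jitted;
  results are bit-reproducible for a fixed seed.

Inputs are standardized per feature with training-set statistics only
(distance and sigmoid-gradient scales; no leakage). Two protocols:
leave-one-out resampling (standardizer and model refit per fold) and a
single fit applied to an independent split whose sample ids are
asserted disjoint from training. Reports carry the confusion matrix,
total accuracy = 100·trace/total and per-class sensitivity =
100·diag/rowsum.

## Enrichment

Upper-tail hypergeometric p-value P(X ≥ a) for a gene list of size n
from a universe of N genes against a term of K genes with a hits,
reported as "a/K". The universe is the chip's annotated gene set, not
the genome, since selection operated on chip probes. Terms with K < 2
or a = 0 are skipped. Raw p-values are the default; Benjamini–Hochberg
and an empirical resampling null (random same-size lists) are options.
Region distributions count probes over the seven fixed region groups
with a promoter rollup (TSS200 + TSS1500 + 5′UTR + 1stExon).

## Synthetic cohorts: what they emulate and what they do not

The generator draws baseline β per probe from the bimodal mixture
typical of array methylation (Beta(2,10)/Beta(10,2) at equal weight
plus 10% Beta(2,2), clipped to [0.005, 0.995] so channels stay above
the floor), plants disjoint per-disease probe sets shifted by
`effect_delta` on the M (logit-β) scale in cases only, inverts the β
definition into channels via a log-normal total intensity (log₂T ~
N(11, 0.7)), and applies multiplicative log-normal channel noise
(default sd 0.1, i.e. ≈ 0.2 M-units of per-measurement noise). All QC
replicates share the single baseline β profile — they are one technical
sample. Chip bias is injected exactly on the M scale as slope·I +
offset with I preserved (channels recomposed), so normalization
recovery is measurable without confounding; each chip draws its
coefficients uniformly from ±bias_slope/±bias_offset — chips must
disagree for a replicate-based correction to have anything to correct.
Matched pairs are split into train/test at the pair level (both members
on one side), keeping class balance exact.

Not emulated: realistic genome coordinates, non-CpG/SNP probes,
cell-type composition, batch structure beyond chip, dye bias, or
probe-type (Infinium I/II) chemistry differences. Passing tests
demonstrate that the algorithms recover what this generative model
plants; they do not certify performance on real cohorts, where bias is
not exactly linear in I and effects are not uniform shifts.

## Problem sizes and numerical choices

Simulation-based checks run at 10,000 probes × 30 pairs with B = 1000
bootstrap replicates (null calibration, planted recovery), 4,000
probes for normalization recovery, and 2,000 probes × 40 pairs per
disease for the end-to-end run — sizes chosen so each check completes
in seconds while keeping per-bin QC counts (≈ 40) and rank budgets
(top-1% = 100) in the regime the method assumes. Determinism
everywhere: every random draw descends from an explicit seed through
named SeedSequence streams; reports are JSON with sorted keys; TSVs are
written with shortest-round-trip floats and read back with round-trip
parsing, so identical configs produce byte-identical artifacts.

Known limitations: the across-probe step follows the literal
subtract-σ_QC reading and is deliberately contrast-neutral; the
bubble-expansion and pruning interpretation of semantic centrality is
one concrete reading of a web tool whose internals are not published in
detail; with heavy ties in vote weights the k-nn tie-break (nearest
neighbor's class) is a convention, not information.
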