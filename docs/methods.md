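# Methods

`regenddr` quantifies the desk-scale readouts of a DNA-damage-response
(DDR) study in regenerating axolotl limbs: which DDR genes change over the
regeneration timecourse, which genes co-vary with an anchor gene, how much
γ-H2AX accumulates per nucleus, how phospho-states of H2AX partition, and
whether a regenerate recovered its complete skeletal pattern. It consumes
derived measurement tables (expression matrices, per-cell focus counts,
densitometry intensities, element counts), never raw reads, gels or
images.

## Timecourse regulation calls

Expression is summarized as one value per gene per timepoint on a
days-post-amputation (dpa) grid containing 0 dpa (the intact limb). For
RNA-seq (TPM) data a gene is **up-regulated** if at any regeneration
timepoint `value(t) >= fold_threshold * value(0)` and **down-regulated** if
`value(t) <= value(0) / fold_threshold`, with `fold_threshold = 2` by
default. "Two times less" is read on the ratio scale (`<= intact/2`), the
symmetric mirror of the up rule. Both thresholds are inclusive ("at least
two times"). A gene with both kinds of evidence — necessarily at different
timepoints — is **mixed**; otherwise **none**. For microarray data the
evidence is dispersion-based and strict: `value(t) > mean + k*sd` /
`value(t) < mean - k*sd` with `k = 1`. The SD basis is not standardised in
this kind of analysis: when intact replicate columns are supplied the
per-gene SD across those replicates is used; otherwise the SD across the
whole series is the (logged) fallback. Genes with zero intact expression
have no defined fold ratio and are excluded from classification and from
composite scoring by default (a `call_up_if_any_positive` policy is
available).

The composite score of a curated gene set (e.g. positive regulators of DNA
repair) is the per-timepoint mean of each member's expression relative to
its own intact value; it equals 1 at 0 dpa identically, which the tests
assert exactly.

Volcano-style selection from a differential-expression table uses strict
cutoffs (`q < 0.05`, fold change beyond 2 or 1/2): boundary genes select
into neither set, so the up and down sets are always disjoint.

qPCR quantities come from a linear standard curve `Ct = slope*log10(q) +
intercept` (slope negative); the -RT control quantity is subtracted and
floored at zero before normalization by the reference gene (ef1a-style).

## Anchor co-expression screen

Each gene's profile is compared to the anchor gene's profile over the
shared timepoints: Pearson r (closed-form covariance ratio), R² = r², and
the OLS slope of gene-on-anchor. "Slope of the correlation curve" is taken
as that OLS coefficient — its sign equals the sign of r, which is all the
partition uses, and is invariant to the regression direction. Genes with
R² strictly above 0.8 split by slope sign into positive/negative sets;
everything else, including constant profiles (undefined r), is
unassociated. Correlation runs on values as given; a log2(x+1) switch
exists but defaults off, since no transform is standard here. Genes
sharing fewer than `min_timepoints = 3` points with the anchor are
unassociated with a warning.

## γ-H2AX focus densities

Per-nucleus focus density is `scale * foci_count / nucleus_area`. The area
unit of the source data is not asserted; `scale` (default 1) lets inputs in
any unit reproduce the conventional 1e6-magnitude density numbers. Bins:
Zero requires an exact zero focus count; Low = (0, 10e6), Med =
[10e6, 20e6), High = [20e6, ∞). The published bin definitions are open on
both sides and leave boundary values unassigned; the half-open convention
here makes the partition total, at the cost of deciding that a density
exactly at a boundary falls in the upper bin. Percent-in-bin tables are
computed within strata (genotype, EdU status, sample) and always sum to
100 per stratum. `percent_positive` is shared percent arithmetic
(EdU+/pH3+/TUNEL+ cells, fully patterned limbs); values are kept at full
precision and rounded to integer percent only when reported.

## Phospho-state arithmetic

Band intensities are normalized per lane by total H2AX (or by a loading
control, per blot design), and the relative pY142 level is the dual
pS139/Y142 signal minus the γ-H2AX signal, computed per lane before any
group averaging. Negative derived values are reported as-is with a
`below_zero` flag — flooring at zero would bias group means upward. Group
summaries report mean and SEM (sd/√n); single-lane groups have undefined
SEM (NaN).

## Skeletal pattern, comet stages, exact test

A limb is fully patterned iff digits = 4, phalanges/metacarpals = 9 and
carpals = 8, by exact equality: the criterion lists the complete element
count of an axolotl forelimb autopod, and a supernumerary regenerate is
not "fully patterned". Comet-stage tables (stages 0–4, ~100 cells per
sample) become percent distributions summing to 100.

`fisher_exact` is an exact conditional test for r×c count tables. All
tables with the observed margins are enumerated by a recursive
margin-constrained fill; each table's multivariate hypergeometric
probability is accumulated in log-factorials, and the two-sided p-value is
the total probability of tables no more probable than the observed one
(probability-ordering rule, the conventional r×c generalization). Ties are
recognized within a 1e-12 relative tolerance, which absorbs last-ulp
differences between equal-probability tables. Enumeration is guarded at a
table total of 500. Tests verify permutation/transposition invariance,
that the enumerated distribution sums to 1, exhaustive agreement with an
exact integer-arithmetic oracle on every 2×2 and 2×3 table with total ≤ 20,
agreement with scipy's 2×2 implementation, and agreement with a 1e5-sample
permutation oracle on larger tables.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with ground-truth labels, so every stage is testable without external
data. Study conditions baked into the defaults: the 8-point dpa grid
(0, 3, 5, 7, 10, 14, 21, 28), equal regulation-class proportions over
2,000 genes, 18 limbs per genotype with 3 complete wild-type and 0
complete mutant limbs, ~100 scored comet cells, and per-(genotype, EdU)
density parameters spanning the 0–65e6 density range with EdU+ and mutant
groups planted at higher means.

- **Noise model**: multiplicative log-normal with configurable CV
  (`noise_cv`, default 0.1) — expression stays strictly positive. The
  intact column is left noise-free so planted fold excursions are exact at
  the effect timepoints.
- **Planted effects**: regulated genes get expected excursions of
  `fold_effect` (default 4, a margin above the fold-2 calling threshold so
  noisy recovery measures noise rather than boundary coincidence); mixed
  genes get their up- and down-excursions at distinct random timepoints;
  "none" genes stay within expected ratios [0.8, 1.25], strictly inside the
  fold-2 band, making zero-noise recovery exact by construction.
- **Class counts** follow the largest remainder rule (ties broken by the
  fixed class order up, down, mixed, none), so planted proportions are
  preserved deterministically.
- **Anchor sets**: planted positives/negatives are affine transforms of
  the anchor profile with positive/negative gain (offsets keep values
  positive); unassociated genes are drawn independently. With only 8
  timepoints an independent gene occasionally exceeds R² = 0.8 by chance
  (~0.3% two-sided); this false-positive rate is a property of the screen,
  measured in the tests against a permutation estimate, not a generator
  defect — "100% recovery at zero noise" applies to the planted
  positive/negative sets.
- **Cells**: planted densities are gamma-distributed per (genotype, EdU)
  group with a configurable fraction of exact-zero cells; areas are
  log-normal (CV 0.2) around 3e-6 area units; focus counts are Poisson
  with mean density×area, the simplest count model consistent with
  per-nucleus counting. At `noise_cv = 0` counts are the rounded
  expectation and the truth bin is recomputed from the realized
  count/area, so downstream binning recovers the truth exactly.
- **Streams**: each generator op seeds its own stream (`seed` + fixed op
  offset), so adding one generator to a run never perturbs another's
  output; identical configs are byte-deterministic end to end.

What the generator does **not** emulate: library-size and length biases of
real RNA-seq, gene–gene correlation beyond the planted anchor structure,
segmentation errors and focus-detection thresholds in imaging, or
between-animal variance components. Passing recovery tests therefore show
the rules are implemented correctly and are robust to multiplicative
noise of the stated magnitude — not that real data meet those noise
assumptions.

## Problem sizes and numerics

Default verification sizes: 2,000 genes × 8 timepoints for regulation
recovery (10 seeds at CV 0.1), 500-gene anchor sets, 2,000 cells for
density checks, exhaustive exact-test audit up to table total 20 and 20
Monte-Carlo-checked larger tables at 1e5 resamples. Percent arithmetic is
exact rational-in-floats; the only tolerances in the core are the exact
test's 1e-12 tie tolerance and the 1e-12/1e-9 assertions in the test
suite. Result files print floats at six significant digits; expression
matrices round-trip at full (17 significant digit) precision.

## Known limitations

- The heterozygote column of a genotype×pattern 2×3 contingency design is
  often unreported in practice; the package tests the exact test on
  synthetic and enumerable tables rather than asserting any particular
  published p-value bound.
- The microarray SD basis and the expression scale (raw vs log) for
  correlation are configuration choices, documented but not asserted as
  any study's intent.
- Boundary densities falling exactly on a bin edge are resolved by the
  half-open convention; analyses sensitive to that convention should
  adjust `FociBinConfig`.
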