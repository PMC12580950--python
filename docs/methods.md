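# Methods

## Scope and model

`cutspec` analyses regional gene expression in a multi-region bulk RNA-seq
design: several anatomically defined muscle regions (by default the six
venison cuts longissimus dorsi LD, intercostal muscles IM, trapezius T,
biceps brachii BB, gluteus maximus GM and quadriceps femoris QF), each with
biological replicates from distinct animals. The pipeline starts from a
gene-level read-count matrix; upstream steps (read trimming, alignment,
counting) are out of scope.

Expression is quantified as FPKM,

    FPKM_gj = c_gj * 1e9 / (T_j * L_g),

with `c_gj` the count of gene `g` in sample `j`, `L_g` the gene length in bp
and `T_j` the sample's total count **over the genes in the matrix** — i.e.
reads assigned to annotated genes, not total sequenced reads. This makes
FPKM invariant to uniform scaling of a sample's counts and inversely
proportional to length, two identities the tests assert.

Region-level expression is the arithmetic mean of FPKM over a region's
replicates. Two gene universes are derived from it:

* **expressed** in a region: region-mean FPKM ≥ 1 (inclusive);
* **retained** (the analysis universe): region-mean FPKM **strictly** > 1 in
  at least one region (default rule `mean_per_region_any`). The harsher
  literal alternative — every replicate of some region above the threshold
  (`all_replicates_any_region`) — is available because the phrase
  "FPKM greater than 1 in the 12 biological replicates" is ambiguous between
  the replicate-wise and the region-mean reading; the mean rule is the
  default because requiring all 12 replicates to pass is far more
  restrictive than typical retained-set sizes suggest. Both rules are
  implemented and tested; neither is asserted to be the original intent.

## Region-specific genes

A retained gene is region-specific (RSG) in region `r` when, with `e` its
mean FPKM in `r` and `O` the vector of its means in the other regions:

1. `e ≥ fold × aggregate(O)` with `fold = 3`; the aggregate is the **max**
   over other regions by default (the strictest standard tissue-specificity
   convention — "others" is read as every other region individually), with
   `mean` available as an option;
2. `e > 0.5 × mean(O)`; under either aggregate this is implied by
   criterion 1, but it is kept as an explicit, separately reported criterion
   because it is part of the stated definition and cheap to evaluate. (It
   would bind only under a different reading, e.g. a share-of-total rule,
   which this package does not assume.)
3. `e` at or above the 0.75 quantile of retained-gene expression **within
   region r**. The quantile uses numpy's linear-interpolation convention
   with an inclusive (≥) boundary, and the rank universe is the retained
   set, since detection operates on it.

Comparison conventions at exact equality: criteria 1 and 3 inclusive,
criterion 2 strict, following "more than three times" / "within the top
25%" vs "greater than 50%" wording. With the max aggregate and `fold > 1`
a gene can be specific to at most one region (property-tested). All three
criteria are scale-free: multiplying every region mean by a positive
constant leaves calls unchanged.

Detected genes are clustered on row-z-scored region means (population sd;
all-constant rows map to zero vectors) with agglomerative complete-linkage
Euclidean clustering; scipy's implementation is deterministic, so leaf order
and merge heights are reproducible.

## Differential expression

Every unordered region pair is compared (15 comparisons for six regions;
the conventional published ordering is kept for the default labels).
Normalisation uses median-of-ratios size factors computed on the pair's
samples: reference = per-gene geometric mean over samples (genes containing
any zero excluded), factor = median ratio to the reference. A pre-installed
reference implementation of the same estimator is used as an independent
oracle in the test suite.

The test itself is a deliberately transparent negative-binomial Wald test —
not a reimplementation of any external package. Per gene, with normalised
group means `µ_A, µ_B` over `n_A, n_B` samples:

* dispersion `α = max(0, (v − µ̄) / µ̄²)`, where `v` is the pooled
  within-group variance and `µ̄ = (µ_A + µ_B)/2`; the truncation at zero is
  the Poisson floor;
* `z = (ln µ_A − ln µ_B) / SE`, `SE² = (1/µ_A + α)/n_A + (1/µ_B + α)/n_B`
  (delta-method variance of a log NB mean);
* two-sided p-values from the standard normal; Benjamini–Hochberg correction
  **within each comparison** (15 independent corrections);
* `log2FC = log2((µ_A + 0.5)/(µ_B + 0.5))`; the pseudocount bounds the fold
  change when a group is all zero and is used nowhere else.

Degenerate genes: both group means zero → p = 1, log2FC = 0; exactly one
zero mean → that mean enters the Wald statistic at the pseudocount so the
statistic stays finite. A gene is called up (down) when q < 0.05 and
log2FC > 1 (< −1). Genes entering DE are the retained universe.

Under the study conditions (n = 12 per group, α = 0.1, genes passing
retention) the test's empirical type-I error at p < 0.05 is ≈ 0.06 —
slightly anticonservative because the method-of-moments dispersion is noisy
at n = 12 and its truncation at zero biases it downward — and BH discoveries
on null data average well under 1% of genes. Both behaviours are asserted by
the acceptance suite, which recomputes them from scratch.

## Gene panels

Panels are named gene-symbol sets; defaults cover fatty-acid biosynthesis,
degradation and elongation, and muscle-fiber structure (TPM1, MYH1, MYL6B,
TNNI1). The original comparison of such panels across cuts was visual; this
module adds an explicit surrogate statistic so "no significant difference"
becomes testable: per gene, the CV of region means (sd/mean, sample sd) and
a Kruskal–Wallis test on replicate-level FPKM across regions (midrank ties,
chi-square approximation; all-identical observations give p = 1), BH
correction within the panel, and a stable/variable call at q < 0.05. This
statistic is a design choice of this package, not a method taken from any
particular study. Symbol-to-id mapping is the caller's responsibility;
panel genes absent from the matrix are reported with `missing=True`, never
dropped silently.

## Synthetic data

The simulator generates the study design directly: counts
`c_gj ~ NB(µ_gj, α)` with `µ_gj = s_j · b_g · m_{g,r(j)}` and variance
`µ + αµ²` (α = 0 is the Poisson limit, drawn as Poisson).

Defaults and rationale:

| parameter | default | why |
|---|---|---|
| regions × animals | 6 × 12 | the study design (72 samples, 6M/6F per region) |
| genes | 5000 | enough for stable quantiles and BH behaviour at desk scale |
| baseline `b_g` | log-normal, median 50 counts, log-sd 1.5 | a typical bulk RNA-seq dynamic range of ~4 orders of magnitude; median chosen so that the retention filter is active but not dominant |
| dispersion α | 0.1 | moderate biological replication noise, standard for bulk tissue |
| library factors `s_j` | Uniform(0.7, 1.3) | ±30% depth variation, exercised by both FPKM and size factors |
| gene lengths | log-normal, median 2 kb, log-sd 0.6 | typical transcript-length spread; independent of expression |
| planted RSGs | 20 per region, fold 8, disjoint | strong but not trivial regional effects with exact ground truth |

Planted genes draw their baseline from the upper quartile of the baseline
distribution (inverse-CDF draw with uniform quantile in [0.75, 1)), so the
top-25% expression-rank criterion is attainable by construction — without
this, a low-expressed planted gene could carry a perfect 8-fold effect yet
be undetectable by design. One `numpy` generator seeded from the config
drives all draws in a fixed order (baselines, planted-gene choice, lengths,
library sizes, counts), so identical configs give byte-identical outputs.

What the simulator does **not** emulate: GC/length bias coupling, batch
effects, sex effects (sex is recorded 6M/6F but has no simulated effect, as
none is modelled in the study design), correlated genes, and multi-region
effects. Passing recovery tests therefore demonstrates that the detector
recovers clean multiplicative regional effects under NB noise — not that it
is robust to confounding in real tissue data.

## Truth evaluation

Sensitivity = planted (gene, region) pairs called exactly / planted pairs;
false-positive rate = null genes called in any region / null genes. Under
the default conditions the full pipeline recovers planted effects with
sensitivity ≈ 1 and FPR ≈ 0 (asserted as ≥ 0.9 / ≤ 0.01 averaged over 10
seeds).

## Numerical and degenerate-input conventions

* Gene and sample order is preserved as read; all outputs report in input
  gene order — determinism over convenience.
* Quantiles: numpy `linear` interpolation everywhere.
* Z-scoring for clustering uses population sd; constant rows → zero rows.
* A sample with zero total counts, a gene missing a length, a region with
  fewer than two samples in DE, a single-region input to detection, and an
  empty retained list are all hard errors naming the offending record.
* Readers validate on load (non-negative integers, unique ids, positive
  lengths) and round-trip byte-identically on their own output.

## Problem sizes used in validation

The acceptance suite and script use the defaults above (5000 genes × 72
samples, 10 seeds for recovery), 100 two-region all-null simulations of
2000 genes for calibration, and a 220-gene two-group experiment for fold
change recovery; these sizes give stable Monte-Carlo estimates while keeping
a full validation run in seconds.

## Known limitations

* The NB-Wald stand-in is slightly anticonservative at n = 12 (see above);
  it is a transparent pipeline component, not a substitute intended to
  reproduce any external tool's numbers.
* FPKM's within-sample normalisation makes cross-sample comparisons depend
  on the composition of the matrix; the DE stage therefore works on
  size-factor-normalised counts, not FPKM.
* The retention-rule ambiguity above can change the analysis universe
  substantially; both rules are exposed so users can check sensitivity of
  their conclusions.
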