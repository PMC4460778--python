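# Methods

This note documents the statistical model behind `transcoex`, the
parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical conventions used throughout.

## The analysis in one paragraph

Expression matrices from several cohorts are merged into one gene ×
sample matrix (quantile normalization per dataset, probe collapsing by
averaging, gene-space intersection, parametric empirical-Bayes batch
adjustment).  A correlation biclustering search finds gene sets whose
average pairwise Pearson correlation (avg PCC) over some sample subset
reaches 0.7.  A bicluster is kept only when it contains *all* samples of
at least one disease class; its disease combination is the set of
completely covered classes, and samples of partially covered classes
(controls included) are trimmed.  Each surviving gene set is scored by
the difference in avg PCC between the union of its diseases' samples
and all control samples, and tested against an empirical null of random
same-size gene groups; Benjamini–Hochberg correction is applied jointly
across all tested sets and survivors at q ≤ 0.005 are labelled gain
(Δ > 0) or loss (Δ < 0) of coexpression.  Descriptive summaries
(shared-vs-specific partition, pairwise disease counts, top-gene
frequencies, disease-gene overlap, term enrichment) operate on the
survivors.

## Average pairwise Pearson correlation

For a gene set G over samples S, avg PCC is the mean of Pearson
correlations over all unordered gene pairs, each computed across S.  A
pair involving a zero-variance gene contributes 0 (not NaN), so
degenerate rows can never inflate an average.  Three samples are the
minimum for a meaningful PCC, two genes for a meaningful average; both
bounds are enforced everywhere.

## Bicluster search

* **Seeding.**  In every sample, genes are ordered by expression (value
  ties broken by gene id, making the procedure deterministic) and cut
  into consecutive windows of `seed_window = 5` genes.  A window becomes
  a seed together with every sample that *co-clusters* its genes —
  i.e. all window genes fall within `seed_span × |window|` consecutive
  rank positions (measured in whole windows; default `seed_span = 3`).
  Seeds need at least 3 supporting samples.  `seed_span = None` demands
  the identical gene set as a window, a much stricter rule that only
  rank-stable data can satisfy: on continuous data with per-sample
  noise, the probability that the exact same 5-gene window recurs in
  three samples is negligible (rank jitter far exceeds order-statistic
  spacing), which is why the relaxed span rule is the default.
* **Expansion.**  From each seed, genes and samples are expanded
  separately and greedily.  A candidate *gene* is added only when its
  mean correlation to the current gene set itself reaches the 0.7
  threshold — every member of a coexpressed set must be coexpressed
  with the others.  (By the mediant inequality the set average then
  also stays above threshold.)  A weaker rule — "add while the
  resulting average stays ≥ 0.7" — would let roughly two uncorrelated
  genes ride into any strong bicluster on the strength of the existing
  pairs, capping attainable gene purity at ~10/12.  A candidate
  *sample* is added while the resulting avg PCC stays at or above the
  threshold; samples are deliberately uncapped, because the analysis
  wants gene sets covering as many samples (and hence complete disease
  classes) as possible.  Genes are capped at 50.
* **Optimization.**  Within the search space spanned by the two
  expansions, single elements are removed — always the one whose
  removal raises avg PCC most, genes preferentially and samples only
  when no gene removal helps, to maximize retained samples — stopping
  at the *first* state meeting the threshold.  Expansion and
  optimization are iterated from each seed to a fixpoint (at most 5
  rounds): a seed polluted by interloper genes is first trimmed to its
  correlated core and then regrown over all consistent samples.
* **Output contract.**  Every emitted bicluster satisfies
  avg PCC ≥ 0.7, 2 ≤ |genes| ≤ 50, |samples| ≥ 3; exact duplicates and
  biclusters contained in another are dropped; all tie-breaks are
  lexicographic, so the search is deterministic and invariant to input
  sample order.

A consequence of the uncapped, threshold-floor sample expansion is that
strong biclusters absorb a tolerance of weakly fitting extra samples
until the average sits just above 0.7.  This is intentional (it is what
lets a bicluster cover every member of a disease class); the refinement
stage's trimming rule removes those extras again because they never
complete a class.

## Refinement and the permutation test

The disease combination of a kept bicluster is the set of disease
classes whose samples are all contained in it.  Sets coexpressed only
among controls receive no combination and are excluded; loss of
coexpression surfaces instead as a disease-complete set with negative Δ.

The null distribution for a set of size k with combination C is built
from `n_draws` gene groups of size k drawn uniformly without
replacement, each scored by exactly the same Δ over exactly the same
disease-sample union — the null is conditioned on both the set size and
the combination.  Nulls are cached per (k, C) with a seed derived from
the master seed, so results do not depend on the order in which
biclusters are processed.  The p-value is the add-one two-sided
estimator `p = (1 + #{|d| ≥ |Δ|}) / (n_draws + 1)`; two-sided because
both gain and loss are reported.  BH correction is applied jointly
across all tested sets and the default cutoff is q ≤ 0.005.
The default `n_draws` is 100,000; the recovery experiments in the test
suite and acceptance script use 10,000 (p-resolution 10⁻⁴, far below
what the BH cutoff requires for the ≤ 25 sets tested per run).

## Integration

* Quantile normalization forces every column onto the mean
  order-statistic profile; ties receive the mean of the reference values
  at their tied ranks, and the operation is idempotent.
* Probe collapsing averages all probe rows mapping to the same gene id;
  unmapped probes are dropped.  Un-logging uses base 2 by default (the
  data it applies to are log2 scale); the base is a parameter.
* Batch adjustment is the parametric empirical-Bayes location/scale
  model: per-gene standardization against the batch-size-weighted grand
  mean and pooled variance, batch-wise means (normal prior) and
  variances (inverse-gamma prior) shrunk by iterated conditional
  posterior means, effects removed, data back-transformed.  Class labels
  are withheld from the batch model so the adjustment cannot absorb
  biological signal.  The iteration, including its convergence test, is
  written to agree with the standard reference implementation to float
  precision (verified against a frozen Bioconductor `sva::ComBat` output
  at < 10⁻⁶, actually ~10⁻¹⁴).  Zero-variance genes cannot be
  standardized and pass through unchanged with a warning.
  Note that empirical-Bayes shrinkage never removes a location shift
  *exactly*: the residual is of order (1 − κ)·shift with
  κ = nτ²/(nτ² + δ²), which vanishes only as shifts grow large relative
  to noise.  Tests assert this EB-consistent behaviour, not exact
  removal.

## The synthetic-data generator

Module genes follow a single-factor model on their member-class
samples, `x_gs = f_s + ε_gs` with `f ~ N(0,1)` per sample and
`ε ~ N(0, σ²)` per gene and sample, so the expected pairwise PCC is the
analytic `1/(1+σ²)`; σ is derived from the requested `within_pcc`.
Outside its member classes a module gene keeps its own dynamic range
(`outside_sd = 1.0`, the factor's scale) but loses all coordination:
what distinguishes member samples is correlation, not amplitude.  (With
quiet outside noise instead, the threshold-floor sample expansion would
absorb hundreds of foreign samples and whole foreign classes would
complete by accident.)  Background genes are independent noise with
`noise_sd = 0.25` — stably expressed genes at a quarter of the
disease-modulated signal's scale; this 1:4 ratio is what lets the
rank-window seeding see a module in the samples where its factor exits
the background bulk.  Batch effects are gene-wise: an additive shift
`N(0, batch_additive_sd)` and a multiplicative scale
`lognormal(0, batch_multiplicative_sd)` per (gene, batch); the study
layout defaults are 0.5 and 0.2.  All randomness flows from one integer
seed through a single generator; identical configs give bit-identical
matrices.

The shipped study layout mirrors a three-cohort design: one cohort with
AD/ALS/HD/MS/PD/SCH plus controls (11/10/10/10/12/10/55 samples), one
with bipolar disorder vs controls (30/31), one with autism vs controls
(29/29) — 237 samples — over 500 background genes.

**What the generator does not emulate, and one consequence.**  Real
intensity data have a wide per-gene dynamic range (each gene lives at
its own baseline), probe-level redundancy, platform-specific
distributions and missing values.  The generator's background is
deliberately *exchangeable* (all background genes share one
distribution), because planting rank-visible modules among hundreds of
genes requires a tight background bulk.  One rank-based operation reacts
badly to that: quantile normalization maps any value that escapes the
bulk onto the same few extreme reference order statistics, erasing the
planted factor's metric signal precisely in the extreme samples that
seed the bicluster search (within-seed correlations collapse to the
noise of within-module rank order).  On real data, where a module's
range is populated by other genes, QN is a mild monotone map and does
no such harm.  The pipeline therefore runs synthetic studies with
`quantile: false` (ComBat-only integration); quantile normalization
remains implemented, tested, and default-on for real multi-platform
data.  Passing recovery tests consequently demonstrate the bicluster
search, refinement and testing machinery — not QN's behaviour on
synthetic extremes.

## Desk-scale problem sizes

The test suite and acceptance script run everything at the study layout
(≈ 500 genes × 237 samples): 20 seeded full-pipeline recovery runs
(12-gene module, within-PCC 0.9, two disease classes), a noiseless
10-gene module over 30 member samples for the Jaccard ≥ 0.9 recovery
check, 2,000-replicate calibration of the empirical p-value, and one
end-to-end run at the full 100,000-draw null.  The whole acceptance
script completes in ~2–3 minutes on one CPU.

## Known limitations

* The seeding sees only modules whose factor excursions leave the bulk
  of the within-sample value distribution; modules buried mid-range
  among similarly expressed genes are invisible to value-window
  seeding (a property of the seeding family, not of this
  implementation).
* Greedy expansion and first-crossing optimization carry no optimality
  guarantee; on tiny spaces they are checked against exhaustive subset
  search, and greedy sample counts occasionally fall one short of the
  exhaustive optimum.
* The permutation null randomizes gene identity only; it preserves the
  sample covariance structure but not any gene-specific annotation
  structure.
* Disease-gene lists, interaction networks, annotation terms and the
  category map are user inputs; nothing is bundled beyond toy test
  fixtures.
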