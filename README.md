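# transcoex

Cross-disease ("transnosological") differential-coexpression analysis of
integrated brain expression data.

Several neurodegenerative diseases and psychiatric disorders overlap in
their neurological dysfunction, suggesting shared molecular mechanisms
that single-disease differential-expression studies cannot see.
`transcoex` implements an analysis that looks for such mechanisms as
**gene sets that gain or lose coexpression** across combinations of
eight brain-disease classes (AD, ALS, HD, MS, PD, SCH, BD, AUT) relative
to controls, in one expression matrix merged from several cohorts:

1. **Integration** — per-dataset quantile normalization, probe-to-gene
   collapsing by averaging, optional un-logging, gene-space intersection,
   and parametric empirical-Bayes batch adjustment (the ComBat model,
   location and scale, no biological covariates).
2. **Correlation biclustering** — per-sample rank-window seeding, greedy
   gene/sample expansion and in-space optimization under an
   average-pairwise-Pearson-correlation constraint
   (avg PCC ≥ 0.7, 2–50 genes, ≥ 3 samples, samples uncapped).
3. **Refinement** — keep only biclusters containing *all* samples of at
   least one disease class (partially covered classes are trimmed); the
   disease combination of a gene set is the set of its completely covered
   classes.  Each set is scored by
   `Δ = avgPCC(disease samples) − avgPCC(control samples)` and tested
   against an empirical null built from random gene groups of the same
   size (100,000 draws by default), with an add-one two-sided p-value and
   Benjamini–Hochberg correction at q ≤ 0.005.
4. **Sharing & enrichment** — shared-vs-specific partition of the
   surviving sets, pairwise disease sharing counts, top-k gene
   frequencies, overlap with user-supplied disease-gene lists (directly
   or via first-order protein-interaction neighbors), and GMT-based
   hypergeometric term enrichment with category-level fold comparison.

A synthetic-data module generates multi-cohort matrices with planted,
class-restricted coexpression modules and known ground truth, so the
whole pipeline is testable without any downloads.  Its default layout
mirrors a three-cohort design (one cohort with six classes plus
controls, one bipolar cohort, one autism cohort; 237 samples in total).

## Worked example

```python
from transcoex import (
    BiclicParams, PlantedModule, combat_adjust, generate_dataset,
    intersect_and_stack, run_biclic, study_config,
)
from transcoex.refinement import refine_all
from transcoex.sharing import pairwise_counts, partition_shared

mods = (
    PlantedModule("M1", 12, frozenset({"ALS", "MS"}), within_pcc=0.9),
    PlantedModule("M2", 12, frozenset({"AD", "PD"}), within_pcc=1.0),
)
matrix, truth = generate_dataset(study_config(modules=mods, seed=1))

parts = [matrix.subset(samples=matrix.samples_of_batch(b)) for b in matrix.batches()]
merged = combat_adjust(intersect_and_stack(parts))

biclusters = run_biclic(merged, BiclicParams())
refined = refine_all(biclusters, merged, alpha=0.005, n_draws=100_000, seed=1)
shared, specific = partition_shared(refined)
```

This prints (via the obvious `print` statements):

```
524 genes x 237 samples, batches: ['batch1', 'batch2', 'batch3']
197 biclusters with avg PCC >= 0.7
27 significant gene sets (16 shared, 11 single-disease)
  AD+PD    gain pcc_dis=1.000 pcc_ctrl=0.052 q=1.08e-05 genes=M2_g00,M2_g01,M2_g05,M2_g09...
     AD  ALS  MS  PD
AD    5    0   0   5
ALS   0   22  11   0
MS    0   11  11   0
PD    5    0   0   5
```

Both planted modules come back with exactly their planted disease
combinations: the noiseless module as AD+PD sets with disease-side
avg PCC 1.0 and control-side ≈ 0 (a *gain* of coexpression), the noisy
module as the ALS+MS block of the pairwise sharing matrix.  No spurious
disease combination reaches the q ≤ 0.005 cutoff.

## Command line

Every stage is also a subcommand of a single `transcoex` entry point:

```bash
transcoex synth     --config cfg.yaml --out DIR
transcoex integrate --expr A.tsv --expr B.tsv --meta meta.tsv --out merged.tsv
transcoex biclic    --expr merged.tsv --meta merged.tsv.meta.tsv --out biclusters.json
transcoex refine    --biclusters biclusters.json --expr merged.tsv --meta ... --out refined.tsv
transcoex share     --refined refined.tsv --out summary/
transcoex enrich    --refined refined.tsv --gmt terms.gmt --out enrichment.tsv
transcoex pipeline  --config run.yaml     # all of the above, one seed, one manifest
```

## Layout

```
src/transcoex/
  matrix.py       gene x sample matrix container + TSV I/O
  synthetic.py    multi-batch generator with planted modules
  integration.py  quantile normalization, probe collapsing, ComBat
  biclic.py       correlation bicluster search
  refinement.py   class-complete selection, permutation test, BH
  sharing.py      shared/specific partition, counts, disease-gene overlap
  enrichment.py   GMT hypergeometric enrichment, category folds
  pipeline.py     orchestration, YAML config, manifest
  cli.py          click entry points
docs/methods.md   model, assumptions, parameter choices, limitations
```
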