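# succession

Analysis toolkit for longitudinal gut-microbiota succession in an infant
birth cohort. It targets the study design in which 13 mother–infant pairs
are sampled at seven occasions — infant stool at 1 week (I1), 1 month (I2),
3 months (I3), 7 months (I4) and 1 year (I5), plus maternal stool just
before delivery (MA) and one year after (MB) — and each sample yields a
genus-level taxon count table and a function-subrole (TIGRFAM-style) count
table of raw sequence counts.

The package answers, with tested and reusable code, the questions such a
cohort poses:

* **Alpha-diversity dynamics** — rarefaction to a common depth; observed
  richness *N*, the Chao1 estimator (classic `N + F1²/2F2` and
  bias-corrected `N + F1(F1−1)/2(F2+1)`), and the Shannon index
  `H = −Σ pᵢ ln pᵢ`; Poisson GLM (log link) trends for richness and beta
  regression (logit mean link) for Shannon mapped into (0, 1); bootstrap
  clustering of per-infant temporal profiles.
* **Compositional directionality** — Bray–Curtis distances on relative
  abundances; global and pairwise ANOSIM (`R = (r̄_between − r̄_within)/(M/2)`
  on midranked distances, permutation p) with multiple-testing adjustment;
  PERMANOVA; PCoA on Gower distances; canonical correspondence analysis
  constrained by timepoint; convex-hull dissimilarity
  `1 − area(∩)/area(∪)` between timepoint hulls on the first two axes.
* **Timecores** — per-timepoint sets of features detected in every
  individual, their Venn partition, arrival/persistence accounting, the
  global core, and mother–infant sharing percentages.
* **Functional profiles** — per-(genus, timepoint) subrole relative-abundance
  vectors (pooled over the timepoint's samples, 1 % abundance and 50 %
  subrole-coverage filters), complete-linkage Bray–Curtis dendrogram with
  taxonomic-order tip collapse.
* **Temporal patterns** — batch self-organizing map over standardized
  feature profiles, with support from 200 individual-resampling bootstrap
  replicates clustered jointly; clusters reported at 60 % / 80 % support.
* **Co-occurrence networks** — association z-scores against an
  environment-stratified fixed-fixed null model (checkerboard swaps confined
  within environment strata), FPR-calibrated aggregation/segregation calls,
  timecore subnetwork extraction with first-appearance dating, and
  transitive-aggregation motif (triangle/clique) enumeration.

A first-class synthetic-cohort generator (`succession.synthetic_data`)
reproduces the statistical structure this analysis assumes — single-genus
dominance at one week, richness rising to 3 months then dropping sharply at
the solid-food transition, a ten-genus persistent core, decreasing
inter-individual heterogeneity with age, genus-linked functional profiles,
35,000–70,000 reads per sample — so every stage is testable end-to-end
without access to cohort data.

## Worked example

```python
import numpy as np
import succession as s
from succession import abundance_io as aio, ordination, timecores, diversity

spec = s.CohortSpec(seed=1)                      # 13 pairs, 7 timepoints
taxa, meta = s.generate_cohort(spec)             # 80 genera x 87 samples

rel = aio.to_relative(taxa)
groups = meta.groups(rel.sample_ids)

res = ordination.anosim(ordination.bray_curtis_matrix(rel), groups,
                        n_permutations=999, seed=0)
print(f"ANOSIM R = {res.R:.2f}, p = {res.p:.3f}")

cca = ordination.cca(taxa, groups)
print(f"CCA1 share of constrained inertia = {cca.proportion_constrained[0]:.1f}%")

cores = timecores.compute_timecores(taxa, meta)
print(f"global core: {len(timecores.global_core(cores))} genera")

sharing = timecores.pair_sharing(taxa, meta, "I1", "MA")
print(f"mean 1-week infant vs mother genus sharing: {sharing.mean():.0f}%")
```

Output:

```
ANOSIM R = 0.26, p = 0.001
CCA1 share of constrained inertia = 59.8%
global core: 10 genera
mean 1-week infant vs mother genus sharing: 83%
```

Timepoints differ significantly in composition (R = 0.26 at p = 0.001:
moderate but real between-timepoint structure), the first canonical axis
carries most of the timepoint-constrained variation, the ten genera forced
into every sample are recovered exactly as the global core, and one-week
infants already share most of their detected genera with their mothers.

The same analyses are available from the command line:

```bash
succession simulate --out cohort/ --seed 1
succession alpha --table cohort/taxa.tsv --metadata cohort/metadata.csv \
    --rarefy-depth auto --seed 0 --out alpha.tsv
succession ordination --table cohort/taxa.tsv --metadata cohort/metadata.csv \
    --method anosim --permutations 999 --seed 0 --out anosim.tsv
succession run --config config.yaml        # full pipeline with manifest
```

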