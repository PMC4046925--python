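# Methods

This note documents the statistical procedures implemented in `succession`,
the defaults they ship with, and the choices made where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Study design and data model

The unit of observation is a stool metagenome sample from a mother–infant
pair (MIP) at one of seven occasions: infant weeks 1, 4, 13, 30 and 52
(I1–I5) and maternal samples within a week before delivery (MA) and a year
after (MB). Two feature spaces are analysed in parallel: genus-level taxon
counts and function-subrole counts (a two-level functional classification
with 116 catalogued subroles, of which 108 are observed in data of this
kind). Counts are raw sequence counts; a feature is *detected* in a sample
iff its raw count is ≥ 1. Relative abundances are per-sample proportions
of raw counts; the 1 % abundance filters operate on these. Tables are
features × samples TSV; metadata is CSV with pair, timepoint, delivery
mode, peripartum antibiotics and feeding columns.

## Synthetic cohort generator

`synthetic_data.generate_cohort` emulates the cohort's statistical
structure rather than any particular dataset. Defaults are the study
conditions:

* 13 pairs × 7 timepoints with I2 present for only 9 pairs (the four
  pairs lacking a one-month sample mirror the real enrolment), 87 samples
  in total; sequencing depth uniform on 35,000–70,000 reads.
* 80 genera, the first 10 of which form a persistent core guaranteed
  detected in every sample. Genus proportions are drawn from a
  timepoint-specific Dirichlet over a per-sample support; the support is
  sized so expected detected richness follows the configured trajectory
  (defaults 22, 32, 45, 30, 38 for I1–I5 and 55/50 for MA/MB: a rise to
  three months, a sharp drop at the solid-food transition, partial
  recovery, adult values above infant ones).
* The Dirichlet concentration starts at `dominance_concentration`
  (default 0.03) at I1 — so a single genus dominates each neonate — and
  grows by `1/heterogeneity_decay` (default 1/0.45) per age step, making
  communities more even and more similar between individuals with age.
  A founder override assigns each infant one of five founder genera
  (Bacteroides, Clostridium, Veillonella, Bifidobacterium, Escherichia)
  at 55–90 % of I1 mass.
* A 2 % uniform floor over the support keeps support genera detectable at
  the sampled depths, so realized richness tracks the trajectory instead
  of being confounded with evenness.
* Function counts are multinomial mixtures of per-genus subrole probability
  vectors (108 subroles by default) weighted by genus abundance; vectors
  are drawn with grouped (phylogeny-like) structure so functional
  similarity follows taxonomic grouping.

What the generator does **not** emulate: real taxon names beyond the core
and founders, growing timecores at I4/I5 (core membership is constant by
construction, so arrival counts on synthetic data are zero), strain-level
dynamics, chimeras/annotation error, or compositional correlations beyond
the Dirichlet. Tests passing on synthetic cohorts therefore demonstrate
the correctness and power of the machinery under the designed structure,
not conclusions about any real cohort.

## Alpha diversity and trends

Rarefaction draws each sample without replacement (multivariate
hypergeometric) to a common depth, defaulting to the minimum sample total;
one draw per sample with a recorded seed. Chao1 is reported in both the
classic form `N + F1²/(2 F2)` (with the standard `N + F1(F1−1)/2` fallback
when no doubletons exist) and the bias-corrected form
`N + F1(F1−1)/(2(F2+1))`; the bias-corrected variant is the headline
value. Shannon uses natural logs.

Richness trends are Poisson GLMs with log link (statsmodels IRLS), Wald
p-values, with timepoints coded as weeks 1, 4, 13, 30, 52. Shannon trends
use beta regression (logit mean link, constant precision,
`statsmodels.othermod.betareg.BetaModel`); since the Shannon index is not
naturally in (0, 1) it is divided by `ln(S_global)` (log of the
dataset-wide distinct-feature count) and then boundary-compressed by
`y → (y(n−1)+0.5)/n`, an order-preserving standard transform for
beta-distributed responses. Type-I-error calibration of this test is
checked by simulation at n = 150 observations per replicate, a size at
which the asymptotic Wald test is in its validity regime.

Per-infant temporal profiles (globally centered and scaled) are clustered
by correlation distance with average linkage. Node support is the ordinary
bootstrap probability — the fraction of timepoint-resampled replicates in
which a node's leaf set recurs — not the multiscale AU approximation;
thresholds (default 0.95) are configurable.

## Distances, tests, ordination

Bray–Curtis `Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ)` on per-sample relative abundances is the
compositional dissimilarity throughout; Gower (mean range-normalized
absolute difference, zero-range features dropped) feeds PCoA. ANOSIM uses
midranks and the permutation estimator `p = (1+b)/(1+m)`, which never
returns zero and floors at 0.001 for 999 permutations; pairwise ANOSIM is
Benjamini–Hochberg-adjusted by default (Bonferroni available). PERMANOVA
forms the pseudo-F from among/within sums of squared distances and reduces
exactly to one-way ANOVA for Euclidean distances on 1-D data (asserted in
tests). PCoA eigendecomposes the double-centered −D²/2 matrix; negative
eigenvalues are reported, not corrected, and axis shares are computed over
positive eigenvalues only.

CCA chi-square-standardizes the count table, projects the residual matrix
onto the (row-weighted, centered) constraint design and decomposes the
projection by SVD; the implementation agrees with the standard constrained
correspondence analysis of community ecology to numerical precision on a
frozen reference fixture. Axis percentages are reported under two
conventions — share of total inertia and share of constrained (canonical)
inertia — because published CCA axis percentages are ambiguous between
them; the constrained-share is the headline. Whether counts or proportions
enter is the caller's choice; CCA defaults to counts (chi-square
standardization makes columns proportional anyway).

Convex hulls are built on the first two ordination axes per group
(shapely); the dissimilarity of two timepoints is `1 − area(∩)/area(∪)`,
symmetric, in [0, 1], and zero iff the hulls coincide. Groups with fewer
than three non-collinear points are an error naming the group.

## Timecores

`timecore(t)` is the intersection of detected-feature sets over the
samples of timepoint t, computed on unrarefied counts (detection = count
≥ 1; minimum-count and minimum-relative-abundance knobs exist for
sensitivity analysis). I2 cores use the nine available samples. The Venn
partition assigns each feature to the exact subset of timecores containing
it (cells are disjoint and cover the union — property-tested). Arrival
accounting (`new_core_arrivals`) and infant–mother sharing
(`100·|infant∩mother|/|infant|`, any-detection, per pair) complete the
module.

## Functional profiles

Profiles are per-(genus, timepoint) subrole relative-abundance vectors,
pooled over the timepoint's samples because per-sample genus×subrole
counts are too sparse. Genera enter only if they exceed 1 % relative
abundance in some sample **and** cover at least 50 % of the subroles
observed dataset-wide (the dataset-wide universe, not the catalogue's 116,
is the denominator). Profiles from all timepoints of a genus are clustered
jointly, one leaf per (genus, timepoint). Distances are Bray–Curtis;
linkage is complete; clades whose tip genera share one taxonomic order
(user-supplied two-column mapping) are collapsed; flat groups are cut at a
configurable count (default 6). Output includes a Newick serialization.

## Temporal SOM

Feature profiles are mean relative abundances per timepoint, centered at
the grand mean and scaled by the grand SD. The SOM is a batch map with a
Gaussian neighborhood shrinking geometrically across epochs to the k-means
limit; grid default 3×1 (one node per expected pattern class: decreasing,
increasing, transient peak), deterministic under seed. Quantization error
decreases overall and is exactly non-increasing once the neighborhood has
effectively vanished; while the neighborhood is active the map minimizes
the smoothed distortion, so the winner-only QE may fluctuate at the 10⁻³
level (tested at that tolerance).

Bootstrap support resamples individuals (pairs) with replacement, rebuilds
every feature's profile per replicate, and clusters all 200 replicate
profile sets jointly with the reference profiles on one SOM. A feature's
support is the fraction of replicates whose profile lands on the same node
as the feature's reference profile (a pairwise co-classification variant
is deliberately not the default; node identity is the simplest consistent
reading). Clusters are reported at 60 % and 80 % support; retention is
monotone in the threshold. Note that bootstrap-stable classification is a
*stability* statement, not a significance test: features with stable but
structureless profiles can retain support, so null (iid-noise) features
are suppressed relative to structured ones rather than eliminated.

## Co-occurrence networks

The null model randomizes a taxa × samples presence/absence matrix by 2×2
checkerboard swaps restricted to columns of the same environment stratum,
conserving every taxon's total and per-environment occurrence counts and
every sample's richness exactly. Burn-in defaults to 10× the number of
ones and thinning to 5×, counted in attempted swaps; strata with fewer
than two samples are frozen with a warning. Association scores are
`z = (C−μ)/σ` per taxon pair, where C is the observed co-occurrence count
and μ, σ the ensemble moments (σ = 0 pairs skipped). The call threshold z*
is not fixed a priori: it is the smallest grid value for which the mean
number of ensemble-member calls (false positives by construction) divided
by observed calls is at most the requested false-positive rate (default
0.05). Aggregations are z ≥ z*, segregations z ≤ −z*. A taxon's dominant
environment is the label holding more than half of its occurrence samples,
else "cosmopolitan".

Timecore subnetworks keep parent edges whose endpoints are co-resident in
some timecore, dated by the earliest such infant timepoint and flagged for
MB membership. Transitive aggregations are triangles and maximal cliques
(size ≥ 3) of the aggregation-only subgraph; segregation edges never enter
motifs. The module accepts a precomputed parent edge list (TSV) or builds
a parent network from any environment matrix, since published parent
networks of this kind are generally not redistributable.

## Pipeline

`succession run --config config.yaml` executes all stages in dependency
order, stamps every output with the configuration hash and seed in a JSON
manifest, logs one structured line per stage, and isolates stage failures
so completed outputs survive. Rerunning a configuration is byte-identical.

## Problem sizes and numerical choices

Default permutation counts are 999; the test suite and acceptance script
use 199–999 permutations, 200 SOM bootstrap replicates, 50 null-model
randomizations of a 30×240 environment matrix, 1000 beta-regression null
replicates, and 20 repetitions of the n = 500 regression recovery — sizes
chosen so the full analysis reruns in about a minute on one CPU while
keeping Monte-Carlo error well inside the asserted tolerances. Numerical
tie-breaks: midranks everywhere ranks are used; eigenvalues below 1e−12
are treated as null space; correlation distance falls back to 0/1 for
constant profiles (identical/different); degenerate hulls and zero-total
samples are hard errors naming the offender.

## Known limitations

* Sharing percentages and timecores are presence-based; no abundance floor
  is applied by default, so they are sensitive to sequencing depth.
* Beta-regression p-values are asymptotic Wald; at very small n they run
  slightly anticonservative.
* The SOM grid, neighborhood schedule and resampling-with-replacement
  choices are conventions, exposed as parameters, not inferences.
* The co-occurrence caller assumes the environment stratification captures
  all "trivial" association structure; unmodeled habitat gradients within
  a stratum will surface as associations.
* Synthetic cohorts have constant core membership over time, so
  arrival-count statistics are only exercised, not stressed, without real
  data.
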