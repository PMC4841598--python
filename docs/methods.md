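# Methods

## Scope and data model

The package analyses a replicate-free two-genotype RNA-seq design: one
library per genotype (wild type WT, mutant MT) per ripening stage. The
primary containers are a `CountMatrix` (genes x samples integer reads,
per-sample library sizes, per-gene lengths in bp), RPKM expression frames
(genes x samples), tidy per-comparison DE tables, and a `ModulePartition`
(gene -> module labels, eigengenes, kME/GS tables). Sample identifiers
follow the `<genotype><stage>` convention (e.g. `MT170`), which the
pipeline uses to form stage-matched MT-vs-WT comparisons with MT/WT
fold-change orientation.

## Exact Poisson differential expression

With `x` reads in a library of `N1` and `y` in a library of `N2`, the
test conditions on `x` and marginalises the latent Poisson rate, giving

    P(y|x) = (N2/N1)^y (x+y)! / ( x! y! (1+N2/N1)^(x+y+1) ),

a negative-binomial pmf in `y` with size `x+1` and success probability
`N1/(N1+N2)`. The two-sided p-value follows the doubled-tail rule
`p = 2C` if `C = sum_{i<=y} P(i|x) <= 0.5`, else `2(1-C)`, capped at 1.
The cumulative includes the observed point mass, so the two doubled tails
are not mirror images around it; the rule is applied literally rather
than via a point-mass-corrected variant, and the resulting test is
slightly conservative (verified empirically below).

Numerics: each pmf term is a log-gamma expression and terms are combined
by log-sum-exp, so counts up to 10^6 neither overflow nor underflow. The
complement `1 - C` is never formed by float subtraction: by a regularized
incomplete-beta identity it equals the swapped-argument cumulative
`sum_{i<=x} P(i|y)` with the library ratio inverted, which is summed in
log space directly. The identity also makes the implementation exactly
symmetric, `p(x,y,N1,N2) = p(y,x,N2,N1)`. P-values are clamped to at
least the smallest positive double so the `(0, 1]` contract holds even in
astronomically deep tails.

Thresholds: DEG = (BH FDR <= 0.001) and (|log2 ratio| >= 1), both
configurable. FDR is computed within each pairwise comparison (the
alternative — pooling across stages — is not used; each stage is reported
as its own comparison file). BH adjustment delegates to
`statsmodels.stats.multitest.multipletests`.

Fold changes use RPKM with a small positive floor (default 0.001 RPKM)
applied only to values below it: the ratio is exact when both sides are
expressed, and a silent side yields a finite magnitude of about
|log2 floor| ~ 10, matching the ~±10 extremes that appear when one
condition has no detectable expression. The floor value is a
configuration choice, not an estimate; analyses sensitive to it should
treat such genes qualitatively (present/absent) rather than by magnitude.

No dispersion is estimated anywhere: with one library per condition,
biological variance is not identifiable, and the test is exact only under
the Poisson assumption. The synthetic generator's negative-binomial
option exists precisely to demonstrate the consequence — under
overdispersion the test's false positive rate inflates well above its
nominal level (a unit test asserts this), which is the honest reading of
its applicability limits.

## TF family assignment

Input is a precomputed domain-hit table (gene, model, e-value, score);
running the profile-HMM or alignment search itself is out of scope. Hits
above the e-value cutoff (default 1e-10, the conventional stringent
threshold) are discarded. A family rule is a non-empty required-model set
plus an optional forbidden-model set; a gene qualifies for a family when
all required models are hit and no forbidden one is, and among qualifying
families the one whose best supporting hit has the smallest e-value wins
(ties: larger score, then lexicographic family name — fully
deterministic). The shipped rule set is a small illustrative subset of a
required/forbidden scheme over common plant DNA-binding domains and is
user-replaceable by a TSV table; real analyses should load the rules of
their reference TF database.

## Coexpression network

Construction mirrors standard weighted gene coexpression network analysis
with an unsigned adjacency:

* **Filter**: keep genes with RPKM > 0.3; the statistic is the per-gene
  maximum across samples (not the mean), so stage-specific genes that are
  silent elsewhere survive; the mean variant is available as an option.
* **Adjacency**: `a_ij = |pearson|^beta`, diagonal set to 0 for
  connectivity purposes. The default `beta = 6` is the conventional
  unsigned-network choice; `pick_soft_threshold` scans candidate powers
  and returns the smallest with approximate scale-free fit R^2 >= 0.8
  (signed fit index on a 10-bin log-log degree regression), falling back
  to the argmax power with a warning on structureless data. When two or
  fewer degree bins are occupied the regression is exact by construction
  and the fit is reported as perfect.
* **TOM**: `tom_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)`,
  diagonal 1, entries clipped to [0, 1] against rounding.
* **Module detection**: average-linkage clustering of 1 − TOM
  (scipy), followed by a two-stage simplified tree cut standing in for
  the dynamic hybrid algorithm: (1) candidate fixed cut heights (height
  quantiles of the dendrogram) are scanned and the cut maximizing the
  number of branches of at least `min_module_size` (tie-break: lowest
  such height) defines tight module cores; (2) each unassigned gene joins
  the module it overlaps most with, provided its mean TOM to that module
  reaches half the module's own mean intramodular TOM — outliers of a
  branch rejoin it, background genes stay grey. This is an approximation:
  it reproduces planted-module structure essentially exactly (adjusted
  Rand index > 0.95 on the latent-factor preset) but is not
  branch-shape-aware the way the full dynamic cut is.
* **Merging**: modules whose eigengenes are closer than
  `merge_cut_height = 0.25` in correlation dissimilarity are merged
  iteratively (closest pair first) until no pair remains below the
  threshold; the fixed point is property-tested. Final modules take
  conventional color names in decreasing size order; grey is unassigned.
* **Single block**: the gene count must not exceed `max_block_size`
  (default 19,000); multi-block pre-clustering is deliberately not
  implemented, since at the intended scale blocking never triggers.

Eigengenes are the first right singular vector of the per-gene
standardized module matrix, scaled to unit variance (ddof = 1) and
sign-aligned so the mean correlation with member profiles is
non-negative. kME, GS and module–trait correlations are Pearson r with
two-sided p-values from the Student t with n − 2 df, evaluated through
the equivalent incomplete-beta form (stable at |r| = 1). The significance
rule for module–trait (and module–TF) links is |r| > 0.8 and p < 0.05;
hub genes require |GS| >= 0.8 and |MM| >= 0.8, each with p < 0.05.
Correlation p-values at very small n (6 samples in the motivating design)
are fragile; the recovery guarantees quoted here are established at
n = 20 samples.

Permutation validation: a module's observed mean off-diagonal TOM is
compared with the same statistic on B random same-size gene subsets
(without replacement, seeded); the empirical p-value is
`(1 + #{null >= obs}) / (B + 1)`, so the smallest attainable p at the
default B = 999 is 0.001. The report keeps raw p-values; no validity
threshold is hard-coded.

## Downstream summaries

Venn partitions are computed exactly for 2 or 3 named sets (all disjoint
regions plus the union; the inclusion–exclusion identity is
property-tested). Fold-change profile clustering follows the Eisen
scheme: uncentered correlation similarity (all-zero profiles are given
similarity 0 to everything), average linkage, tree cut to k flat
clusters (default k = 6, a parameter rather than an inferred number),
labels I, II, ... assigned in dendrogram leaf order. Missing fold-change
entries must be imputed before clustering; the DE layer's floor rule
produces finite extreme values for silent genes, so in the integrated
pipeline no missing values arise. Term enrichment is the one-sided
hypergeometric upper tail `P(X >= k)` per term with BH correction across
terms and an enriched call at corrected p < 0.01 (the correction method
in the original tooling is unstated; BH is assumed).

## Synthetic data

The generators produce the exact statistical structure the methods
assume, so recovery tests measure the methods rather than the simulator:

* **Counts**: `x ~ Poisson(lambda_g m_gs N_s / 1e6)` with log-normal
  per-gene rates (log-mean 3.0, log-sd 1.2 — a right-skewed
  reads-per-million distribution typical of bulk RNA-seq), uniform gene
  lengths 200–5000 bp, library size 10^6, 2 genotypes x 3 stages, and a
  planted DE fraction (default 10%) whose mutant-sample multiplier is
  `2^(+-effect)` (default effect 2). The default preset (2,000 genes, 6
  samples) mirrors the motivating study's shape at roughly one-tenth gene
  scale. The negative-binomial option multiplies rates by Gamma noise to
  probe the exact test under overdispersion.
* **Coexpression**: module m has a standardized latent factor f_m over
  samples; member genes are `loading * f_m + N(0, noise_sd)` with
  `noise_sd = sqrt(1 - loading^2)` by default, giving unit gene variance
  and within-module correlation loading^2 (0.81 at the default 0.9).
  Preset: 5 modules of 50 genes plus 100 background noise genes; network
  tests use 20 samples for correlation stability. Traits are linked
  factors plus N(0, 0.3) noise.
* **Domain hits**: each planted TF gene hits one required model of its
  family at e-value 10^U(-50, -11); misses and above-cutoff decoys are
  injected at stated rates and recorded in the truth object.

Every generator is deterministic given (seed, parameters), and the truth
object (JSON-serialisable) carries the seed, parameters and all planted
structure. What passing recovery tests shows is internal consistency —
the pipeline finds exactly the structure its models posit. Real data add
overdispersion, correlated noise, batch structure, length biases and
annotation error that these generators deliberately omit (only
overdispersion is modelled, as a negative control).

## Numerical and design choices

* Exact-test tails: log-gamma + log-sum-exp summation over the smaller
  tail; complement via the swap identity; p clamped into `(0, 1]`.
* Correlation p-values: incomplete-beta form of the t-test, exact at
  |r| = 1.
* Eigengene sign and standardization conventions fixed (ddof = 1,
  non-negative mean member correlation) for reproducibility.
* All randomness flows through `numpy.random.default_rng` seeded
  explicitly; pipeline outputs embed the seed in the run manifest and
  reruns are byte-identical.
* The two clustering-shaped components are scikit-learn estimators
  (`WGCNA`, `ProfileClusterer`: `fit`, `labels_`, `get_params`) so they
  compose with sklearn tooling; the other stages are plain functions, as
  an exact test or a rule lookup has no meaningful fit/predict split.
* Problem sizes in tests and the acceptance script (2,000-gene count
  presets, 10,000-gene null calibration, 350-gene networks, B = 999
  permutations, 100 trait-link replicates) were chosen as the smallest
  scales at which the measured quantities are stable to well within their
  acceptance margins.

## Known limitations

* The exact test is valid only under Poisson sampling; no
  replicate-aware or dispersion-corrected inference is offered.
* The simplified tree cut is height-based and can behave differently
  from the dynamic hybrid algorithm on strongly nested or unbalanced
  dendrograms.
* The shipped TF rule table is illustrative, not a curated database.
* Multi-block network analysis, signed networks, consensus networks and
  GO-graph-aware enrichment are out of scope.
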