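# Methods notes

This note records the statistical models, the defaults and their
rationale, the design choices made where the design was genuinely open,
and what the synthetic-data experiments do and do not demonstrate.

## Differential abundance

Each feature is compared between groups with the two-sided Wilcoxon
rank-sum test. For tie-free pooled samples with combined n ≤ 20 the exact
permutation distribution is used; otherwise the normal approximation with
tie-corrected variance and a continuity correction applied toward the
mean, which reproduces the R `wilcox.test` convention (in particular,
identical groups give p = 1 exactly). Benjamini–Hochberg correction is
applied within each taxonomic rank: features at different ranks are
nested sums of one another, so pooling them into a single family would
mix dependent copies of the same signal; a flag pools all ranks instead.
Enrichment direction goes to the group with the higher median relative
abundance (mean as tie-break, `none` if both tie) — medians because
compositional profiles are sparse and heavy-tailed. A prevalence filter
exists but is off by default.

The AChRAb subgroup contrasts split cases at a titre of 0.5 nmol/L,
seropositive strictly above, and always compare against the full control
group.

## Marker selection by CV error curves

Candidates are ranked once by mean impurity importance of a forest
trained on all candidates, in canonical (sorted) feature order so the
ranking cannot depend on input column order; ties break lexicographically.
The error curve is estimated per trial with a fresh stratified fold
assignment (stratification is enforced — at cohort sizes near 20 an
unstratified fold can lose a class entirely); the error at k is the
pooled misclassification fraction over held-out folds for a forest on the
top-k candidates.

The selection cutoff is the average curve's minimum plus the
across-trial standard deviation at that point, and k* is the smallest k
whose average error is at or below the cutoff, so k* ≤ k_min always. A
bare standard deviation is not on the error scale, which is why the
additive min+SD form is used. When all trials agree exactly at k_min
(common at small n, where errors are multiples of 1/n), the SD collapses
to zero and k* = k_min; more trials make this less likely. Defaults are
500 trees, sqrt(p) features per split, unlimited depth, 5 folds and 5
trials; folds and trials are both configurable because repeated-trial
10-fold variants of this procedure are also in circulation.

Training-cohort probabilities are out-of-bag vote fractions (avoiding
resubstitution optimism); held-out samples get ordinary vote fractions.
AUC is the Mann–Whitney statistic with ties counted one half, identical
to pairwise concordance. The validation design holds out a seeded random
subset of controls together with the validation-cohort cases (the
53/34-train, 19/12-test shape).

## Co-abundance gene groups

Canopy clustering on per-sample gene-family abundance profiles: a seed
profile is drawn from the unassigned pool in a seeded random order; all
pool profiles with Pearson r > 0.9 to the centroid are gathered; the
centroid is recomputed as the per-sample median; gathering repeats to a
fixed point (cap 100 iterations). Gathered members leave the pool, so
membership is a partition. Canopies whose centroids correlate above 0.97
merge; canopies under 3 members are dropped. The thresholds and the
median centroid follow the established co-abundance-clustering
convention; all are parameters. By default the clustering input is the
significantly different stratified families (a flag clusters everything).

A CAG is annotated to a species when at least 80% of members carry that
species' stratification tag — inclusive at exactly 80%, so 8 of 10
qualifies and 7 of 10 does not. Enrichment reuses the Wilcoxon + BH
machinery on centroid profiles. Network edges between centroids require
r > 0.5 (positive) or r < −0.2 (negative); nodes carry size, species and
enrichment.

## Ecology

Shannon diversity uses the natural logarithm (the vegan convention; the
base is configurable) over non-zero proportions. Bray–Curtis is computed
on per-sample vectors and is bounded in [0,1] for relative abundances.
PCoA is classical scaling of −D²/2; Bray–Curtis matrices are
non-Euclidean, so negative eigenvalues arise and are dropped with a
warning rather than corrected — the ordination is descriptive here, and a
correction would change no downstream decision. PCA is the centred SVD;
on Euclidean distance matrices the two agree up to sign, which the tests
exploit, along with a cross-check against scikit-bio's implementation.

## Virome presence

Presence requires mean alignment depth strictly greater than 2×
fold-coverage ("over two"), with the threshold configurable. Depth
summaries are the input contract; alignment itself is out of scope.

## SCFA calibration and association

Standard curves are ordinary least squares of peak area on concentration
over the seven-level 1–200 μg/ml dilution series; replicate points enter
individually. Quantification inverts the line; negative back-calculations
are clipped to zero and flagged, and concentrations below the lowest
calibrated level are reported but flagged as below the limit of
quantification rather than censored. Group comparison is Welch's t-test
by default (equal-variance Student's t via a flag) because equal group
variances are not defensible a priori. Species–acid association is
Pearson r with the two-sided t-distribution p on n−2 df,
pairwise-complete; BH adjustment across the species × acid matrix is
optional and off by default, matching the Hmisc-default convention of
reporting raw correlation p-values.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not any real cohort:

* **Taxonomic profiles** are log-normal: a per-feature baseline
  log-abundance drawn once (SD 2, giving realistically heavy-tailed
  compositions), plus `direction × effect_size` for the planted
  differential features in cases, plus per-sample log-noise of SD
  `dispersion`, closed to relative abundances. Planted directions are
  balanced. Defaults: 53 cases vs 46 controls, 25 differential species,
  effect 2.0 natural-log units, dispersion 1.0 — the cohort shape and
  planted dimensionality of the study design this package targets; effect
  size and dispersion are calibration choices, since no cohort estimates
  exist to plug in.
* **Zeros** emulate a detection limit: each feature's lowest values are
  censored, with an expected zero fraction decreasing in baseline
  abundance (mean 0.3 by default) and the most abundant feature never
  censored. Censoring, rather than independent Bernoulli dropout, makes
  prevalence co-vary with abundance the way profiler output does; it also
  means a strongly shifted feature gains a presence/absence signal.
* **Metadata** mirrors the cohort table: AChRAb titres (seropositive
  fraction 34/53, positives strictly above 0.5 nmol/L, controls at or
  below), age ~ N(7, 3.8) years, gender and birth-mode rates per group.
* **Gene families**: each planted block shares a unit-variance per-sample
  log-latent; member noise SD is calibrated so the *value-scale*
  (log-normal) pairwise Pearson correlation matches
  `within_cag_correlation` — calibrating on the log scale would
  systematically undershoot the correlation the canopy actually sees.
  ≥ 90% of a block's members carry the block's species tag; non-block
  families are independent noise. An optional group effect on the block
  latent supports enrichment experiments.
* **Viral depth**: controls are always zero; positive cases get
  2 + Exponential(mean 5) fold-coverage, so every true positive clears
  the presence cutoff; prevalence defaults to 10/53.
* **SCFA panel**: per-acid baselines plus a case-group shift on butyric
  and isobutyric acid (default −2 μg/ml against noise SD 2, i.e. a one-SD
  deficit), plus a coupling coefficient times the centred log-ratio (CLR)
  of the coupled species' abundance — CLR so the coupling is scale-free
  on compositional input.

Everything is a pure function of the seed; the emitted file set is
byte-for-byte reproducible.

### What the synthetic experiments show — and what they don't

Passing recovery tests shows the implementation correctly extracts planted
structure of the assumed form at study-like dimensions. It does not show
the methods would perform equally on real cohorts, where effects are
smaller, features are correlated beyond the planted blocks, zeros are
messier, and batch structure exists. The null-calibration experiments
(uniform p-values, chance-level permuted-label AUC) are run on the
continuous (uncensored) generator because rank-test p-values under heavy
ties at zero are discrete and conservative — a property of the test, not
a defect — and a Kolmogorov–Smirnov uniformity check is only meaningful
for continuous statistics. The planted-marker recovery study likewise
uses the uncensored generator: under detection censoring a two-log-unit
shift turns into a near-perfect presence/absence separation, and the
error curve then bottoms out at one or two species — a different (and
easier) regime than the graded multivariate signal the recovery study is
designed to probe.

## Problem sizes and numerical choices

Simulation-backed tests run at the study's cohort shape but with forests
scaled to 40–60 trees and 2–3 CV trials; the selection statistics under
study are unchanged while each study stays within a few minutes. The
acceptance script runs the full pipeline at the production defaults
(500 trees, 5 folds, 5 trials). Determinism everywhere derives from a
single seed via independent seed sequences per stage; forest seeds are
derived per (trial, k, fold). Degenerate inputs have defined behaviour:
constant features give p = 1 and no direction, zero-variance profiles are
excluded from correlation (NaN, flagged), zero-sum samples raise a named
error, all-zero prediction samples get a valid probability.

## Known limitations

No compositionality-aware differential tests (ANCOM/ALDEx2 family) and no
covariate adjustment — deliberately, to mirror the target workflow.
Canopy thresholds are convention, not fitted; the real number of CAGs in
any cohort depends on them. Probabilities from the final forest are
uncalibrated vote fractions. The generator plants independent blocks and
species; it cannot emulate phylogenetically structured correlation.
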