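# Methods

This note documents the models, numerical choices and limitations of the
`rpqcluster` pipeline, in the order the method runs.

## Scoring

Raw RPQ-16 responses are integers 0–4. The correction maps 1 → 0 and leaves
all other levels unchanged (idempotent); corrected scores therefore lie in
{0, 2, 3, 4} and a corrected value of 1 is impossible — this is asserted
structurally in the tests. The ≥ 16 total threshold for "significant
symptoms" is inclusive, as is the 12-month boundary for the prolonged group
(exactly 12 months is prolonged). Participants with any missing item
response are excluded from score-based analyses (complete-case) with a
logged count; no imputation is attempted. The standard published RPQ-16
item order is used, with the first three items (headache, dizziness,
nausea/vomiting) forming the RPQ-3 subscale.

## Clustering

**Correlation.** Spearman rho is computed with midranks for ties (scipy).
A constant score column makes rho undefined; the implementation falls back
to Pearson-on-midranks and sets the undefined off-diagonal entries to 0
with a warning, treating a constant symptom as uninformative for
co-ranking. This arises only in degenerate or tiny cohorts.

**Profile distances.** Items are clustered on the rows of the correlation
matrix *including* the unit diagonal entries, because that is what
row-clustering a correlation matrix with a Euclidean metric does in the
common heat-map implementations. Excluding the diagonal changes distances;
the inclusive convention is deliberate and fixed.  No row standardisation
is applied before the distance computation.

**Linkage.** Agglomeration is unweighted average linkage (UPGMA): the
distance between groups is the arithmetic mean of all cross-pair leaf
distances. UPGMA heights are monotone non-decreasing, which the MergeTree
constructor asserts on every run. The implementation uses the
Lance–Williams update and is verified merge-by-merge against a naive
re-scan oracle and against scipy's linkage on fixed cohorts. Equidistant
candidate pairs are broken deterministically: the pair whose smallest leaf
index is lowest wins, then the pair whose other smallest leaf index is
lowest. Single, complete or Ward linkage are not offered in the pipeline
run; average linkage is the documented default of the row-clustering
convention this pipeline follows.

**Cluster formation.** "Formed" means: let K be the smallest merge index
after which no singleton group remains; the symptom-cluster set is the
partition immediately after merge K, giving 16 − K clusters, each of size
≥ 2. The alternative height-based reading of "hierarchical level" is not
implemented as a separate mode; when the merge heights at and just above
the cut tie, a warning is logged because the cut is then ambiguous in
height terms. Clusters are named by exact membership match against the
canonical five-cluster composition (headache-related, sensitivity,
sleep-fatigue, cognitive, emotional); non-matching groups get generic names
derived from their leading member, since naming is a labelling convention,
not derivable from data alone. Clustering a group smaller than 30
participants logs a "preliminary, small n" warning.

## Membership

Thresholds are inclusive ("at least mild" = corrected ≥ 2, "at least
moderate" = ≥ 3). The mean criterion compares exactly — the implementation
tests `sum ≥ t·size` in integer arithmetic, so no floating-point rounding
can flip a membership. The nesting all ⊆ mean ⊆ any (min ≥ t ⇒ mean ≥ t ⇒
max ≥ t) is asserted at runtime on every assignment.

## Association testing

* **Test selection.** Fisher's exact test replaces the chi-squared test
  when any expected cell count is below 5 (the classical rule; the
  threshold is a keyword argument). The chi-squared test applies no Yates
  continuity correction by default (configurable).
* **Fisher p.** Two-sided, by hypergeometric enumeration: the sum of all
  conditional table probabilities no greater than the observed one, with a
  relative tolerance of 1e-7 against floating-point ties (the convention of
  the standard implementations). Verified to 1e-12 against exact integer
  enumeration for every table with n ≤ 40.
* **Odds ratios.** OR = ad/bc with Wald 95% CIs on the log scale. Any zero
  cell triggers the Haldane–Anscombe correction (+0.5 to all cells), and
  the result is flagged as corrected.
* **Mann-Whitney.** U for the first sample from midranks. For groups of at
  most 8 each, the two-sided p is exact by enumeration over all group-label
  assignments (tie-exact); otherwise the normal approximation with tie and
  continuity corrections is used. For heavily tied five-level data at
  n ≈ 12 per group the approximation tracks an exact permutation p to
  within about 0.05; at the sample sizes the pipeline analyses (hundreds),
  it is accurate to well under 0.01.
* **Families.** One Bonferroni family per severity threshold for the 30
  cluster × impairment tests (α = 0.05/30 ≈ 0.0017) and one for the 36
  score × impairment severity comparisons (α = 0.05/36 ≈ 0.0014).
  Significance flags are exactly `p < family_alpha`; raw p < 0.05 is
  reported separately. Sensitivity re-analysis (any/all criteria) runs only
  for pairs significant under the main criterion, and `sensitivity_robust`
  records whether both alternatives stay significant.
* **Severity-by-impairment scope.** The global comparison (any impairment
  vs none, on the corrected total) uses all impairment-question completers.
  The per-impairment comparisons are run among participants who reported at
  least one impairment (the "none" group is excluded), which is the
  categorical-ordinal design the membership analysis complements. The
  "other" impairment category is excluded from all analyses as nonspecific;
  "none" is never generated independently but derived as the absence of
  every specific flag.
* **Degenerate tables.** An empty 2×2 margin (possible in tiny early-group
  runs) makes the test undefined; the pipeline records a NaN result with a
  log entry rather than aborting, so a 20-participant early-group run still
  completes end-to-end.

## Synthetic cohorts

The generator is a Gaussian copula: each participant draws a 16-dimensional
standard-normal latent vector with correlation `rho_within` (default 0.6)
inside each planted block and `rho_between` (default 0.15) across blocks;
positive definiteness is checked at construction. Coordinates are
discretized through per-item cutpoints into 0–4 responses. Defaults use one
shared set of category probabilities (0.55, 0.15, 0.14, 0.10, 0.06 for
levels 0–4), calibrated once so that roughly a third of a prolonged cohort
crosses the corrected-total ≥ 16 marker — the prevalence regime of the
cohorts this package emulates. Discretization attenuates rank correlations
below the latent rho, which the tests check as a property.

Impairment flags follow per-impairment logistic models on the mean
corrected severity of each planted cluster. Default intercepts target
marginal prevalences of 34.3% (appointments), 44.9% (conversations), 5.9%
(driving), 27.6% (math), 37.0% (paperwork) and 29.1% (planning); when
slopes are planted the intercept is centred by subtracting slope × expected
cluster-mean severity so the marginal prevalence stays near its target.
Default slopes (0.45–0.6 log-odds per unit mean severity) sit on the
cluster–impairment pairs where moderate effects are plausible — sleep-
fatigue and cognitive most broadly, driving not at all — and produce
empirical membership odds ratios of about 3–4.5 at large n. The "other"
category is generated independently at 4% and excluded downstream;
impairment-question completion is an independent 254/467 coin so that
missing-impairment handling is always exercised. The prolonged fraction
defaults to 445/467. One master seed feeds named independent sub-streams
(duration, latent scores, impairments, other, availability), so adding a
stage never perturbs another stage's draws.

`implied_membership_odds_ratio` computes the population membership-
impairment OR by taking exact logistic expectations over a large seeded
Monte-Carlo draw of the severity distribution (no impairment noise is
simulated), and `calibrate_slope_for_or` bisects the slope against it —
this is how experiments plant an effect of known population OR.

**What the generator does not emulate.** Real cohorts have item-specific
marginals, heterogeneous within-block correlations, demographic structure,
comorbidities and informative missingness; the generator has none of these.
Passing recovery and calibration tests therefore show that the pipeline's
machinery is correct under its assumed dependence structure, not that five
clusters would be recovered from any particular real cohort.

## Problem sizes and known limitations

* Cluster recovery is measured on 20 cohorts of n = 1000. Under the default
  exchangeable block correlations the formation rule recovers the planted
  partition exactly in roughly 85–95% of seeds; when it misses, a 4- or
  5-item block has assembled as two sub-pairs whose final join falls after
  the last singleton pairing, so the cut splits that block into a 6-cluster
  refinement. This is a property of the formation rule under exchangeable
  within-block correlation (a single `rho_within` makes all within-block
  distances statistically identical), not an estimation failure — the
  partition is still a refinement of the truth, and the modal cluster count
  remains five.
* Null family-wise error uses 100 cohorts at the emulated study size
  (n = 445); Bonferroni plus the discreteness of Fisher's test make the
  realised rate conservative (1–4%).
* Coverage of the planted-OR Wald CI uses 400 replicate cohorts of
  n = 1000, chosen to estimate the coverage proportion to about ±2.5%;
  measured coverage is ≈ 93%, slightly below nominal because the log-OR
  point estimate carries a small positive small-sample bias.
* The exhaustive Fisher oracle comparison covers all 2×2 tables with
  positive margins and n ≤ 40 (132,470 tables).
* Everything is deterministic given (config, seed); pipeline runs with the
  same inputs produce byte-identical CSV artifacts.
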