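# Methods

## Model and procedure

`mmclust` segments a multimorbid population (everyone with ≥ 2 of 33 chronic
conditions) by k-means in a joint feature space of binary condition
indicators and yearly healthcare-utilization counts. The procedure has five
stages.

**Standardization.** Every clustering variable — including the binary
condition flags — is centered and scaled to unit variance. Sample SD
(divisor n−1) is used; at registry scale the choice is numerically
irrelevant, but it must be fixed for bit-reproducibility. A zero-variance
column (a condition nobody has) is an error, not silently dropped: the
caller should remove it deliberately. Utilization counts are not capped or
winsorized before standardization.

**Domain balancing.** With p_c = 33 condition columns against p_u = 7
utilization columns, the condition block would contribute 33/7 times as much
to expected squared pairwise distance between independent standardized
observations (each standardized column contributes E(z_i − z_j)² = 2). The
utilization block is therefore multiplied by w = √(p_c/p_u) = √(33/7) after
standardization, equalizing the blocks' expected contributions. The argument
assumes independent columns; the package implements the stated formula
without re-deriving it for correlated data. A scalar `weight_factor`
multiplies w for the sensitivity analysis; no per-variable weighting is
offered.

**Clustering.** Hartigan–Wong k-means: after a Voronoi assignment to the
initial centroids, single points are transferred between clusters whenever
the size-adjusted insertion cost n_t·d²(x,c_t)/(n_t+1) is below the removal
gain n_s·d²(x,c_s)/(n_s−1), with centroids updated live after every
transfer. This strictly decreases WCSS and typically reaches lower optima
than Lloyd iterations. Implementation details that the algorithm's
definition leaves open, fixed here:

- *Initialization*: k distinct observations sampled uniformly without
  replacement (no k-means++, keeping the initialization distribution simple
  and uniform).
- *Ties*: a point equidistant to several centroids goes to the lowest
  cluster index; deterministic given the seed.
- *Empty clusters* after the initial Voronoi step are reseeded with the
  point farthest from its current centroid; during transfer passes a
  cluster cannot empty because singletons are never moved.
- *Iteration cap*: 100 full passes, with a `converged` flag in the result;
  in practice convergence takes well under 100.
- After convergence, centroids and WCSS are recomputed exactly from the
  assignments, washing out incremental floating-point drift.
- The inner loop is JIT-compiled (numba); the first call in a fresh
  environment pays a one-time compilation cost of a few seconds.

**Stability protocol.** One *run* = best (lowest WCSS) of 25 random
initializations. 200 runs are executed; if the minimum WCSS recurs in more
than 10 runs (equality at relative tolerance 1e-10 — WCSS values are
compared as reals, and a tolerance is unavoidable in floating point; whether
recurrence should instead be checked by identical partition is an open
interpretation, and value-with-tolerance is implemented), the minimizing
clustering is accepted; otherwise 100 extra runs are added and the overall
best kept. Per-run RNG substreams are derived from the master seed by
counter (`SeedSequence((seed, run_index))`), so results are reproducible and
independent of execution order. All protocol levels are configurable; the
desk-scale defaults in the pipeline (20 runs × 5 starts) keep an n ≈ 5,000
analysis in minutes on one CPU, while the full-scale values (200 × 25)
remain the estimator defaults.

**Selection and description.** The k range [2, 20] is scored by the WCSS
elbow, the Calinski–Harabasz index and the centroid-based simplified
silhouette (a_i = distance to own centroid, b_i = minimum distance to
another centroid, s_i = (b_i − a_i)/max(a_i, b_i), s_i := 0 when both are
zero). All indices are computed in the weighted space, consistent with the
WCSS they accompany. The package reports curves and per-index argmaxes but
does not auto-pick k: the cluster count is a judgment combining statistics,
model simplicity and clinical interpretability. Sociodemographics never
enter the clustering; they are used only to describe the clusters found.

## Profiling conventions

- O/E ratios are computed from unrounded prevalences; printed-table
  reproduction uses round-half-up to two decimals. Recomputing O/E from
  *rounded* prevalences can differ in the last digit — unrounded-first is
  the only self-consistent rule. A condition with zero overall prevalence
  gets a NaN O/E sentinel.
- Portfolios use exact-set semantics: a person with {A, B, C} counts toward
  the {A, B, C} portfolio only, never toward {A, B}. In the
  risk-factor-excluded variant (hypertension, high cholesterol, obesity
  dropped) cardinality is recomputed after exclusion, so a person can fall
  below two conditions and then contributes to no portfolio. Percentages
  use the cluster size as denominator (this reproduces published worked
  values, e.g. 211/5,035 ≈ 4.19%). Ranking ties break by count descending,
  then alphabetically by the sorted condition names.
- Sociodemographic lowest/highest annotations flag the clusters with the
  extreme percentage per category row; ties resolve to the lower cluster
  label. A mean-age row appears only when a numeric `age` column is
  present; the standard schema carries age bands.

## Sensitivity analysis

The design is rebuilt at 0.5·w and 2·w, the full protocol reruns at the same
k with a fresh counter-derived substream (published analyses do not state
whether seeds were shared between weight settings; independent substreams
are the conservative choice), and the perturbed solution is matched to the
base solution by maximum-overlap optimal assignment
(`scipy.optimize.linear_sum_assignment` on the k×k contingency matrix) —
maximizing the diagonal is the only matching rule consistent with reporting
diagonal agreement. Reported per factor: the matched confusion matrix (rows
sum to base cluster sizes, columns to perturbed ones) and the diagonal
agreement fraction. The range [0.5·w, 2·w] probes robustness of one chosen
weighting; it is not a weight-optimization device.

## Synthetic cohorts: what they emulate, and what they do not

The generator draws, per person: a cluster from the mixing proportions;
conditions as independent Bernoulli variables at the cluster's prevalences;
utilization as negative binomial counts (mean/dispersion parameterization,
variance m + m²/θ) — registry utilization is strongly overdispersed (bed-day
means range from 0.14 to 29.5 across published clusters, implying heavy
tails), so Poisson would be unrealistic; and sociodemographics from
per-cluster categorical distributions. The multimorbidity constraint
(≥ 2 conditions) is enforced by redrawing the *condition vector only*, which
preserves mixing proportions and utilization laws exactly but biases
condition marginals slightly upward in low-prevalence clusters.

Two presets:

- `paper_like_spec()` — mixing proportions from the published cluster sizes
  (24,017 / 5,035 / 918,901 / 236,381 of 1,184,334) and condition
  prevalences, utilization means and sociodemographic distributions from
  the published per-cluster tables. Dispersions are not published; bed days
  and hospitalizations use θ = 0.5 (heaviest tails), other variables 1.0 —
  a package choice, flagged in the preset metadata.
- `well_separated_spec()` — the positive control for planted-recovery
  testing: four clusters with disjoint signature-condition blocks at 90%
  prevalence over a 3% background (any two clusters differ by 0.87 in
  prevalence on ≥ 16 conditions), published utilization scales with tight
  dispersion (θ = 20), and moderated mixing (10/8/52/30%). The published
  mixing is *not* used here deliberately: with a 0.4% cluster (~20 people
  at n = 5,000), merging it changes between-cluster variance negligibly,
  so no variance-ratio criterion can prefer k = 4 regardless of separation
  strength. The moderated mixing preserves the published ordering (one
  dominant low-utilization cluster, one small mental-health cluster) while
  keeping the four-group structure statistically identifiable.

Within-cluster conditions are independent: real comorbidity has residual
dependence (e.g. among cardiovascular diagnoses) that no public marginal
table pins down. Passing planted-recovery tests therefore shows the
pipeline recovers mixture structure expressed through marginals and
utilization levels; it does not certify behavior under strong within-cluster
condition correlation, longitudinal drift, or informative missingness —
none of which the generator models.

## Numerical choices and degenerate inputs

- WCSS-recurrence equality: relative 1e-10; result invariants (centroids =
  within-cluster means, WCSS consistency) verified at 1e-8 in tests.
- Calinski–Harabasz returns +inf when WCSS = 0 (coincident points) and
  rejects k = 1 and k = n.
- `best_of_starts` resamples up to 100 times if sampled initial centroids
  coincide as points, then raises; data with fewer than k distinct rows is
  an initialization error.
- Cohort CSVs round-trip exactly: integer-valued utilization is written and
  re-read as integers. Missing sociodemographic cells map to "unknown"
  (mirroring the unknown categories used for employment/education in
  registry practice); missing condition or utilization cells are errors.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run at desk scale, chosen so the
full suite completes in seconds-to-minutes on one CPU: planted recovery and
k-selection at n = 5,000 with 8 runs × 4 starts over k ∈ [2, 8]; oracle
equivalence on 50 instances with n ≤ 10 (exhaustive partition enumeration);
the balancing property with 10⁵ Monte-Carlo pairs; weight sensitivity at
n = 300. The published full-scale analysis (n ≈ 1.18 M, k ∈ [2, 20],
200 × 25 protocol) is out of desk scope but reachable with the same code by
raising the protocol parameters.

## Known limitations

- The Hartigan–Wong implementation runs optimal-transfer passes to
  convergence; the classical quick-transfer bookkeeping (a pure speed
  optimization) is not implemented.
- No mini-batch or approximate path; n ≈ 10⁶ × 40 columns is feasible but
  slow on one core.
- No statistical testing of between-cluster differences, no automated elbow
  detection, no alternative clusterers (density-based, fuzzy, latent-class)
  — deliberately out of scope.
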