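# mmclust

Weighted k-means segmentation of multimorbidity cohorts.

People living with two or more chronic conditions are a large, heterogeneous
group: the same pair of diagnoses can come with very different care needs.
Classic multimorbidity clustering groups patients by conditions alone and
only afterwards describes their healthcare use, which lets the most prevalent
conditions dominate and hides resource-intensive subgroups. `mmclust`
implements the alternative: cluster on chronic-condition profiles **and**
healthcare-utilization patterns jointly, with the two variable blocks
balanced so neither dominates, then describe the resulting clusters with the
sociodemographic variables that were deliberately kept out of the clustering.

It is aimed at epidemiologists and health-services researchers working with
registry extracts (one row per person: 33 binary condition indicators, 7
yearly utilization counts, sociodemographics). Because such registry
microdata cannot be shared, the package ships a synthetic cohort generator
that emulates the published per-cluster structure, so the whole pipeline is
testable end to end without data access.

## Method

For person *i* let x_i ∈ {0,1}^33 be the condition indicators and
u_i ∈ ℕ^7 the utilization counts. All 40 variables are standardized to zero
mean and unit variance (sample SD); the standardized utilization block is
then multiplied by the domain-balancing weight

    w = √(p_c / p_u) = √(33 / 7) ≈ 2.171,

so that under independent standardized columns both blocks contribute equally
in expectation to squared pairwise Euclidean distances. In this weighted
space, k-means (Hartigan–Wong algorithm: single-point transfers accepted when
the size-adjusted insertion cost n_t·d²(x,c_t)/(n_t+1) is below the removal
gain n_s·d²(x,c_s)/(n_s−1), with live centroid updates) minimizes the
within-cluster sum of squares (WCSS). Solution stability is handled by a
two-level protocol: each *run* keeps the best of 25 random-observation
initializations; 200 runs are executed, and if the minimum WCSS recurs in
more than 10 runs that solution is accepted, otherwise 100 further runs are
added. The number of clusters is explored over k ∈ [2, 20] with the WCSS
elbow, the Calinski–Harabasz index (BCSS/(k−1))/(WCSS/(n−k)), and a
centroid-based simplified silhouette s_i = (b_i − a_i)/max(a_i, b_i).

Clusters are profiled with observed/expected prevalence ratios
(O/E = cluster prevalence / population prevalence), exact chronic-condition
portfolios ("exactly these m conditions and no others", with and without the
three risk-factor conditions hypertension, high cholesterol and obesity),
utilization means, and sociodemographic distributions. Robustness to the
weight choice is checked by re-clustering at 0.5·w and 2·w and reporting
Hungarian-matched confusion matrices and diagonal agreement.

## Worked example

```python
import numpy as np
import mmclust as mm

spec = mm.paper_like_spec(n=20_000, seed=1)     # preset from published tables
cohort, _ = mm.generate_cohort(spec)
design = mm.build_design(cohort)                # standardize + weight
print("balancing weight w =", round(design.weight, 4))

model = mm.WeightedKMeans(n_clusters=4, n_runs=20, n_starts=5,
                          extension_runs=20, random_state=7).fit(design)
profiles = mm.cluster_profiles(cohort, model.labels_)
print(profiles.summary())

table = profiles.prevalence
g = int(np.argmax(table.oe.loc["depression"]))
print("depression: overall {:.1%}, cluster {} {:.1%}, O/E {:.2f} (+{:.0f}%)".format(
    table.overall["depression"], g,
    table.prevalence.loc["depression"].iloc[g],
    table.oe.loc["depression"].iloc[g],
    table.pct_increase.loc["depression"].iloc[g]))
```

prints

```
balancing weight w = 2.1712
Cluster sizes:
  cluster 0: 2521 (12.61%)
  cluster 1: 187 (0.94%)
  cluster 2: 17256 (86.28%)
  cluster 3: 36 (0.18%)
Mean conditions per cluster:
  0: 4.03
  1: 4.55
  2: 3.48
  3: 3.47
  all: 3.56
depression: overall 22.8%, cluster 3 77.8%, O/E 3.41 (+241%)
```

The weight is √(33/7); the dominant low-utilization cluster and a small,
depression-heavy cluster with O/E ≈ 3.4 mirror the qualitative structure of
registry cohorts: cluster 3's members show depression 3.4 times as often as
the multimorbid population overall. With the desk-scale protocol shown here
(20 runs × 5 starts on overlapping simulated clusters) the minimum WCSS does
not recur, so the protocol automatically runs its extension block — visible
in `model.protocol_report_`.

The same stages are available from the shell:

```bash
mmclust simulate --generator paper_like --n 20000 --seed 1 --out cohort.csv
mmclust select-k cohort.csv --k-min 2 --k-max 8 --runs 20 --starts 5 --out curve.csv
mmclust cluster cohort.csv --k 4 --runs 20 --starts 5 --seed 7 --out assignments.csv
mmclust profile cohort.csv assignments.csv --outdir profiles/
mmclust sensitivity cohort.csv --k 4 --factors 0.5,2.0 --outdir sens/
mmclust full-run config.yaml        # everything, as one reproducible bundle
```

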