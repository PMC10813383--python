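# glycoda

Compositional analysis of serum *N*-glycome chromatographic profiles.

Serum *N*-glycans measured by HILIC-UPLC arrive as 46 integrated peak
areas (GP1..GP46), each expressed as a percent of the total area. The
profile is therefore *compositional*: the 46 values sum to 100% and
carry only relative information, so ordinary multivariate statistics
applied to the raw percentages are invalid. `glycoda` implements the
full analysis pipeline for such data:

- **Derived traits** — the 17 structural traits (galactosylation
  G0–G4, sialylation S0–S4, branching A1–A4, core and outer-arm
  fucosylation CF/OF, oligomannose OM) as weighted peak sums, with
  exact fractional weights for co-eluting peaks.
- **Log-ratio algebra** — closure, multiplicative zero replacement,
  clr, and pivot isometric log-ratio (ilr) coordinates
  `z_i = sqrt((D-i)/(D-i+1)) · ln(x_i / g(x_{i+1..D}))`, with exact
  inverses, so standard statistics can run in unconstrained space.
- **Group comparison** — a permutation-calibrated max-type two-sample
  test on clr means for "do two groups share an *N*-glycome?",
  coordinate-wise Mann–Whitney follow-up with Benjamini–Hochberg
  correction, Kruskal–Wallis and chi-square helpers.
- **Age trends** — per-sex penalized B-spline smooths (second-order
  difference penalty, GCV) of each ilr coordinate, back-transformed to
  the percent scale with Monte-Carlo 95% bands; beta-response smooths
  for bounded traits; age windows of significant sex differences.
- **Clustering** — robust PCA (FAST-MCD scatter), k-means on the full
  ilr coordinates with elbow selection of k, cluster phenotyping
  tables, and age/sex-adjusted cluster effect models (OLS and
  logistic).
- **Synthetic cohorts** — a generator that emulates the statistical
  structure of a population *N*-glycome study (two latent clusters,
  smooth sex-specific age trends, rank-2 factor covariance, covariates
  linked to cluster membership) with full ground truth, so every stage
  of the pipeline has recoverable truth to test against.

## Worked example

```python
import numpy as np
from glycoda import (GeneratorConfig, generate_cohort, ilr, GP_COLUMNS,
                     robust_pca, choose_k_elbow, adjusted_outcome_models)
from sklearn.metrics import adjusted_rand_score

sim = generate_cohort(GeneratorConfig(seed=1))       # 1516 subjects
z = ilr(sim.cohort_table[GP_COLUMNS].to_numpy())

pca = robust_pca(z, h_fraction=0.75, k_components=2, seed=1)
print(f"top-2 robust PCA variance share: {100*pca.explained_fraction[:2].sum():.1f}%")

res = choose_k_elbow(z, k_max=8, seed=1)
print(f"elbow-selected k: {res.chosen_k}; cluster sizes: {np.bincount(res.labels)[1:].tolist()}")
print(f"ARI vs generator truth: {adjusted_rand_score(sim.true_labels, res.labels):.2f}")

adj = adjusted_outcome_models(sim.cohort_table, res.labels).set_index("outcome")
fru = adj.loc["fructosamine"]
print(f"fructosamine shift (cluster 1, age/sex-adjusted): "
      f"{fru['estimate']:.1f} (95% CI {fru['ci_low']:.1f}-{fru['ci_high']:.1f}) umol/L")
```

prints

```
top-2 robust PCA variance share: 62.8%
elbow-selected k: 2; cluster sizes: [488, 1028]
ARI vs generator truth: 1.00
fructosamine shift (cluster 1, age/sex-adjusted): 13.3 (95% CI 11.0-15.7) umol/L
```

The two principal components carry most of the ilr-space variance
(the generator's rank-2 factor structure), the elbow rule lands on two
clusters which match the generated phenotypes exactly, and the adjusted
linear model recovers the injected +14.1 μmol/L fructosamine shift of
the simple-glycan-rich cluster within its confidence interval.

The same stages are available from the shell:

```bash
glycoda simulate --n 1516 --seed 1 --out cohort.csv
glycoda traits cohort.csv --out traits.tsv
glycoda test cohort.csv --by sex --n-perm 999
glycoda cluster cohort.csv --out labelled.csv
glycoda report --seed 1 --outdir run/
```

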