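# Methods

## The compositional view of the serum N-glycome

A HILIC-UPLC serum *N*-glycome profile is 46 peak areas closed to
100%. All inference in `glycoda` runs on log-ratio coordinates: the
pivot ilr basis ordered by chromatographic peak number GP1..GP46.
Coordinate `i` contrasts peak `i` against the geometric mean of all
later-eluting peaks, so the early coordinates read as "simple glycans
versus the rest" — convenient, because the biology of interest
(agalactosylated, asialylated, mono/biantennary structures) elutes
first. Pivot coordinates are basis-dependent: per-coordinate test
results are statements about this basis, not about single peaks in a
basis-free sense. The global max-type test, PCA eigenvalues, k-means
geometry and Aitchison distances are all invariant to the choice of
orthonormal ilr basis; only coordinate-wise summaries are not.

Zeros are handled by multiplicative replacement: a zero in peak column
`j` becomes half the smallest positive value observed in that column,
the remaining entries of the row shrink proportionally, and the row is
re-closed. This preserves ratios among unaffected parts. A column with
no positive value is an instrument/integration failure and is rejected.

## Derived traits

The 17 traits are fixed weighted sums over peaks, with weights 1, 1/2
or 1/3 where a peak contains co-eluting structures, stored as exact
rationals. Three families partition total abundance (sialylation;
galactosylation + oligomannose; branching + oligomannose), which the
test suite verifies per peak. The trigalactosylated and triantennary
traits (and the tetra- pair) are defined on identical peak sets and are
therefore identical functions — a deliberate property of the trait
definitions, preserved bit-exactly. Traits are computed on the closed
percentages and not re-closed per family, so complements stay additive.

## Synthetic cohort generator

No public cohort of this kind exists, so the generator is the package's
test bed: it produces cohorts with the statistical structure the
analysis assumes, with ground truth exposed.

- **Demographics**: sex ~ Bernoulli(0.553 female), age ~ Uniform(18, 91)
  years. The uniform shape is the simplest density spanning the target
  range; real cohorts are age-stratified samples, so this is adequate.
- **Latent clusters**: membership in the simple-glycan-rich cluster 1
  follows a logistic model in age, base log-odds log(431/1085) at the
  reference age 52 and +0.3 per decade, reproducing both the ~28%
  base prevalence and the older age of cluster 1.
- **Composition**: ilr mean = baseline + cluster offset + smooth
  sex-specific age trend + rank-2 factor term; observed ilr adds
  isotropic noise (sd 0.25); the composition is the inverse ilr, so
  closure is automatic. The baseline is a fixed realistic profile with
  mass concentrated in disialylated digalactosylated biantennary peaks
  (implied traits near published population medians). The cluster
  offset is a clr contrast raising GP1–GP11, scaled so those peaks are
  about 3x more abundant in cluster 1 — the same order as published
  cluster contrasts in simple traits — and large enough relative to
  the factor variance that the true partition is the best 2-means
  split. Factor loadings are two smooth orthogonal patterns with norms
  2.0 and 1.6, orthogonalised against the cluster offset; together
  with the noise floor this yields a top-2 variance share near 65%,
  the "two components dominate" regime.
- **Age trends**: per-coordinate half-period sine plus linear-in-age
  terms with amplitudes ≤ 0.15 log-ratio units; the last six
  coordinates get a female-specific slope and baseline offset,
  mirroring the concentration of sex differences in higher-order
  glycans. Constants live in `default_age_trends()` and give the trend
  module recoverable truth.
- **Covariates**: linear-plus-Gaussian links on cluster and age with
  documented constants (fructosamine baseline 251, cluster shift
  +14.1 μmol/L; glycated albumin +0.58%; AST +0.96 IU/L; GGT +5.34
  IU/L; glomerular filtration −3.26 mL/min; T3 and TNF-alpha small
  shifts). The comorbidity count uses a hurdle construction: the
  two-or-more indicator is drawn from a logistic model with cluster
  log-odds ln(1.53) around an 8.2% baseline prevalence, then expanded
  to a count. A Poisson count with a log-*rate* cluster effect was
  rejected: for a rare count the implied odds ratio of the ≥2
  indicator is roughly the squared rate ratio, so it cannot represent
  an odds-ratio-scale effect faithfully; the hurdle makes the printed
  odds ratio the exact ground truth the adjusted logistic model
  estimates.
- **Reproducibility**: every variable block draws from its own
  substream (`SeedSequence(seed, spawn_key=(block,))`), so adding a
  covariate never perturbs earlier draws, and equal configs give
  byte-identical tables.

What the generator does *not* emulate: measurement batch effects,
heavy-tailed or skewed peak noise, missing covariate patterns,
age-dependent noise, and any dependence between the factor scores and
demographics. Passing tests therefore demonstrate correctness of the
machinery under a clean logistic-normal data-generating process, not
robustness to instrument artefacts.

## Group comparison

The global two-sample test uses the max over clr columns of the squared
standardised mean difference, calibrated by random relabelling
(permutation p-value `(1 + #{M* >= M})/(n_perm + 1)`). A max-type
statistic with permutation calibration keeps finite-sample validity at
a few hundred subjects per group, where asymptotic extreme-value
calibrations of high-dimensional mean tests are unreliable; the
statistic's form is the standard high-dimensional compositional
two-sample statistic. Columns with zero variance in both groups are
skipped with a warning. Per-coordinate follow-up uses Mann–Whitney
(exact enumeration when n1+n2 ≤ 12 without ties, tie-corrected normal
approximation with continuity correction otherwise) and
Benjamini–Hochberg step-up correction across the 45 coordinates. All
tests are two-sided at α = 0.05.

## Age-trend smoothing

Each ilr coordinate is smoothed against age separately per sex — a
"factor per curve" design rather than a shared smooth plus
interaction — with cubic B-splines on uniformly extended knots
(Eilers–Marx construction; 10 basis functions by default), a
second-order difference penalty, and λ selected by GCV over a 21-point
log grid spanning 1e-4..1e6. The uniform extended knots matter: they
keep straight lines exactly in the penalty null space, so heavy
smoothing degenerates to the least-squares line, never to an artefact.

Coefficient uncertainty uses the Bayesian posterior covariance
σ²(BᵀB+λP)⁻¹. Its pointwise intervals absorb the smoothing bias on
average across the function and are the standard choice for penalized
regression bands; the frequentist sandwich form systematically
under-covers where the penalty biases the fit, which we confirmed in
coverage simulations before settling on the Bayesian form.

Percent-scale curves and bands come from Monte-Carlo propagation: draw
coefficients per coordinate from N(β̂, cov), evaluate on the age grid,
apply the inverse ilr per draw, and take pointwise 2.5/97.5 percentiles
per peak (default 1000 draws, seeded). The mean curve is the inverse
ilr of the coordinate-wise means, so the 46 mean curves close to 100%
exactly at every age. A delta method was rejected: the inverse ilr is
strongly nonlinear near small parts, exactly where the interesting
peaks live.

Bounded traits (CF, OF, OM as fractions of total area) are smoothed
with a beta likelihood, logit-linked mean and constant precision φ, by
penalized Fisher scoring; φ is updated by moments each cycle and λ
chosen by GCV on the working model. Precision is held constant in age
because nothing in the data demanded a dispersion model. Boundary
responses are nudged inward by 1e-6 with a warning.

Sex-difference windows are maximal age runs where the pointwise 95%
interval of the male−female difference (on the link/ilr scale, variance
summed across the two independent fits) excludes zero. These are
pointwise, not simultaneous, intervals: under identical trends about
5% of the grid will be flagged by construction.

## Robust PCA, clustering, phenotyping

Robust location/scatter come from FAST-MCD with subset fraction
h = 0.75 and the usual consistency correction plus chi-square(0.975)
reweighting (via scikit-learn's `MinCovDet`); `h_fraction = 1` and
cohorts under 100 subjects use the classical covariance (the latter
with a loud warning). Eigenvalues of the scatter give the explained
fractions; ilr loadings are mapped to 46-part clr loadings through the
basis matrix for interpretation.

K-means runs on the full 45-dimensional ilr coordinates (Euclidean
there = Aitchison metric), k-means++ with 25 restarts, best of the
restarts by within-cluster sum of squares. PCA is a variance summary
and plotting device, not a pre-reduction step. Label 1 is always the
cluster whose back-transformed centroid holds the most GP1–GP11 mass,
making labels stable across seeds and runs.

The elbow rule is made algorithmic: k maximising the normalised second
difference (WSS_{k-1} − 2·WSS_k + WSS_{k+1})/WSS_1 over k = 2..k_max−1,
with a "no clear elbow" flag when the maximum falls below 0.01 (the
WSS decline is then near-linear and no k is defensible).

Phenotyping reports medians and IQRs per cluster for all 17 traits,
testing each on a comparison scale appropriate to its nature: clr
within its compositional family for the galactosylation, sialylation
and branching traits, logit for the bounded fucosylation and
oligomannose traits; covariates use Mann–Whitney or chi-square; all
p-values BH-corrected within their table. Adjusted cluster effects use
OLS (continuous outcomes) or logistic regression (binary outcomes,
e.g. carrying ≥2 comorbidities) on cluster + age + sex with Wald 95%
intervals; a |coefficient| above 15 on the logit scale is treated as
separation and the interval suppressed.

## Problem sizes and numerical choices

Closure and round-trip tolerances are 1e-9. The test suite exercises
the full default cohort (n = 1516) once for the structural checks
(elbow k = 2, ARI ≥ 0.8, top-2 variance > 50%, effect recovery), and
uses scaled designs elsewhere: 200 null replicates at 100 subjects per
group for the type-I error of the permutation test (99 permutations
each), 100 replicates at n = 400 for trend-band coverage (300
Monte-Carlo draws, 20-point age grid), and a 50-seed sweep at n = 500
for confidence-interval coverage of the injected fructosamine and
comorbidity effects. These sizes give Monte-Carlo error comfortably
below the margins being tested while keeping the suite quick to run.

## Known limitations

- Pivot-basis dependence of per-coordinate results (see above).
- The generator's qualitative defaults (trend amplitudes, factor
  loadings, covariate noise scales) are choices where no published
  variance information exists; they satisfy the documented qualitative
  structure, nothing stronger.
- GCV can undersmooth at small n; no REML option is provided.
- Sex-difference windows use pointwise bands; simultaneous bands would
  be wider.
- The beta smooth's GCV acts on the working model, an approximation to
  a marginal-likelihood criterion.
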