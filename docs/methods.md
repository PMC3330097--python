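# Methods

`fieldexpr` re-implements, as a tested pipeline over synthetic data, the
statistical workflow used to analyse genome-wide time-series expression of
two plant accessions grown outdoors: detection census, variance
partitioning, time-course significance screens, silhouette-guided
clustering with environmental attribution and stress-set enrichment,
vegetative-stage PCA regressed on weather and development, and
template-based co-regulation search.

## The synthetic experiment

The generator (`synthgen`) emulates the study design rather than any one
dataset. Two accessions are transplanted to a field plot and the whole
shoot is sampled every 3 days from day 18 after germination: 6 vegetative +
2 flowering timepoints for the earlier-bolting accession (bolting day 34)
and 8 + 2 for the later one (bolting day 40), three replicate arrays per
sample with one late replicate of the second accession dropped — 53 arrays
over 18 samples. Daily weather is AR(1) temperature (stationary means
8.7 °C minimum, 23.7 °C maximum, sd 2.5 °C, lag-1 correlation 0.5, the
tmax−tmin spread floored at 0.5 °C) with rain on a Bernoulli 8/30 fraction
of days, uniform 2.5–31.8 mm. Rosette leaf number and diameter grow
linearly with age plus replicate noise.

Per-gene log2 expression is additive:

    y[g,s] = mu_g + a_g·I[accession] + f_g·I[flowering]
             + cT_g·z_tmax(day) + cP_g·z_ppt(day)
             + sqrt(v_clust)·tau_k(g)(day) + eps,  eps ~ N(0, v_resid)

Indicator and covariate columns are standardized over the realized design
and coefficients are scaled so each term contributes exactly its configured
fraction of per-gene variance; signs are independent across genes and
terms so cross-covariances cancel on average. Cluster templates tau_k are
orthonormalized random rotations of a natural-cubic-spline basis of day —
smooth, mutually orthogonal, unit variance — shared by all members of a
cluster. Null genes carry no effects at all.

Default variance fractions are accession 0.30, flowering 0.30, environment
0.10 (split evenly between tmax and precipitation), cluster 0.10, residual
0.20, with 30% null genes. They plant the qualitative structure the
analysis expects — accession and flowering status roughly equal and
dominant, precipitation the leading environmental factor — at magnitudes
where recovery is non-trivial. Baseline means are bimodal (N(9.5, 2.5²)
for expressed genes, N(4, 0.8²) for the 33% never-expressed fraction);
with residual variance 0.2 this yields inter-replicate correlations of
≈0.98 across genes, matching good-quality array replication.

Detection flags derive from each gene's baseline mu_g exceeding the
background quantile of baselines (the never-expressed fraction), then flip
independently per array at a 1% noise rate. Thresholding the baseline
rather than the noisy per-array value keeps planted presence exact at zero
flip rate and makes the flagged fraction strictly monotone in the
background quantile; the flip rate models per-array call noise.

What the generator does **not** emulate: probe-level effects and
single-feature polymorphisms, spatial plot heterogeneity, nonlinear or
interactive environmental responses, and heavier-than-Gaussian replicate
noise. Passing recovery tests therefore demonstrates correctness of the
estimators under the planted model, not robustness to those features of
real arrays.

## Detection census

A gene is expressed at a timepoint iff called present on **all available**
replicates of that (accession, day) group — the all-replicates rule,
generalized to "all available" when a replicate is lost. The census exposes
per-timepoint sets, per-accession unions and the overall union, because
"expressed" can reasonably mean either granularity; Venn region counts are
computed by direct set partition.

## PVCA

PCA is computed by SVD of the gene-centered matrix (no scaling by default:
the data are already on log2 scale). For each retained component
(eigenvalue share ≥ 1e-6; configurable cap), a variance-components model
with *all* factors random and a fixed intercept is fitted to the score
vector. Continuous covariates enter as tertile-binned categorical random
effects (bin count configurable); semi-continuous covariates whose
quantile bins collapse (precipitation: mostly dry days) fall back to a
low/high split, covariates constant in a stratum are reported as zero with
a warning, and binned covariates that collide into an identical sample
partition (the two temperature series occasionally do) are dropped as
aliased with a warning rather than crashing the factor-confounding check.

Two estimation backends:

* **ANOVA method-of-moments (Henderson III).** Sequential projection
  quadratic forms y'(P_j − P_{j−1})y are equated to their expectations,
  which are linear in the variance components (coefficients are traces
  tr(A·Z_f Z_f')); the linear system is solved and negative estimates
  truncated at zero. On balanced one-way layouts this reduces exactly to
  the textbook expected-mean-squares estimator (tested to 1e-6).
* **REML** by L-BFGS-B minimization of the restricted negative
  log-likelihood over bounded component values, started from the
  method-of-moments estimate.

`method="auto"` uses method-of-moments on balanced designs and REML
otherwise. Per-component estimates are converted to proportions and
averaged with eigenvalue weights (`weighting="per_pc"`, the standard PVCA
normalization); the alternative `"pooled"` normalization — eigenvalue-
weighted component sums divided by the weighted total — is exposed but not
default, because its quadratic eigenvalue dependence crushes the residual
share and fails planted-fraction recovery.

## Time-course testing

`anova_per_gene` fits the fixed-effects factorial model per gene with
sequential (type-I) sums of squares in model order, vectorized across
genes via one thin QR per model term; it matches `statsmodels.anova_lm`
term by term. Zero-variance genes get F = 0, p = 1 so row counts are
preserved. `bh_fdr` implements the Benjamini–Hochberg step-up exactly
(tested against a brute-force implementation of the definition).

The spline test compares a natural cubic spline of day (df = 3 by default,
knots at quantiles of the distinct days; the basis is the standard
truncated-power construction with linearity constraints outside the
boundary knots) to an intercept-only fit, with
F = ((RSS0 − RSS1)/df)/(RSS1/(n − df − 1)). Significance comes from
permuting the sample→day assignment; permutations are shared across genes
(each gene's p-value is exactly valid by exchangeability, and p-values are
conditionally — hence jointly — independent under the null), with
p = (1 + #{F_perm ≥ F_obs})/(n_perm + 1), resolution 1/(n_perm + 1).

Permutation counts are a resolution question, fixed a priori: a q ≤ α
screen needs the floor p-value 1/(n_perm+1) to be well below α times the
fraction of genes at the floor. The pipeline uses 499 permutations for the
q < 0.01 full-course screen and 1,999 for the q < 0.05 vegetative-stage
screen; the type-I calibration suite uses 199, where only the rejection
rate matters.

## Clustering and enrichment

The clustering substrate is each gene's replicate-mean expression per
(accession, day), standardized per gene, so Euclidean distance is
equivalent (up to scale) to correlation distance — bridging the
correlation-threshold and silhouette framings of cluster definition.
K-means (best of 10 restarts) partitions the profiles; silhouette widths
s(i) = (b−a)/max(a,b) are computed from the full pairwise distance matrix,
with members of singleton clusters assigned 0. The cluster-number rule
scans K upward and selects the smallest K whose worst-cluster mean
silhouette is ≤ 0 there **and** for the next `persistence_window` (default
3) values of K; if it never fires by K_max, K_max is returned with a
warning — on strongly-templated synthetic data the rule legitimately never
fires, and the per-K diagnostics table lets users apply either the "K
where it fires" or "last K before" reading.

Per-cluster attribution re-runs the environmental PVCA on each cluster's
member submatrix (clusters under 5 genes skipped and flagged) and reports
each proportion in the four display bins <25%, 25–50%, 50–75%, >75%.
Enrichment of every cluster × gene-set pair uses the upper-tail
hypergeometric probability with the set intersected against the universe
(default background: the clustered genes — the conservative choice; the
whole array is an option), BH-corrected across all pairs at q ≤ 0.05 by
default with the raw p ≤ 0.01 mode available. With a set→{abiotic,biotic}
map, per-cluster enrichment is summarized as both / abiotic-only /
biotic-only counts.

## Vegetative-stage PCA, regression, templates

The vegetative submatrix keeps pre-bolting samples and the intersection of
the per-accession q < 0.05 vegetative time-course screens. Each of the
first five PC score vectors is regressed by OLS on maximum temperature,
precipitation, rosette leaf number, rosette diameter and age; minimum
temperature is excluded from the default model because it tracks maximum
temperature (re-includable by flag). VIF_j = 1/(1 − R²_j) flags
collinearity at ≥ 10 (optionally dropping flagged covariates); BH
correction runs across all covariate p-values of the tested axes. Rows
with missing phenotypes are dropped and counted.

Extreme-loading gene lists take ceil(α·n) genes per tail of the loading
distribution (α = 2.5% per tail; n = 8,954 gives 224 + 224 = 448 — the
normative rounding), ties broken by stable rank. Template matching
computes signed Pearson correlations between per-(accession, day) mean
profiles and the template gene's profile and keeps |r| ≥ threshold;
anti-correlated genes match. The threshold is interpreted on the r scale
by default (0.7 is the conventional choice) or converted from an
r-squared when flagged (0.47 → |r| ≥ 0.6856), since co-regulation
thresholds are quoted on both scales; the mode is recorded with the run.
Gene–PC correlations use per-sample values; template matching uses mean
profiles, which equal least-squares means in balanced groups.

## Pipeline and problem sizes

`run_pipeline` executes eight stages (simulate, census, pvca, diffexpr,
cluster, enrich, vegpca, template) from one YAML config into a shared run
directory of plain TSV artifacts, writing a JSON run report with the
config echo, seed registry, per-stage counts, timings and captured
warnings. All randomness flows from the seeded generator, so a rerun with
the same config and seed reproduces every table.

Analyses and the acceptance script run at desk scale — 2,000 genes, the
53-array design, 199–1,999 permutations, K scans to 12–15 — sizes chosen
so every stage completes in seconds while estimator behaviour (recovery
bias, calibration) is already stable. One consequence worth knowing: with
the default planted fractions, the vegetative-stage screen is
underpowered (each accession recovers only a modest, partially
overlapping subset of the truly time-varying genes), so the vegetative
PCA substrate in the demonstration scripts is small. The vegpca machinery
itself is validated in the tests on planted configurations.

## Known limitations

* Variance-component models support categorical (or binned) random
  factors with a fixed intercept only — no general mixed-model engine,
  no nested/continuous random slopes.
* Gene-wise ANOVA is fixed-effects; randomness enters only in the PVCA
  layer. Whether any gene-wise term should be random is left to the user.
* The spline test's permutation null assumes exchangeability of samples
  across days; strong replicate batch structure would violate it.
* Enrichment treats gene sets as unordered; no directionality
  (up/down-regulation) is used.
* The correlation-threshold clustering variant is exposed only through
  the silhouette diagnostics, not as a separate algorithm.
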