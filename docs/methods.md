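# Methods

This note documents the statistical machinery in `cnfc`, the choices made
where conventions diverge, and what the synthetic validation does and does
not establish.

## Module scoring and the CNFC composite

Expression is first brought onto a comparable scale per platform: CPM
(column totals scaled to 10⁶) and log2(x + 1) for RNA-seq counts, deposited
log-intensities for microarrays (multiple probes per gene collapsed by the
per-sample median), log2(x + 1) for targeted-panel ROI tables. Low-expressed
genes are removed with a strict CPM > 1 in ≥ 2 samples rule before model
fitting; the boundary is strict (a gene sitting exactly at the threshold in
every sample is dropped) and both threshold and sample count are
configurable.

Each gene is then standardized across samples within the dataset (z-score).
The SD uses the sample (n − 1) denominator — the convention of mainstream
statistics stacks; population SD would rescale every score by the same
factor √((n−1)/n) and leave all correlations, contrasts and the composite's
ordering unchanged. Standardization can be stratified by a metadata key
(e.g. within each spatial segment type, or within each FACS fraction) so
samples are compared only to their own stratum. Zero-variance genes are set
to z = 0 rather than dropped: they contribute neutrally, module sizes stay
stable, and the event is logged. A stratum with a single sample is an error,
not a silent NaN.

A module score is the per-sample arithmetic mean of z over the module's
genes mapped into the matrix (set intersection, in matrix row order).
Modules mapping fewer than `min_mapped` genes (default 3 — a mean of fewer
than 3 z-scores is too unstable to interpret) are reported missing.
Cross-species symbol handling is by case transformation only (mouse Title
case vs upper-case conventions); no ortholog database is consulted, so a
rat/human matrix is scored with the mouse symbols' case-mapped equivalents
or a user-supplied panel.

The composite is CNFC = w_E·E + w_T·T − w_I·I with unit weights by default.
Weights are magnitudes: the minus sign on injury/inflammation is fixed in
the formula and negative weights are rejected. Plasticity is always scored
and never composed — developmental consolidation and injury-driven regrowth
both move it, in opposite biological contexts. For validation plots a
median-based raw-scale aggregate (median log2(CPM+1) over module genes) is
available; on the default development simulation the mean- and median-based
composites correlate at r > 0.9, so the choice of aggregator is not
load-bearing.

Stage fold-change summaries average replicates within each stage before the
ratio; ratios are computed on unrounded values and rounded to 2 decimals for
presentation only. A zero baseline flags the ratio undefined.

## The NB-GLM differential-expression engine

Per gene, counts follow a negative-binomial GLM with log link,

    log μ_i = β₀ + β₁·x_i (+ covariates) + offset_i,   Var(y_i) = μ_i + α μ_i²,

with x the 0/1 group indicator and offset the natural log of total counts
per sample. A single common dispersion α is shared across genes (no tagwise
shrinkage): with n = 3 per group there is far too little information to
estimate per-gene dispersions, and a common α keeps the estimator
transparent.

α is estimated by a method-of-moments step: fit the Poisson GLM of the same
design, then

    α_g = max(0, Σ_i ((y_i − μ̂_i)² − μ̂_i) / μ̂_i² / (n − p)),

with p the number of design coefficients; the common α is the median over
genes with defined estimates. The (n − p) denominator is a
degrees-of-freedom correction analogous to the residual variance in OLS.
The estimator is deliberately pluggable (`alpha=` overrides it everywhere);
α = 0 degrades the model exactly to Poisson, which the tests exploit as an
independent oracle route (statsmodels Poisson GLM, agreement to 1e-6).

Coefficients are maximized by Fisher-scoring IRLS with weights
w_i = μ_i/(1 + αμ_i), initialized at β = 0 with the intercept at
log(mean y) − mean offset, converged when max |Δβ| < 1e-10 or 50
iterations. Standard errors come from the inverse expected Fisher
information at the optimum. Complete separation (e.g. a group with all-zero
counts) drives the linear predictor against its clip bound; such fits are
reported missing rather than pseudo-counted — no pseudo-count scheme is
part of the model, and a fabricated finite log2FC would be worse than an
honest NA. The group effect is reported in log2 units (β₁/ln 2); Wald
z = β̂₁/SE refers to the standard normal, with two-sided tail probabilities
computed via the normal log-survival function so that set-level and
gene-level p-values far below double underflow remain representable
(`log10_p` column). BH FDR adjustment (statsmodels step-up) closes the
pipeline; inputs outside [0, 1] are rejected.

## Gene-set statistics

Module movement over a DE table is summarised by (i) the arithmetic mean
log2FC over mapped genes with non-missing estimates, and (ii) a directional
Stouffer combination Z = Σ z_g / √n of the signed Wald z statistics, with a
two-sided log-space p (a one-sided tail is emitted alongside, since
combined-evidence conventions differ). Genes are equally weighted — no
per-gene precision weighting — and duplicates are collapsed. An alternative
transform rebuilding z from each gene's two-sided p and the sign of its
log2FC is provided; it is identical when p derives from the same normal
Wald z and exists for externally produced tables. Cohen's d uses the pooled
(n_a + n_b − 2) SD and is undefined at zero pooled variance.

## Group comparisons

Welch's unequal-variance t with Satterthwaite df for two-group score
contrasts (the statistic is oriented so its sign matches delta = mean(b) −
mean(a)); OLS with intercept for covariate-adjusted contrasts (score ~
group + age), with age as plain numeric days (P32 → 32) — the minimal
encoding when only two ages exist — and rank-deficiency reported with the
offending columns; Pearson r with the t-transform p (n − 2 df) for panel
agreement and benchmarks. All p-values are two-sided. A
signature-vs-module correlation screen scores cell-type marker sets
(neuronal / supporting / immune) with the same mean-z mechanics and flags
|r| above a configurable threshold (default 0.8, report-only): a module
trajectory that tightly tracks a composition signature may reflect changing
cell makeup rather than per-cell state.

## PCA benchmark

Covariance PCA over samples on log2(CPM+1): genes are mean-centered, not
variance-scaled (inputs already share a log scale; correlation PCA is
available by pre-standardizing). The lowest 25% of genes by variance are
dropped first — the filter threshold is a free choice, exposed as a flag,
and the benchmark correlations are insensitive to it on the synthetic data.
Component signs are arbitrary, so PC1 is aligned to correlate non-negatively
with a reference score (the excitability module by convention) and the flip
is recorded. Data-driven module weights are the raw OLS coefficients of PC1
on standardized module scores (all four modules enter the regression;
plasticity's coefficient is reported but excluded from the weighted
composite, whose signs stay fixed at +E +T −I using coefficient
magnitudes). With two samples the single component trivially carries all
variance; this degenerate case is allowed rather than erroring, since it
exercises the conservation invariant.

Note the weight regression is descriptive, not causal: in the development
design the excitability and plasticity trajectories are strongly
anti-correlated, so the regression can split their shared variance
arbitrarily; only the weighted composite's agreement with the unweighted one
is a stable quantity.

## Synthetic data: what it emulates, and what it does not

`simulate_counts` draws gene g, sample i counts from NB(μ = L_i · q_g ·
2^(x_i·lfc_g), α) with log-normal library factors (sdlog 0.3) and log-normal
baseline means; defaults are the study conditions under test: n = 3 per
group, 2000 genes, α = 0.067, a 12-gene excitability module at log2FC −2.6
with smaller plasticity (−0.83) and trophic (−0.58) shifts.
`simulate_development` applies per-module monotone stage effects on the
log2 scale (excitability +0.8/stage, plasticity −0.8/stage,
trophic/metabolic +0.1/stage from a high baseline, injury flat from a low
baseline) across E16/P0/P4/P7 at n = 3 per stage; module genes combine the
built-in 24-gene panel symbols with extra synthetic genes sharing each
trajectory, so full-vs-minimal panel agreement is testable.
`simulate_microarray` draws Gaussian log-intensities (n = 3 vs 4) with
designated trophic genes shifted +2 in one group, optionally emitted at
probe level. One seed governs everything via spawned substreams; identical
seeds give identical matrices.

These generators validate the *machinery*: calibration of the Wald test
under the null at n = 3 + 3, recovery of module-level effects, scoring
algebra, and the benchmark correlations. They do not reproduce features of
real cochlear data — gene–gene correlation beyond module co-regulation,
composition shifts, batch structure, platform-specific mean–variance
quirks — so passing tests demonstrate correctness of the methods, not
biological validity of any particular score on a real cohort.

A note on the method-of-moments estimator at this sample size: with n = 6
and the zero floor, the per-gene MoM α is biased toward zero, so the median
recovered on data generated at α = 0.067 sits near 0.05. This is a property
of the estimator at small n, shared by simple MoM approaches generally; the
common-α median is used for stabilisation, not as an unbiased dispersion
estimate.

## Problem sizes

Default simulations use 2000 genes (300–500 in fast unit tests) and the
design sizes above; the full test suite and the acceptance script each run
in well under a minute on one CPU. All tolerances asserted in tests are
stated inline next to the values they guard.

## Known limitations

- No TMM/upper-quartile normalization: deposited normalized matrices are
  consumed as given.
- No ortholog mapping beyond symbol case; no GO/KEGG enrichment (external
  services); no read-level simulation.
- The DE engine offers no dispersion shrinkage or quasi-likelihood tests;
  it is intentionally the transparent common-dispersion Wald pipeline.
- Missing values are rejected, never imputed.
- Absolute CNFC values are within-dataset standardized scores and must not
  be compared across datasets without harmonised processing.
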