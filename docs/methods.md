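# Methods

This note records the statistical models, default parameters, and
numerical choices behind each module, and the realism and limits of the
synthetic-data generators.

## Receptor status by mixture modeling (`receptor_mixture`)

Each receptor transcript (ESR1, PGR, ERBB2) is modeled marginally on
the log2 scale as a two-component Gaussian mixture,
w·N(μ_neg, σ²_neg) + (1−w)·N(μ_pos, σ²_pos), fit by
expectation-maximization. Numerics and defaults:

- E-step in log space with `logsumexp`; variances floored at 1e-4 to
  prevent component collapse; convergence at |Δ log-likelihood| < 1e-8,
  at most 500 iterations.
- Five starts per fit (one quantile-based, four random perturbations,
  seeded); the best final log-likelihood wins. The log-likelihood
  history of the winning run is retained and is non-decreasing (a
  tested EM invariant).
- Components are relabeled so μ_neg ≤ μ_pos; calls are therefore
  invariant to component ordering within a run.
- A fit is flagged unimodal when the mean gap is below the pooled SD or
  either weight is below 0.05. A unimodal marker yields all-positive
  calls with a warning: with no resolvable low mode, declaring
  negativity would be unsupported, and a false positive receptor call
  only removes a sample from TNBC analysis rather than contaminating it.
- A sample is called negative for a marker when the posterior
  probability of the low component is ≥ 0.5 (configurable), and
  triple-negative when negative for all three markers. When IHC
  annotations are available, `identify_tnbc` supports using the mixture
  alone, intersecting with IHC, or rescuing IHC-negative samples absent
  from the expression calls.

## Centroid subtyping and refinement (`centroid_subtyping`)

Each sample is correlated (Spearman by default; Pearson available) with
each of the six subtype centroids over the intersection of measured
genes and centroid genes. Correlation is computed by ranking once per
sample and per centroid and applying the Pearson formula to ranks,
vectorized over centroids; an error names the first centroid whose gene
overlap falls below `min_overlap` (default 0.5 of its genes).

The six-way call is the highest-correlation subtype; exact ties break
by a fixed order (BL1 > BL2 > IM > M > MSL > LAR) so calls are
deterministic. A sample whose best correlation is below `uns_threshold`
(default 0.1) is unclassified (UNS).

Refinement to the four tumor-intrinsic subtypes: samples called IM or
MSL are reassigned to the argmax over {BL1, BL2, M, LAR} with no
threshold in this branch (the sample demonstrably carries classifiable
signal; the question is only which intrinsic subtype underlies it).
UNS samples are re-examined against the intrinsic centroids with the
threshold applied. The IM and MSL correlations are preserved unchanged
as per-sample immune and stromal descriptor scores.

Centroids can be derived from labeled data as row-standardized
per-label means (≥ 2 samples per label). Because row standardization
subtracts each gene's cohort mean — which carries the
proportion-weighted mixture of all centroids — a derived centroid
estimates the label's deviation from that mixture, not the raw
centroid; the tests validate it against the centered truth.

## Paired compartment analysis (`lcm_paired`)

- Differential expression: paired or Welch t statistics computed
  vectorized over genes with a variance floor of 1e-12 (zero-variance
  genes are flagged), Benjamini-Hochberg q-values, and a pass gate of
  |log2FC| ≥ log2(2) and q < 0.01. Values are log2, so the log2 fold
  change is the (paired) mean difference; no unlogging is performed.
- Overrepresentation: hypergeometric upper tail
  (`hypergeom.sf(k−1, N, K, n)`) per gene set with BH correction across
  sets; differential genes must lie inside the stated universe.
- Concordance: pair-level comparison of tumor and stroma six-way calls,
  reporting concordant and discordant counts and how many discordant
  pairs carry a stromal MSL call.
- Exact Wilcoxon signed-rank: zero differences are dropped (with a
  warning when all are zero), ties receive mid-ranks, and for n ≤ 25
  the null distribution of the positive-rank sum is built by dynamic-
  programming convolution over doubled ranks (doubling makes mid-ranks
  integral), equivalent to enumerating all 2^n sign assignments. The
  two-sided p is min(1, 2·min(P(W ≥ w), P(W ≤ w))). For n one-sided
  differences this gives 2/2^n — e.g. 2/1024 ≈ 0.001953 at n = 10.
  For n > 25 a normal approximation uses the realized-rank variance
  Σr²/4, which is exact under mid-ranking.
- Compartment separation: PCA on samples plus a silhouette score of the
  compartment labels in PC space.

## TIL association (`til_immune`)

TIL percentages are binned as mild < 20 ≤ moderate < 50 ≤ intense
(values outside [0, 100] are rejected). The IM-TIL association reports
the Spearman correlation, per-bin medians of the IM score with a
monotonicity flag, and a Kruskal-Wallis test across bins; constant
scores are flagged degenerate rather than producing an undefined
correlation.

## Clinical statistics (`clinical_stats`)

- Contingency: Pearson chi-square without continuity correction, or the
  exact conditional Fisher test for 2×2 tables (two-sided as the sum of
  table probabilities no larger than the observed); `auto` selects
  Fisher for a 2×2 with any expected cell < 5. Zero-margin rows/columns
  are dropped with a warning.
- Odds ratios are taken against the whole unselected cohort including
  the group itself (the forest-plot convention for neoadjuvant-response
  reporting; the cohort's own OR is exactly 1). A Haldane-Anscombe +0.5
  is applied to all four implied cells when any is zero; CIs are Woolf
  log-scale intervals.
- Binomial CIs (Wilson default, Clopper-Pearson optional) are reported
  on the 0-100 percent scale.
- Survival: Kaplan-Meier fits and multivariate logrank via lifelines;
  medians are the first time the product-limit estimate reaches 0.5.
- Cox proportional hazards on one continuous covariate maximizes the
  Breslow partial likelihood by Newton-Raphson with step-halving, on a
  centered covariate for conditioning; inference is a likelihood-ratio
  test against the null model (χ², 1 df). Requires ≥ 10 events and a
  non-constant covariate. A single-covariate Breslow implementation is
  used (rather than a full regression framework) because the analysis
  needs exactly one continuous score and the closed-form risk-set
  recursions make the estimator easy to verify; the tests cross-check
  the coefficient against lifelines.

## Synthetic cohorts (`synthetic_data`)

All generators are pure functions of (config, seed) via
`numpy.random.default_rng`; identical configs produce byte-identical
outputs.

Structure of a generated cohort:

- Centroids: columns of a QR-orthogonalized Gaussian matrix (pairwise
  correlations well below 0.3 in magnitude). The immune signature loads
  +0.55 on the IM centroid and −0.65 on the M centroid (immune
  infiltration and mesenchymal state are opposite biologies, so
  immune-rich samples show high IM and depressed M correlations); the
  stromal signature loads +0.75 on MSL.
- Expression: signal_sd (1.2) times the sample's intrinsic centroid,
  plus immune and stromal signatures weighted by Beta(2, 8) admixture
  draws times scale 1.5, plus N(0, 1) noise.
- Receptors: rows overridden by latent status using two-component
  Gaussians separated by ~4.5-5 within-component SDs (e.g. ESR1 neg
  N(5.5, 0.8) vs pos N(9.5, 0.8)), the clean bimodality receptor
  transcripts show on log2 microarray scales. TNBC samples (fraction
  0.30) are negative for all three markers; every non-TNBC sample is
  guaranteed at least one positive marker.
- Intrinsic subtypes drawn at proportions BL1/BL2/M/LAR =
  0.36/0.22/0.25/0.17; pCR Bernoulli at subtype rates
  0.41/0.18/0.35/0.29; exponential survival with subtype hazards and
  uniform censoring over a 12-year horizon; clinical covariates (grade,
  stage, nodal status, metastatic sites) drawn at subtype-specific
  probabilities.
- TIL percentages and the immune admixture share a Gaussian copula with
  the Pearson parameter r = 2·sin(π·ρ/6) chosen so the Spearman
  correlation hits the target ρ = 0.67.

Paired LCM pairs share a patient baseline; the stromal profile
additionally receives the MSL centroid signal (scaled by
`stroma_msl_boost`) and an additive log2 shift (`compartment_fc`) on a
recorded set of spiked genes. With both set to zero the compartments
are exchangeable, which the tests use as a differential-expression
null.

Limits: genes are independent given the latent factors (no co-expression
blocks beyond the centroid/signature structure), expression is Gaussian
rather than heavy-tailed, receptor marginals ignore copy-number-driven
skew, survival is exponential (constant hazard), and clinical
covariates are conditionally independent given subtype. The generators
are designed to exercise the estimators' assumptions, not to emulate
any specific platform.

## Pipeline (`pipeline`, `cli`)

A flat YAML config with a single seed; per-stage seeds are derived by
fixed offsets. Stage order is fixed (inputs → receptors → subtype →
clinical); a failure halts the run with a stage-named error. The CLI
maps configuration violations to exit code 2, missing input files to 3,
and stage failures to 1. A `manifest.json` records the package version,
the resolved config, per-stage row counts and timings, and SHA-256
hashes of any ingested input files.
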