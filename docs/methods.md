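# Methods

## The immune-compartment model

`airatio` estimates relative immune infiltration from bulk tumour RNA-seq
by marker-gene averaging: each immune cell type is represented by a small
set of genes expressed predominantly by that cell type, and the cell-type
score is the plain mean of their log2(TPM+1) expression, with no per-gene
standardisation. This is a *relative* abundance model — it assumes marker
expression in the bulk mixture scales with the infiltrating cell fraction
and that the markers are not expressed by the cancer cells. The second
assumption is checked, not taken on faith: the rank-validation module
compares within-sample percentile ranks of the marker genes between
infiltrated tumours and infiltration-free (cell-line style) samples.

The packaged default panel follows the Danaher et al. (2017) immune
cell-type marker table: 14 cell types over 60 genes, with compartments

* adaptive — CD8 T-cells, B-cells, CD45, Cytotoxic cells, T-cells,
  Th1 cells, Treg;
* innate — Dendritic cells, Macrophages, Mast cells, Neutrophils,
  NK cells, NK CD56dim cells;
* excluded — Exhausted CD8, which contributes to the total TIL mean but to
  neither compartment of the ratio.

The panel is a user-replaceable three-column TSV, so the exact gene list
(and whether the 14th cell type enters the TIL mean) is configuration, not
code.

## The A/I ratio

Scores are reverse log-transformed (`2^x − 1`) to the linear scale, then
min–max scaled to [0, 1] per cell type across the scaling scope. The
adaptive score A and innate score I are compartment means of the scaled
values, and the ratio is A/I. Choices worth knowing:

* **Scaling scope** defaults to the whole analysis cohort (one dataset at a
  time); per-cancer-type scaling is available. The extremes are
  data-dependent, so the ratio is cohort-relative by construction; one
  added extreme sample rescales everyone (tested explicitly).
* **Degenerate cell types** (constant across the scope) scale to 0 with a
  warning: a constant column carries no discriminative signal and the
  0/0 alternative is worse.
* **I = 0** yields a *missing* ratio, never an epsilon-inflated infinity;
  an explicit epsilon option exists for users who need completeness.
* **Median splits** label a sample high only when *strictly above* the
  median of its scope (ties low), which makes stratification deterministic.
  The female-median reference split labels males against the female median
  of the same stratum, to ask whether holding males to the female threshold
  removes the gender survival gap.
* **Transform discipline**: the expression transform (linear TPM vs
  log2(TPM+1)) is declared by the caller and never sniffed from data,
  because a misdetected transform silently corrupts the reverse-log step.
  Scoring always converts to log2(TPM+1) first, so the reverse-log step
  always sees log-scale scores.

## Downstream statistics

* Cox proportional hazards via lifelines with Efron tie-handling (the
  least-biased common default), complete-case missing handling, and
  separation/non-convergence returned as a flagged result rather than an
  exception. Age enters linearly in years; stage as ordinal 1–4 with
  substages collapsed to the major stage; gender as an is_male indicator.
* Kaplan–Meier / log-rank on median strata, with an administrative horizon
  (e.g. 15-year OS) implemented as censoring at the horizon.
* Meta-analysis of per-stratum hazard ratios by fixed-effect
  inverse-variance weighting on the log-HR scale (weights 1/SE²);
  DerSimonian–Laird random effects behind a flag for sensitivity analysis.
  The arithmetic is authored here (it is a three-line closed form) and
  cross-checked against statsmodels in the test suite.
* Nested Cox models compared by likelihood-ratio test, χ² with df equal to
  the covariate-count difference; identical models give statistic 0, p = 1.
* Group comparisons by two-sided Wilcoxon rank-sum with tie correction,
  switching to exact enumeration when both groups have ≤ 8 tie-free
  observations; 2×2 response enrichment by Fisher's exact test
  (point-probability two-sided p). Per-cancer-type p-values are reported
  raw, with a Benjamini–Hochberg column available as a clearly-labelled
  extension.
* The below-diagonal fraction counts I > A strictly; A = I is on the
  diagonal, not below it.

All p-values are two-sided except the two contracts that state otherwise
(the tumour-vs-cell-line rank test and nothing else).

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any particular real dataset:

* latent adaptive skew `s ~ Normal(μ_gender, 1)`, with
  `μ_female − μ_male = adaptive_skew_effect` (default +0.5);
* per-cell-type infiltration `f_c = scale · T · exp(0.5·d_c·s + ε)`, where
  `d_c` is +1 for adaptive, −1 for innate, 0 for excluded cell types,
  `T ~ LogNormal(0, 0.5)` is a per-sample total-infiltration multiplier and
  `ε ~ Normal(0, 0.3)` per-cell-type jitter;
* marker-gene TPM = log-normal background + `f_c` × a per-gene amplitude
  (~100 TPM at unit infiltration); non-marker genes are background only,
  drawn from the same per-gene baseline family
  (`LogNormal(meanlog 1.0, sdlog 1.5)` with multiplicative noise sd 0.5) —
  so zero-infiltration "cell-line mode" makes markers statistically
  indistinguishable from background;
* overall survival `~ Exponential(h·exp(beta_ai·(s − mean s)))` with
  `h = 1/1000` per day (median ≈ 2 years) and independent exponential
  censoring at rate 1/3000 per day (≈ 25% censoring); the
  progression-free endpoint shares the truth on a 1.6× accelerated clock;
* ordinal response PD < SD < PR < CR by cumulative logit on `s`
  (slope 1.0, cutpoints −0.4 / 0.7 / 2.2, giving roughly 36% PD, 22% SD,
  26% PR, 15% CR at the default conditions); SD is generated explicitly so
  the response-evaluable filter is exercised.

The exponential baseline (rather than Weibull) keeps closed-form
expectations for test assertions — e.g. the censoring fraction under a
null hazard is exactly `censor_rate / (censor_rate + baseline_hazard)`.
One root seed expands into per-stage substreams (cohort, genes,
expression, outcomes, response), so changing the response model cannot
perturb the expression draws, and a fixed seed reproduces every output
byte-identically.

Reference conditions are n = 1000 samples, half female,
`beta_ai = −0.7`, `adaptive_skew_effect = +0.5`. The background pool
defaults to 2,000 genes: marker percentile ranks depend on the background
*distribution*, not its size, and 2,000 log-normal baselines give a
representative spread. What passing tests on this generator show is that
the pipeline recovers structure of this assumed form; real cohorts add
things the generator deliberately omits — gene–gene correlation,
cancer-type-specific baselines, marker expression by cancer cells,
non-proportional hazards — so agreement here validates the machinery, not
any clinical claim.

## Validation strategy and problem sizes

The test-bed checks every statistical primitive against an independent
reference: a direct-loop reimplementation of the scaling/ratio chain
(agreement to 1e−12 on a 10 × 13 cohort), a sort-based tie-averaging rank
oracle (exact on 1,000 random vectors), exact-rational hypergeometric
enumeration for Fisher (all 2×2 tables with n ≤ 20) and full permutation
enumeration for the exact Wilcoxon (group sizes ≤ 8), closed forms for the
meta-analysis, and the generator's ground truth for end-to-end recovery.
Calibration uses 400 null replicates at n = 300 for the median-split
log-rank type-I error (exact binomial envelope) and 200 replicates for
LRT p-uniformity (KS at α = 0.01); recovery uses 20 seeds at n = 1000, and
the provenance check 20 seeds at n = 50 per arm with a 500-gene
background. These sizes keep the whole suite to a few minutes on one CPU
while leaving the binomial/KS envelopes meaningful.

## Known limitations

* The ratio is undefined for cohorts whose innate compartment is constant
  (all ratios missing) — handled totally, but such a cohort is un-analysable
  by this statistic.
* Cohort-relative scaling means absolute ratio values are not portable
  across datasets; only within-dataset contrasts are meaningful.
* Marker panels are trusted as given; no expression-based panel QC beyond
  the ≥ 50% coverage rule per cell type (error below, warning between 50%
  and 100%).
* Sample matching between expression and clinical tables is exact string
  match after whitespace strip; cohort-specific identifier munging (e.g.
  barcode truncation) is the caller's responsibility.
* No proportional-hazards diagnostics or competing-risks models; the Cox
  machinery reports what it fits.
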