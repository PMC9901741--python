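# airatio

Adaptive-to-innate immune ratio analysis of bulk tumour RNA-seq.

Checkpoint-inhibitor immunotherapy works by unleashing the adaptive immune
response against tumour neoantigens, but stratification by PD-L1 status or
mutation burden leaves many responders and non-responders misclassified. A
complementary idea is to ask how the tumour microenvironment is balanced: a
strong *innate* infiltrate (macrophages, neutrophils, mast cells, ...)
relative to the *adaptive* infiltrate (CD8 T cells, B cells, cytotoxic
cells, ...) may mark tumours where a specific anticancer response never
properly forms. `airatio` turns that idea into a reproducible pipeline for
oncologists and bioinformaticians working with bulk expression cohorts:
marker-gene immune scoring, the adaptive/innate compartment ratio, and the
survival and therapy-response statistics that go with it, plus a synthetic
cohort generator with recorded ground truth so the whole chain is testable
without any external download.

## The statistic

For each immune cell type *c* with marker gene set *G(c)* (a packaged
Danaher-style panel: 14 cell types, 7 adaptive + 6 innate + 1 excluded),
the per-sample score is the mean log expression

```
score_c(s) = mean_{g in G(c)} log2(TPM_g(s) + 1)
```

and the total TIL score is the mean of all cell-type scores. For the
compartment ratio the scores are mapped back to the linear scale
(`2^x - 1`) and min–max scaled per cell type across the analysis cohort,

```
scaled_c(s) = (x_c(s) - min_c) / (max_c - min_c)   in [0, 1]
```

then averaged within compartments and divided:

```
A(s) = mean over adaptive cell types of scaled_c(s)
I(s) = mean over innate  cell types of scaled_c(s)
A/I ratio(s) = A(s) / I(s)        (missing if I(s) = 0)
```

Because the scaling extremes are cohort-wide, the ratio is a
*cohort-relative* statistic: comparable within one dataset, not across
datasets scaled separately. Downstream, samples are split at the median
A/I ratio (strictly above = high) for Kaplan–Meier / log-rank and Cox
proportional-hazards analyses, per-cancer-type hazard ratios are combined
by fixed-effect inverse-variance meta-analysis, and therapy response
(CR/PR/PD; SD excluded as uninterpretable) is compared by Wilcoxon
rank-sum, high-A/I × high-TIL quadrant Fisher tests, and the fraction of
patients with I > A ("below the diagonal").

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort of 1,600 patients across four cancer types in which females carry a
+0.5 shift of the latent adaptive skew and the skew is protective
(log-hazard −0.7 per unit):

```
$ python analysis/01_simulate_cohort.py
simulated 1600 samples x 2060 genes across 4 cancer types
$ python analysis/02_score_immune.py
Spearman rho(latent skew, A/I ratio) = 0.905
median A/I: female 0.809 vs male 0.530 (females shifted adaptive, as simulated)
$ python analysis/03_survival.py
15-year OS by gender x A/I median split: log-rank p = 2.50e-60
multivariable Cox: A/I HR = 0.573 (p = 5.49e-37), TIL HR = 0.933
meta-analysis (female): HR = 0.325 [0.272, 0.389]
meta-analysis (male): HR = 0.336 [0.283, 0.400]
$ python analysis/04_response.py
A/I ratio CR vs PD: p = 2.82e-48 (CR > PD)
responders with high A/I and high TIL: 248/657 (38%), Fisher p = 7.10e-21
fraction with I > A in PD: 85% (n=582)
$ python analysis/05_rank_check.py
mean marker percentile: tumours 0.89 vs cell lines 0.52 (one-sided rank-sum p = 3.09e-118)
```

Read: the computed ratio tracks the simulated latent skew (ρ = 0.90),
recovers the simulated gender difference and the protective effect
(median-split HR well below 1), responders sit in the high-A/I, high-TIL
quadrant far more often than chance, progressors overwhelmingly have more
innate than adaptive signal, and the marker genes rank high only when
infiltrate is present — the provenance check that the signal is not coming
from the cancer cells themselves.

The same machinery is scriptable via the `airatio` CLI
(`simulate`, `score`, `survive`, `respond`, `rankcheck`, `run`) or directly
from Python (`airatio.score_cell_types`, `airatio.compute_profiles`, ...).

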