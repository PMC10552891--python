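# oxynet

Integrative mRNA–miRNA–somatic-variant correlation network analysis for an
oxysterol-related gene panel in luminal breast cancer — built as a fully
testable pipeline over synthetic cohorts with known planted structure.

## The problem

Oxysterols (oxidized cholesterol derivatives) act as signaling lipids in
estrogen-receptor-positive breast cancer. A 113-gene panel covering their
synthesis, transport and receptors can be profiled at three levels in the
same patients: miRNA microarrays (log2 intensities), mRNA sequencing
(counts, TPM-normalized for correlation), and targeted DNA sequencing
(somatic variants). The analysis questions are:

* which miRNAs are co-expressed (network components at Spearman |r| ≥ 0.8,
  BH q < 0.05 within one test family per analysis);
* which gene–miRNA pairs are correlated across the samples shared between
  layers, whether those edges replicate in two independent cohorts
  (five-way classification: confirmed in both / one, not found, disputed in
  one / both), and whether they appear in predicted (top 20% by score) or
  experimentally validated interaction databases;
* which genes respond to somatic-mutation status or clinical factors
  (TMM-normalized exact negative-binomial test, volcano thresholds
  |log2FC| ≥ 2, q < 0.05);
* which features predict overall / disease-free survival (median-split
  log-rank screens with BH correction; Cox proportional hazards with tumor
  size as covariate).

Real cohorts of this design live in controlled-access repositories, so the
package ships a first-class simulator: latent-Gaussian-factor cohorts with
planted co-expression clusters, signed cross-omics edges, negative-binomial
counts, batch shifts, mutation-linked fold changes and exponential
proportional-hazards survival — every planted fact recorded in a ground
truth that serializes to JSON. Every stage is therefore testable against a
known answer.

## Core statistics

* Spearman rank correlation `r` (Pearson on average ranks), p from the
  t-approximation with n−2 df; Benjamini–Hochberg step-up FDR per declared
  family.
* ComBat empirical-Bayes location–scale batch model (parametric and
  nonparametric priors).
* Exact conditional NB test: group-sum counts compared to their conditional
  distribution given the total under a common dispersion φ (method-of-
  moments, pooled); reduces to the exact binomial test at φ = 0.
* Kaplan–Meier product-limit estimator, two-group log-rank test, and Cox
  partial-likelihood Newton–Raphson with Efron tie handling and
  monotone-likelihood detection.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
cohort (123 miRNA samples × 280 miRNAs in 3 batches; 67 mRNA samples × 113
genes; 56 shared):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_preprocess_mirna.py
python analysis/03_correlation_networks.py
python analysis/04_database_concordance.py --seed 1
python analysis/05_differential_expression.py
python analysis/06_survival_analysis.py
```

With seed 1 this prints (abridged):

```
228 miRNAs and 121 samples passed all filters (2 PCA outliers excluded)
86 strong miRNA-miRNA edges; largest co-expression group has 13 miRNAs;
  5 cross-layer edges ({'confirmed_both': 2, 'confirmed_one': 1,
  'not_found': 1, 'disputed_one': 1})
5/5 edges (100.0%) predicted and 4 (80.0%) experimentally validated
  in the 11-database fixture
pN1_vs_pN0: 29 vs 38 samples, 1 gene at q<0.05:
  STARD5 (log2FC +3.05, q 1.2e-13)
DFS screen: top hit hsa-miR-19b-3p (p=7.31e-07, q=0.000167)
hsa-miR-19b-3p (median-split) DFS: Cox HR 4.182 (95% CI 2.292-7.630,
  P=3.12e-06) with pT covariate
```

Reading it: the filter cascade retained 228 of 280 simulated miRNAs and
121 of 123 samples; the strong-edge network recovers most of the planted
15-member co-expression cluster (two members were drawn low-expressed and
legitimately filtered); the five cross-layer edges that reach significance
at n = 56 are classified against the two validation cohorts exactly as
planned; the planted pN1-linked STARD5 fold change (+3.26 planted, +3.05
estimated) and the planted prognostic miRNA are both recovered.

The same stages are available as CLI subcommands (`oxynet simulate`,
`preprocess`, `correlate`, `network`, `validate`, `dbannot`, `de`,
`survival`) for running on externally supplied TSV matrices; outputs are
byte-identical across runs for a fixed seed.

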