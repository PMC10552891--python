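# Methods

This note records the models, the parameter choices and their rationale,
what the simulator does and does not emulate, and the numerical decisions
that were genuinely open.

## Cohort simulator

### Expression model

All correlation structure is planted through shared latent Gaussian
factors. A co-expression cluster with target pairwise correlation r gives
each member the latent signal `z = sqrt(r)·f + sqrt(1−r)·e` for a shared
standard-normal factor `f`, so the population correlation between any two
members is exactly `r = v/(v+σ²)` with loading variance `v = r` and noise
`σ² = 1−r`. The construction is positive semi-definite by design; the only
infeasible requests — a miRNA appearing in two edges, or in both a cluster
and an edge — are rejected with an error naming the offending feature.

miRNA log2 intensities are `baseline + noise_sd · z + batch_shift`, with
per-feature baselines N(9, 1.5) (a 15% low-expressed subpopulation at
N(4.5, 1)), per-feature expression SD `noise_sd = 1.0` log2 units, and
per-batch per-feature shifts N(0, `batch_shift_sd` = 0.5). A detection flag
is emitted as value > 6.0 log2 units — an explicit noise-floor rule rather
than an emulation of scanner software, whose detection calls are not
documented for this platform class.

mRNA counts are negative binomial (dispersion 0.1) around log-normal
means: per-gene log2 means N(8, 1.5), i.e. a median of ~256 counts per
gene per sample and a panel library of 50–75k. Shallower defaults were
rejected because at a few thousand counts per library the per-gene M-value
noise leaves trimmed-mean normalization with a composition residual that
no count pipeline can remove; ~250 counts/gene matches what a 113-gene
panel receives from a standard mRNA-seq run. Transcript lengths are
uniform 0.3–10 kb; TPM follows count/length rate normalization to 10⁶ per
sample.

Cross-omics edges tie one miRNA latent to one mRNA latent with the
requested sign. Because the observable is the rank correlation of log2
TPM — not the latent — the planted latent correlation is inflated by (i)
the Gaussian-copula Spearman→Pearson conversion `ρ_P = 2 sin(π ρ_S / 6)`,
(ii) the delta-method count-noise attenuation `(E[1/μ] + φ)/ln²2` with the
Jensen term `E[1/μ] = e^{(σ ln 2)²/2}/2^{μ_g}`, and (iii) the variance of
the log TPM denominator. Calibration checks show planted targets recovered
within ±0.03 at n = 123.

What the simulator does **not** emulate: probe-level microarray artifacts,
read-level sequencing noise, copy-number structure, gene-length biases
within a sample, non-monotone gene–miRNA relationships, and real
linkage between mutation status and expression programs beyond the planted
fold changes. Passing tests therefore demonstrate statistical correctness
of the pipeline under a monotone-linear latent model, not robustness to
every artifact of real data.

### Clinical, variants and survival

Clinical covariates are drawn from realistic luminal-cohort margins (pT
0.5/0.4/0.1 over pT1–3, pN1 44%, luminal B 60%, ER+ 98%). Each mutation
contrast marks `round(fraction · n)` samples as carriers with 1–2 variant
rows in the contrast's genes; a 5% background variant rate is confined to
genes outside every contrast so planted group labels stay exact.

Survival is exponential proportional hazards: baseline hazard ln 2 / 60
per month (median 60 months), log-hazards per SD of the named features'
latent signals, and uniform administrative censoring Uniform(0, U) with U
solved by bisection so the expected censoring fraction matches the
requested rate (default 0.5). OS uses a 0.7× baseline hazard relative to
DFS. Closed-form truth makes Cox recovery testable.

### Validation cohorts and database fixtures

Validation cohorts (defaults n = 157 and 374, the scale of public
sequencing cohorts this design validates against) share the discovery
feature set, fully overlap in samples, and are emitted on the log2 scale
directly — they emulate preprocessed public expression matrices. Each
planned edge's population correlation is the discovery magnitude times
+1/−1/0 per its five-way class in each cohort.

Predicted-database fixtures give decoys scores Uniform(0, 0.8) and
enriched true edges Uniform(0.9, 1.0), so `enrichment = 1` guarantees
top-quintile membership and `enrichment = 0` makes true edges exchangeable
with decoys; validated databases are unscored row subsets at a
configurable inclusion rate.

## Preprocessing

Quantile normalization maps each column to the cross-column mean of sorted
values; within-column ties receive the mean of the rank-means their
positions span. The operation is exactly idempotent on tie-free data; with
ties a second pass can shift tied entries slightly (the reference
implementations behave the same way).

The signal filter pools all values, takes the 20th percentile as the
floor, and keeps features at or above it in ≥ 50% of samples (the pooled
reading of an ambiguous "20–100th percentile" rule; both the percentile
and the fraction are parameters). The detection filter keeps features
detected in ≥ 25% of samples, inclusive. Order: signal, then detection;
PCA outlier exclusion runs after normalization and before the filters (the
alternative order is a flag away, as the original ordering is not
documented).

PCA is column-centered SVD with the sign convention that each component's
largest-magnitude loading is positive. Outlier flagging measures Euclidean
distance from the score centroid in the first 3 PCs and flags samples
beyond median + 3 × 1.4826 × MAD of the distances. The k = 3 rule has a
per-sample null exceedance of ~0.6% (the distances are chi-distributed, so
a threshold symmetric in SD units sits closer to the tail than a normal
intuition suggests); in a 50-sample cohort about one in four runs flags a
bystander alongside a true outlier, which is the operating point of the
rule, not a defect.

ComBat follows the location–scale empirical-Bayes model: standardize per
feature against the batch-size-weighted grand mean and pooled residual
variance, estimate per-batch location/scale, shrink (parametric
normal/inverse-gamma with method-of-moments hyperparameters, iterated to
convergence; or the nonparametric empirical prior computed as a
likelihood-weighted average over the other features), remove, restore.
The default is parametric — it admits closed-form calibration tests — with
nonparametric behind a flag for fidelity to array practice. After
adjustment the residual row mean is re-centered so the per-feature grand
mean is preserved exactly. EB shrinkage deliberately leaves a residual
batch-mean difference of roughly half the sampling noise of the batch
means (verified bit-comparable to the reference implementation); claims of
"X% shift removal" must therefore be read relative to noise scale.

Expression dichotomization: high = value ≥ median; when the median is
zero, high = any expression. Constant vectors are an error, never a
silent single-group split.

## Correlation networks

Spearman r is the Pearson correlation of average ranks (tie-aware); p uses
the t-approximation with n−2 df (exhaustive permutation optional for
n ≤ 9); |r| = 1 reports p = 0. Constant features have no defined rank
correlation and are excluded from the family with a warning — never
reported as r = 0. Each invocation of the pairwise engine is one BH
family: all miRNA–miRNA pairs, all mRNA–miRNA pairs, each validation
cohort, each subgroup. Networks keep edges with q < 0.05 and, for
within-layer co-expression, |r| ≥ 0.8 (both bounds exactly as
conventional: q strictly below, |r| inclusive). Components are maximal
connected groups, sorted by size then lexicographically smallest member.

Edge validation classifies each discovery edge per cohort as agree
(significant, same sign), dispute (significant, opposite sign) or absent
(not significant after the cohort's own within-family FDR, or not
tested), then maps the pair of statuses to the five classes; the mixed
agree/dispute case maps to disputed-in-one with a logged conflict.
Validation-cohort FDR is computed within the tested pair set (the
restricted-family reading; configurable by passing a different family).

Power note: with only a handful of true edges in a 31,640-pair family, the
BH step-up threshold is data-poor (cutoff near p ≈ k·0.05/31,640 for k
accepted edges), and per-edge recovery of a |r| = 0.6 edge at n = 56 caps
near 0.65–0.7 for any method; recovery improves sharply when many edges
are real, because the accepted set itself relaxes the cutoff. The
acceptance suite reports this operating point honestly.

## Differential expression

Groups: a sample is "mutated" if it carries ≥ 1 somatic variant of any
class in any gene of the contrast (single gene or gene set); clinical
contrasts split on a stated category level. Groups smaller than 5 log a
prominent warning (contrasts down to n = 2 are allowed, as tiny mutation
groups are scientifically relevant here).

Normalization is trimmed-mean-of-M-values with the standard defaults (30%
two-sided M trim, 5% A trim, inverse-asymptotic-variance weights,
reference = sample whose upper quartile is closest to the mean), factors
scaled to geometric mean 1; verified bit-identical to the reference
implementation. Dispersion is a single pooled method-of-moments estimate,
`(s²−μ)/μ²` weighted by μ² across genes and groups, floored at 0 —
deliberately simpler than tagwise shrinkage, and adequate when one common
dispersion truly generated the data.

The exact test conditions each gene's group-sum (of library-rescaled,
rounded counts) on the total: group sums are NB(n_k·μ, φ/n_k), the
conditional distribution is the normalized product of the two pmfs, and
the two-sided p sums all outcomes no more likely than the observed one
(minimum-likelihood rule) — exactly the two-sided binomial test at φ = 0.
For totals above 2000 the support is windowed to ±20 conditional SDs
(tail mass far below double precision); above 200k a normal approximation
takes over. log2FC is group over reference on normalized means with a 0.5
pseudocount, so it is always finite.

A composition caveat measured during development: on a closed 113-gene
panel, ten same-direction 4-fold changes shift ~9% of the library, and
TMM (any TMM) leaves a residual that manifests as weak opposite-direction
calls in null genes. This is a property of compositional count data, not
of the implementation; interpret one-sided contrast results on small
panels accordingly.

## Survival

Kaplan–Meier is the product-limit estimator over event times (censoring
reduces the risk set only); the log-rank test accumulates hypergeometric
O−E and variance over pooled event times (1 df). The Cox model maximizes
the Efron-corrected partial likelihood by Newton–Raphson on centered
covariates (Breslow optional), converging at max |score| < 1e-8 within 50
iterations with step-halving; a likelihood plateau beyond |β| > 15, a
singular information matrix, or divergence past |β| > 50 is flagged as
non-convergence — monotone likelihood is never reported as a finite
estimate. Wald 95% CIs and p-values are reported for the first (exposure)
covariate. Efron is the default for its small-sample tie behavior. The
feature screen reuses the dichotomization rule verbatim, runs one log-rank
test per feature, and reports both unadjusted p and BH q across the
screen; undichotomizable features are skipped with a warning. The pT
covariate is coded binary (pT1 vs larger), with ordinal coding left to the
caller.

## Problem sizes in the validation suite

The calibration experiments use the cohort scales the design targets: 200
null cohorts of 123 samples × (280 + 113) features for family-wise FDR;
100 replicates for cluster recovery (15 members, r = 0.9, n = 123) and
edge recovery (10 edges, |r| = 0.6, n = 56); 500 features × 120 samples
for batch adjustment (fixture noise SD 0.5 log2 — a realistic per-probe
scale at which batch-mean sampling noise does not swamp the planted +2
shift); 100 replicates of 113 genes × 60 samples for DE (signs balanced
5 up / 5 down so the planted set does not itself create a composition
artifact; `noise_sd = 0` so φ is the entire dispersion); 500 Cox
replicates at n = 150 and 1000 log-rank null cohorts at n = 60. The whole
suite completes in well under two minutes on one CPU; the acceptance
script uses the same conditions at somewhat smaller replicate counts.
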