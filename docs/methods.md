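# Methods

`passig` implements a pathway-level signature pipeline for predicting
response to anti-PD1 immune checkpoint blockade from bulk tumor RNA-seq, in
the melanoma setting where paired pre-treatment (PRE) and on-treatment (ON)
biopsies are available. This note describes the model at each stage, the
parameters that matter, what the synthetic cohort generator does and does
not emulate, and the numerical choices made where the design was open.

## Response labeling

Patients are labeled responder (R) when RECIST is CR or PR, or SD with
progression-free survival strictly greater than 180 days; nonresponder (NR)
when PD, or SD with PFS at or below 180 days; NE stays NE. The boundary case
of exactly 180 days is not covered by the prose rule ("longer than" vs
"shorter than" leave 180 unassigned); this package resolves it as NR
(strict inequality for R), and `classify_response` documents that choice.
SD without a PFS time is an error, never a guess.

## Differential expression

Counts are modeled as negative binomial with mean `s_j * q_ij` and variance
`mu + phi * mu^2`. The stack is deliberately self-contained and analytically
transparent:

- **Size factors**: median-of-ratios against the geometric-mean
  pseudo-sample, using only genes expressed in every sample.
- **Dispersion**: per-gene method of moments on normalized counts,
  `phi = max(floor, (s^2 - m) / m^2)`, floor `1e-8`. No empirical-Bayes
  shrinkage is attempted; the unit tests show the estimator recovers
  generative dispersions at moderate n and the Wald test's type-I error sits
  at nominal (the acceptance suite checks the fraction of p < 0.05 on null
  NB data against [0.035, 0.065]).
- **Wald test**: per-group normalized-count means; the log2 fold change uses
  a pseudo-mean of 0.5 normalized counts inside the logarithm (configurable)
  to avoid log 0; the standard error comes from the delta method on the NB
  variance of each group mean; `z = lfc / se`, two-sided normal p, BH
  adjustment across genes.
- **Volcano rule**: "significantly upregulated" means log2FC > 1 and raw
  (unadjusted) Wald p < 0.05; the downregulated set is the same rule on the
  negated contrast. Raw p is intentional — it matches the stated selection
  criterion — while the BH-adjusted values are still reported per gene.
- **Ranking**: the list fed to enrichment is ordered by the Wald statistic
  (descending), ties broken lexicographically by gene id. The ranking metric
  is configurable (`stat`, `log2FoldChange`); the Wald statistic is the
  default because it blends effect size with precision.

## Preranked GSEA

The enrichment score is the classical weighted Kolmogorov–Smirnov-like
running sum with weight exponent p = 1 (configurable): hits add
`|r|^p / N_R`, misses subtract `1/(N - N_H)`, and ES is the maximal signed
deviation. The leading edge is the set members at or before the peak for
positive ES, strictly after it for negative ES.

Significance uses a gene-label permutation null: size-matched random gene
sets drawn from the ranked universe (the scheme of preranked fgsea-style
tools, not phenotype permutation), default 10,000 permutations, and
`p = (1 + #{same-sign |ES*| >= |ES|}) / (1 + #same-sign)`. NES divides ES by
the mean magnitude of same-sign permuted scores; when no same-sign
permutation exists the NES is flagged unstable. The multiple-testing filter
is BH across all tested pathways applied to the permutation p-values —
matching the "adjusted p-value < 0.05" filter wording — rather than the
classical permutation-FDR. Candidates are the pathways with ES > 0 and
FDR < 0.05, ranked by NES, truncated to the top 15 (ties by smaller p, then
name).

Permutation ES values are computed by an O(m) piecewise-linear evaluation at
hit positions only, vectorized across permutations; the tests verify exact
agreement with the full running-sum recomputation and exact-enumeration
consistency on instances small enough to enumerate.

## ssGSEA

Counts are converted to TPM using a supplied gene-length table
(`tpm = rate / sum(rates) * 1e6`, rates = counts/length); every column sums
to 10^6. Per sample, genes are ranked by expression (average ranks on ties),
and the pathway score integrates the difference between the rank-weighted
in-set ECDF (weights `rank^alpha`, alpha = 0.25) and the uniform out-of-set
ECDF. With normalization on (the default), the score matrix is divided by
its global max − min. That normalization couples samples within a matrix, so
validation cohorts are always scored within their own matrix — never jointly
with training data — which also mirrors the per-dataset scoring used to
mitigate batch effects. Leading-edge genes absent from a cohort's matrix are
dropped; a set missing more than half its genes is an error.

## Cost-sensitive elastic-net logistic model

With pathway scores X (candidates × samples) and labels y (R = 1), the model
minimizes

    (1/n) Σ_i w_i [log(1 + e^{η_i}) − y_i η_i]
        + λ (α ||β||_1 + (1 − α)/2 ||β||_2²)

with observation weights inversely proportional to class frequency
(normalized to mean 1) — the standard cost-sensitive device for the R/NR
imbalance. The source description of cost-sensitivity ("the offset") is
ambiguous between class weights and an additive offset; class weights are
used because an additive offset cannot change the ranking that AUC measures.

Features are standardized internally; coefficients are reported back on the
original scale. The mixing parameter α defaults to 0.5 (the conventional
equal L1/L2 blend; never stated in the source). λ runs over 100 log-spaced
values from the KKT-derived λ_max (the smallest penalty at which the
all-zero vector is optimal) down to λ_max·10⁻⁴. The solver is iteratively
reweighted least squares with cyclic coordinate descent and soft
thresholding, warm-started along the path; tests verify KKT optimality,
agreement with a generic convex optimizer to 10⁻⁶ in objective, and exact
zeros at λ ≥ λ_max. Penalty selection is stratified 3-fold cross-validation
on weighted binomial deviance with the one-standard-error rule (largest λ
within one SE of the minimum); fold assignment is seeded.

## PASS score, cutoff, odds

The signature keeps the pathways with nonzero coefficients, their
leading-edge gene sets, and their coefficients as effect sizes. The PASS
score of a sample is the weighted average

    score = Σ_k β_k x_k / Σ_k |β_k|

(the absolute-value normalizer handles mixed-sign coefficients and makes the
score invariant to positive rescaling of β; the intercept does not enter the
score). The classification cutoff maximizes Youden's J
(sensitivity + specificity − 1) over midpoints of consecutive sorted unique
training scores, ties resolved to the smallest threshold. The per-sample
odds are the logistic `exp(β0 + Σ β_k x_k)`, and survival stratification
splits at the mean of the odds: strictly above the mean is "high". The Cox
hazard ratio is reported low-vs-high (HR > 1 means the low-odds stratum
fails faster), and the output headers state that orientation.

## Time-response (TimeANLS) variant

Candidate pathways come from the unpaired DE contrast of responders'
on-treatment vs pre-treatment samples (positive fold change = up on
treatment); two independent elastic nets are then fitted — one on PRE
samples (R vs NR), one on ON samples — sharing the candidate ssGSEA
features. Both returned signatures reference the same candidate list.

## Evaluation and comparison

AUC is the Mann–Whitney concordance (ties count half), which the tests pin
to the trapezoidal ROC area to 10⁻¹². Accuracy and the Matthews correlation
coefficient are computed at the training cutoff, with MCC defined as 0 when
any confusion-matrix margin is empty. Signature comparison repeats (default
1000×): stratified sampling of 80% of samples without replacement,
preserving the R/NR proportion within each cohort; AUC per signature on the
subsample; one-sided rank-sum test between the target's AUC vector and each
comparator's. Because 80% subsamples overlap heavily, the resampled AUCs
concentrate near each signature's full-sample AUC: the procedure resolves
which signature wins on the dataset at hand and is anticonservative as a
test of equal generalization — a property of the procedure itself, noted
here and exercised in the tests (tail symmetry under an exchangeable null).

Published comparator signatures (IFN-γ, T-cell-inflamed GEP, chemokine,
CYT, MHC-I/II, CD8A/CSF1R ratio, checkpoint-pair counts) are scored by a
generic engine (mean log2(TPM+1), geometric mean of TPM+1, log ratios, pair
counts); the bundled gene lists are labeled reconstructions of literature
defaults and are meant to be replaced for any serious benchmark.

## Survival statistics

Kaplan–Meier, the two-sided log-rank test and the binary-covariate Cox model
are delegated to lifelines (Efron tie handling; fit precision tightened to
10⁻¹² so the estimate matches a direct partial-likelihood maximization to
10⁻⁶). Monotone-likelihood configurations (no events in one group) return an
infinite-HR sentinel flagged as non-converged rather than an error. A
proportional-hazards diagnostic is available through lifelines but never
gates results.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes:

- **Counts**: NB via gamma–Poisson, `mean = s_j · 2^(μ_i + a_p + m_{p,k} + Δ)`,
  dispersion φ = 0.2 (Var = μ + φμ²); baseline log2 means N(4, 2);
  log-normal library sizes (sd 0.3).
- **Patient structure**: paired PRE/ON biopsies share a patient-level offset
  a_p (sd 0.2) and per-patient per-pathway offsets m_{p,k} (sd 0.5). The
  module-level term is essential realism: co-regulated pathways fluctuate
  together across tumors (e.g. immune infiltration), so pathway-level noise
  does not average away over member genes. Without it, even a weak uniform
  per-gene effect yields a near-perfect pathway classifier, which real
  pre-treatment cohorts do not show.
- **Effects**: the first `n_driver_pathways` (default 3) pathways' member
  genes gain δ log2 units in responders — δ_pre = 0.3, δ_on = 1.5 by
  default, encoding the expectation that responder biology sharpens under
  therapy. Under these defaults the held-out PRE AUC lands around 0.6–0.75
  and the ON AUC near 1, reproducing the qualitative ordering (on-treatment
  more predictive) rather than any dataset's exact numbers.
- **Labels and survival**: exponential PFS/OS with a nonresponder:responder
  hazard ratio (default 3) and independent exponential censoring tuned to
  the requested marginal censoring rate (default 20%); RECIST codes are
  drawn consistently with the true response under the 180-day SD rule, so
  relabeling the generated table reproduces the truth exactly.
- **Gene sets**: 50 pathways of 20–100 genes over 2,000 genes, disjoint by
  default (a configurable fraction can be drawn from a shared overlap pool);
  gene lengths uniform on [200, 20000] bp.

All randomness flows from a single seed through fixed stage keys; the same
seed reproduces counts, tables and survival bit for bit.

What the generator does **not** emulate: transcriptome-wide correlation
beyond the module structure, batch/platform effects, varying sequencing
depth–dispersion coupling, gene-length biases in counts, informative
censoring, or single-cell structure. Passing tests therefore demonstrate
that the pipeline recovers the signal it models under its own assumptions —
not performance on any real cohort.

## Problem sizes in the test and acceptance runs

The shipped tests and `scripts/acceptance.py` use the default study
conditions with 1,000 GSEA permutations and 10–20 independent seeds for the
end-to-end sweeps, 2,000 null genes × 20 (tests) or 5 (script) repetitions
for the Wald calibration, and 200–500 repetitions for the log-rank
calibration — sizes chosen so a full run completes in minutes on one CPU
while keeping the Monte-Carlo error well inside the asserted bands. The
pipeline default for GSEA remains 10,000 permutations.

## Known limitations

- The DE stack is not DESeq2: no empirical-Bayes dispersion shrinkage,
  Cox–Reid adjustment, LFC shrinkage, outlier filtering or independent
  filtering. Numerics will differ from DESeq2 on real data even though the
  inferential form (NB Wald) matches.
- The NES/FDR convention is BH over permutation p-values, not the
  Subramanian permutation-FDR.
- The exact normalizer of the published "weighted average" score and whether
  its intercept enters are not stated in the source; the Σ|β| normalizer and
  intercept-free score used here are documented choices.
- Single binary covariate Cox only; no multivariate adjustment.
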