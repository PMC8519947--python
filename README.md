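# passig

Pathway-based super-signature (PASS) construction and evaluation for
predicting response to anti-PD1 immune checkpoint blockade from bulk tumor
RNA-seq.

Only a minority of metastatic melanoma patients derive durable benefit from
anti-PD1 therapy, and single-gene markers generalize poorly across cohorts.
`passig` builds *pathway-level* predictive signatures from cohorts with
pre-treatment (PRE) and/or on-treatment (ON) biopsies and RECIST-annotated
outcomes. The pipeline:

1. **Label** patients: R = CR/PR or SD with PFS > 180 days; NR = PD or SD
   with PFS ≤ 180 days.
2. **Differential expression** (R vs NR): negative-binomial Wald test with
   median-of-ratios size factors and method-of-moments dispersion;
   Benjamini–Hochberg correction.
3. **Preranked GSEA** on the Wald-statistic-ranked gene list over a pathway
   collection (GMT): weighted Kolmogorov–Smirnov running-sum ES, gene-label
   permutation p (10,000 permutations), NES, BH-FDR; keep pathways with
   ES > 0 and FDR < 0.05, rank by NES, take the top 15 candidates.
4. **ssGSEA** scores of each candidate's *leading-edge* genes per sample, on
   TPM.
5. **Cost-sensitive elastic-net logistic regression** over the pathway
   scores (inverse-class-frequency weights, stratified 3-fold CV on weighted
   binomial deviance, one-standard-error λ):

       (1/n) Σᵢ wᵢ [log(1+e^{ηᵢ}) − yᵢηᵢ] + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)

6. **PASS score** = Σₖ βₖxₖ / Σₖ|βₖ| (effect-size-weighted average of
   pathway scores), classification cutoff by the Youden index, per-sample
   logistic odds, and mean-odds high/low survival strata (Kaplan–Meier,
   log-rank, Cox HR).

It also implements the time-response variant (TimeANLS: candidates from the
responders' ON-vs-PRE contrast, independent PRE and ON models over shared
features), ROC/AUC and accuracy/MCC evaluation, the 1000× stratified-80%
resampling comparison against published signatures, and a fully seeded
synthetic cohort generator so every stage is testable without any data
download.

## Worked example

```python
import dataclasses
from passig import (SimulationConfig, simulate_cohort, TrainSettings,
                    train_signature, validate_signature)

# synthetic training cohort: 2000 genes, 50 pathways (3 drivers whose genes
# are upregulated in responders: +0.3 log2 pre-treatment, +1.5 on-treatment),
# 100 patients (40% responders) with paired PRE/ON biopsies
cfg = SimulationConfig(seed=11)
counts, samples, truth, genesets, lengths = simulate_cohort(cfg)

settings = TrainSettings(n_perm=1000, seed=1)
sig, model, report = train_signature(counts, samples, genesets, lengths,
                                     timepoint="ON", cfg=settings)
print(report.selected, truth.driver_pathways)
print(round(report.training_auc, 3), round(sig.cutoff, 3))

# independent test cohort drawn from the same gene-set universe
test_counts, test_samples, *_ = simulate_cohort(
    dataclasses.replace(cfg, seed=99), genesets, lengths)
res = validate_signature(sig, test_counts, test_samples, lengths)
print(round(res["auc"], 3), round(res["accuracy"], 3), round(res["mcc"], 3))
cox = res["survival"]["pfs"]["cox"]
print(round(cox.hr, 2), round(cox.pvalue, 4))
```

Output:

```
['PW000', 'PW001', 'PW002', 'PW003', 'PW041', 'PW026', 'PW019', 'PW039', 'PW028'] ['PW000', 'PW001', 'PW002']
1.0 0.205
1.0 0.89 0.8
2.19 0.1854
```

The elastic net selected all three driver pathways (plus six weakly
weighted passengers); the held-out AUC of 1.0 reflects the strong
on-treatment effect (δ_on = 1.5 across whole pathways), while accuracy 0.89
and MCC 0.80 show the training-derived Youden cutoff transfers a little
less perfectly than the ranking. The mean-odds low-odds stratum progresses
about twice as fast (PFS HR low-vs-high = 2.19) — the expected direction,
though not significant at 100 test patients (p = 0.19). Pre-treatment
signatures trained on the same cohorts land around AUC 0.6–0.75 — the
qualitative finding that on-treatment biopsies are more predictive than
pre-treatment ones.

## Command line

```sh
passig simulate --seed 3 --out sim/
passig train --config run.yaml          # DE -> GSEA -> ssGSEA -> ENLR
passig train-time --config run.yaml     # TimeANLS PRE/ON pair
passig score --signature out/signature_ON.json --config test.yaml
passig compare --scores scores.tsv --target PASS-ON --out out/
passig run-all --config run.yaml        # simulate + train + validate + compare
```

See `passig --help` for the full list (`de`, `gsea`, `ssgsea`, `evaluate`,
`survival`, ...). Exit codes: 0 success, 2 config error, 3 data-contract
error, 4 statistical degeneracy.

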