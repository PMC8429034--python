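# lncpair

Rank-based immune-related lncRNA **pair** signatures for survival
prognosis in tumor cohorts.

Expression-level prognostic signatures are fragile across platforms and
normalizations.  An alternative is to score each patient only by the
*within-sample ordering* of gene pairs: for two immune-related lncRNAs
A and B, the pair feature is

```
value(A|B, sample) = 1  if expr(A) > expr(B) in that sample, else 0
```

which is invariant under any strictly increasing per-sample transform
of expression.  `lncpair` implements the full analysis around this
primitive, as used for kidney clear cell renal cell carcinoma (ccRCC)
risk models built on TCGA-KIRC-style cohorts:

1. **Screening** — lncRNAs coexpressed with curated immune genes
   (Pearson |r| ≥ 0.8, BH-adjusted p < 0.001), then differential
   expression tumor vs normal (|log2FC| ≥ 1, Wilcoxon rank-sum FDR <
   0.05) yielding DEirlncRNAs.
2. **Pairing** — the 0/1 pair matrix over all k(k−1)/2 canonical pairs,
   keeping pairs whose "1" fraction lies strictly between 20% and 80%
   of patients (near-constant pairs carry no contrast).
3. **Signature** — univariate Cox screen (p < 0.05), L1-penalized Cox
   with seeded event-stratified 10-fold cross-validation (λ_min by
   cross-validated partial-likelihood deviance), then bidirectional
   AIC-stepwise multivariable Cox.  The risk score is

   `riskScore = Σ_{i=1..N} value(i) · coef(i)`

   over the N retained pairs.
4. **Evaluation** — KM-weighted time-dependent ROC/AUC at 1/2/3 years,
   an optimal cutoff by AIC scan (or Youden's J), risk-group
   assignment, Kaplan–Meier curves and the log-rank test.
5. **Association** — chi-square contingency with clinical categories,
   rank-sum tests of the score across clinical subgroups, univariate
   and multivariable Cox independence models, subgroup survival, and
   Spearman/rank-sum associations with immune-infiltration fractions,
   checkpoint-gene expression (PDCD1, CD247, CTLA4, TIGIT, LAG3) and
   precomputed drug-sensitivity (IC50-like) scores.

A synthetic-cohort generator (`lncpair.simulate`) produces tumor/normal
cohorts with planted immune coupling, differential expression, a
pair-driven exponential proportional-hazards survival model, and
clinical/immune/drug annotations tied to the planted risk, so the whole
pipeline is testable without external downloads.  Infiltration
deconvolution and drug-response prediction themselves are out of scope:
the pipeline consumes those as tables.

## Worked example

```python
from lncpair import (SimulationParams, generate_cohort,
                     PipelineConfig, run_pipeline_on_cohort)

cohort = generate_cohort(SimulationParams(seed=1))   # 300 tumor / 50 normal
result = run_pipeline_on_cohort(cohort, PipelineConfig(seed=1))
print(result.report)
```

On this cohort (200 lncRNAs, 100 immune genes, 3 planted pairs with
log-hazard coefficients 1.0 / −0.9 / 0.8) the run reports:

```
n_irlnc 40, n_de 20 (17 up / 3 down)
n_pairs_built 190 -> stable 139 -> uni-Cox 36 -> LASSO 15 -> final 9
cutoff -0.150 (aic); groups: 209 high / 91 low
AUC: 1yr 0.738, 2yr 0.813, 3yr 0.842
log-rank chi2 62.44, p = 2.7e-15
```

The funnel narrows exactly as the method intends, all three planted
pairs (`LNC0002|LNC0008`, `LNC0005|LNC0007`, `LNC0006|LNC0010`) are in
the final signature with coefficient signs matching the planted
hazard, every horizon AUC exceeds 0.73, and the high-risk group has
clearly worse survival.  The extra retained pairs share lncRNAs with
the planted ones and carry correlated signal — the expected behavior
of stepwise selection under collinearity.

The same run is available from the shell:

```bash
lncpair run --outdir out/ --seed 1
lncpair simulate --outdir cohort/ --seed 1       # stage-by-stage instead
lncpair screen --expr cohort/expression.tsv --groups cohort/groups.tsv \
    --annotation cohort/annotation.tsv --immune cohort/immune_genes.txt \
    --outdir out/
```

A packaged reference table (`lncpair.reference`) carries a published
12-pair ccRCC signature and its cohort's clinicopathological counts,
used for analytic identity checks (`exp(coef) = HR`, CI geometric-mean
identity, percentage arithmetic) and as a schema example.

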