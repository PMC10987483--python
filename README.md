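# tmesuite

Tumor-microenvironment (TME) subtyping of cancer transcriptomes, as a
tested, reusable pipeline. The package covers the full workflow used to
stratify colorectal-cancer cohorts into TME subtypes and to dissect what
drives their different outcomes:

1. **Signature scoring** — per-sample scores for curated TME gene sets
   (score = arithmetic mean of log2 expression over the set's genes), plus
   preprocessing: hierarchical-clustering outlier removal, correlation-based
   signature filtering, and a univariate Cox screen of each signature's
   prognostic direction.
2. **Subtype discovery** — non-negative matrix factorization (V ≈ WH,
   generalized Kullback–Leibler objective, multiplicative updates) of the
   signatures × samples score matrix, with consensus clustering over random
   restarts. The rank k is chosen over k = 3…8 by the highest product of the
   cophenetic correlation and dispersion coefficients of the consensus
   matrix; final labels (TMES1…TMESk) come from the best-objective run.
3. **Subtype projection** — nearest-centroid transfer of a trained subtype
   model onto external cohorts by Pearson correlation on cohort-standardized
   scores (robust to platform shifts between microarray and RNA-seq data).
4. **Survival statistics** — Kaplan–Meier curves, log-rank tests, univariate
   Cox proportional-hazards fits (Newton on the Breslow partial likelihood),
   and maximally selected log-rank cutpoints for dichotomizing a marker.
5. **Signature selection ensemble** — LASSO-penalized Cox with 10-fold
   cross-validation, random-forest importance (intersection of Gini and
   out-of-bag permutation top-30 lists), and SVM-RFE; the prognostic
   signature set is the three-way intersection.
6. **Single-cell stage** — QC (mitochondrial fraction, cell complexity, gene
   prevalence), log-normalization, highly-variable-gene selection, PCA,
   Leiden clustering on a shared-nearest-neighbor graph, rank-sum marker
   detection (FDR < 0.05, |log2FC| > 0.25), marker-set cluster annotation,
   and ligand-receptor interaction testing between cell groups with
   cluster-label permutation p-values.

Because the public cohorts this kind of analysis is usually run on are large
downloads, the package ships synthetic-data generators
(`tmesuite.synthetic_data`) that produce bulk cohorts with planted subtypes
and proportional-hazards survival, and single-cell counts with planted cell
types, low-quality cells, and ligand-receptor co-expression — every stage is
therefore testable offline against a known ground truth.

## Worked example

```python
from tmesuite import (BulkSimConfig, gen_bulk_cohort, score_signatures,
                      rank_survey, final_subtypes, logrank_test)

expr, sigs, surv, truth = gen_bulk_cohort(BulkSimConfig(seed=1))
scores = score_signatures(expr, sigs)           # 50 signatures x 300 samples
survey = rank_survey(scores, (3, 8), n_runs=50, seed=0)
print(survey.table)
labels, model, consensus = final_subtypes(scores, survey.chosen_k,
                                          n_runs=500, seed=0)
print(logrank_test(surv, labels.as_dict()))
```

prints (values from this exact invocation):

```
   k  cophenetic  dispersion   product
0  3    0.996555    0.472494  0.470867
1  4    0.998548    0.712602  0.711567
2  5    0.999817    0.970761  0.970583
3  6    0.999243    0.914345  0.913653
4  7    0.998902    0.893127  0.892147
5  8    0.997741    0.848333  0.846417
LogRankResult(chi_square=77.8968..., df=4, p_value=4.857e-16)
```

The five-subtype structure planted by the generator is recovered: the
cophenetic × dispersion product peaks at k = 5 (`chosen_k = 5`), and the
resulting subtypes separate survival (the generator assigns each subtype a
different hazard). With the default strong separation the final labels match
the planted subtypes exactly (adjusted Rand index 1.0).

The same stages are available from the command line:

```sh
tmesuite simulate bulk --out cohort/ --seed 1
tmesuite score --expression cohort/expression.tsv \
               --signatures cohort/signatures.gmt --out scores.tsv
tmesuite discover --scores scores.tsv --out discovery/ --seed 0
tmesuite run-all --config config.yaml --out run/   # end-to-end + manifest
```

`run-all` writes a `manifest.json` recording every parameter, seed, and
output hash; re-running with the same config reproduces byte-identical
outputs.

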