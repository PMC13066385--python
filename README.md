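# ccdeconv

Compartment-resolved transcriptome analysis of metachronous-metastasis risk
in clear cell renal cell carcinoma (ccRCC).

About a third of ccRCC patients with apparently localized disease relapse
with metastases months to years after nephrectomy (*metachronous*
metastasis, MM), while others remain indolent (IN) through follow-up and a
third group presents with synchronous spread (SM). Bulk tumor expression
confounds the cancer cells with the stromal/immune compartment, so this
package separates the two before asking which genes mark metastatic risk,
and then builds a compact survival model from the candidates.

The pipeline covers, as composable library modules with a thin CLI:

* **Two-compartment deconvolution** — per gene and sample group, bulk
  log2 expression `b_i` of a sample with tumor purity `p_i` is fit by
  constrained least squares as

  `b_i ≈ p_i·e_c + (1 − p_i)·e_s ,  e_c, e_s ≥ 0`

  giving group-level cancer (`e_c`) and stroma (`e_s`) expression.
  Purity itself enters as the median consensus of multiple upstream
  estimation methods.
* **Compartment-specific differential expression** — the DE score
  `DE = log2( |e_c2/e_c1| / |e_s2/e_s1| )` contrasts how strongly a gene
  changes between cohorts in cancer versus stroma; significance comes from
  a label-permutation null in which the deconvolution is re-run on every
  shuffle, with Benjamini–Hochberg FDR control. A
  difference-of-fold-changes variant `(e_c2−e_c1) − (e_s2−e_s1)` is
  available via `statistic="difference"` and has substantially higher
  power (see `docs/methods.md`).
* **Genomic association stages** — SEG→gene copy-number mapping,
  two-group Wilcoxon rank-sum locus tests (exact for small groups),
  Fisher exact mutation-carrier tests, CNA–expression Pearson
  correlation, and one-sided Fisher (hypergeometric) pathway enrichment
  against a defined background universe.
* **GPR reaction scoring** — boolean gene–protein–reaction rules are
  parsed (AND binds tighter than OR) and scored on compartment expression
  with the `OR→max`, `AND→min` substitution, per group and compartment.
* **Cox risk modelling** — univariate proportional-hazards screening, a
  multivariate 5-gene signature benchmarked by repeated event-stratified
  5-fold cross-validation (AUC, c-index, AIC, likelihood-ratio p,
  specificity at a target sensitivity), nested cross-validation with
  LASSO-Cox feature selection, and tertile risk stratification with a
  log-rank test.
* **Synthetic cohorts** — a generator that plants known compartment fold
  changes, a contiguous copy-number-loss region with a dosage effect, and
  gene-linked exponential hazards, providing ground truth for every stage.

## Worked example

Simulate a cohort at the default study conditions (IN 68, MM 44, SM 80
samples), deconvolute, and test for compartment-specific DE between the
indolent and metachronous groups:

```python
from ccdeconv import (SimulationConfig, simulate_cohort, prepare_expression,
                      deconvolute, permutation_de_test)

cfg = SimulationConfig(n_genes=1000, seed=0)          # IN 68, MM 44, SM 80
expr, annotation, truth = simulate_cohort(cfg)

prepared = prepare_expression(expr, min_median=2.0)   # FPKM filter + log2(X+1)
profile = deconvolute(prepared, annotation["purity"], annotation["group"])

de = permutation_de_test(prepared, annotation["purity"], annotation["group"],
                         groups=("IN", "MM"), n_perm=2000, seed=0,
                         statistic="difference")
hits = de[de["q_bh"] < 0.25].sort_values("p_empirical")
```

This prints (`hits` head, 999 genes tested, 97 significant at q < 0.25):

```
        de_score  cancer_log2fc  stroma_log2fc  p_empirical    q_bh direction
gene
G00177   -1.6273        -0.5632         1.0641       0.0002  0.0631    stroma
G00684    1.5221         1.2849        -0.2372       0.0003  0.0631    cancer
G00987   -1.5176        -1.2716         0.2459       0.0003  0.0631    cancer
```

`cancer_log2fc`/`stroma_log2fc` are the MM-vs-IN changes of the
deconvoluted compartment expression; `direction` names the compartment
carrying the larger change. Of the 97 hits, 90 are genes with planted
compartment fold changes (46 stroma, 44 cancer) and 7 are false positives
— consistent with the q < 0.25 FDR target.

Benchmarking a planted 5-gene hazard signature (each β = log 1.8, n = 94,
the MM/IN cohort scale) by 20×5-fold cross-validation:

```python
report = repeated_cv_evaluate(table, signature, k=5, repeats=20,
                              target_sensitivity=0.878, seed=0)
print(report.summary.round(4))
```

```
                                mean      sd
auc                           0.8287  0.0147
sensitivity                   0.9062  0.0000
specificity_at_sensitivity    0.4955  0.0618
c_index                       0.7744  0.0910
```

and tertile stratification of the resulting risk score yields a log-rank
chi-square of 35.79 (p = 1.7e-08) with a per-group number-at-risk table.

The same stages run from the shell:

```bash
ccdeconv-mm simulate --out cohort/ --seed 0
ccdeconv-mm de-test --expr cohort/expression.tsv --purity cohort/purity.tsv \
    --labels cohort/annotation.tsv --groups IN,MM --n-perm 2000 --seed 0 --out de.tsv
ccdeconv-mm run --config run.yaml      # orchestrated, with a JSON manifest
```

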