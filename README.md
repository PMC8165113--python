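# valvesex

Sex-stratified analysis of aortic-valve transcriptomics, built as a tested,
reusable pipeline:

- **cohort_sim** — synthetic matched cohorts: Table-1-style clinical
  covariates, three tissue samples per patient (nondiseased / intermediate /
  calcified), and log2 expression matrices with planted sex effects,
  calcification effects, sex-by-calcification interactions, X-escape-like
  and Y-linked genes. Every downstream stage has a ground-truth oracle.
- **matching** — maximum-likelihood propensity model (P(male | covariates)),
  greedy 1:1 nearest-neighbour matching with caliper, and balance
  diagnostics via absolute standardized differences (continuous, binary,
  multicategory Mahalanobis forms).
- **concordance** — the per-gene matched-pair 2×2 statistic: a sex score
  (fraction of same-grade male-vs-female comparisons won by the male
  sample) and a tissue score (fraction of patients whose calcified sample
  exceeds the nondiseased one), with extreme-quadrant gene selection around
  the (0.5, 0.5) centre.
- **expression_stats** — variance filtering guided by a permutation-based
  projection score, gene-centred PCA, paired (repeated-measures)
  calcified-vs-nondiseased t-tests, tissue-adjusted male-vs-female t-tests,
  Benjamini–Hochberg q-values, fold-change filtering (genes with
  0.8 < FC < 1.2 removed), the two-stage sex-differential gene selection,
  and average-linkage hierarchical clustering on correlation distance.
- **predictors** — genetic-algorithm wrapper feature selection with
  random-forest cross-validated fitness, patient-grouped k-fold CV (default
  k = 6), a six-model bench (logistic regression, kNN, naive Bayes,
  gradient boosted trees, random forest, feedforward net) with pooled ROC
  curves, node-improvement importance weights, pure-tree extraction with
  readable split rules, and the sex-chromosome-only feature subset.
- **pipeline / cli** — plain-text I/O (TSV/CSV/JSON), stage orchestration
  with a deterministic per-stage seed fan-out, and a `valvesex` CLI.

## CLI

```sh
valvesex simulate --seed 42 --out cohort/
valvesex match --clinical cohort/clinical.csv --out matched/
valvesex concordance --expression cohort/expression.tsv \
    --samples cohort/samples.tsv --pairs matched/pairs.tsv --out conc/
valvesex filter --expression cohort/expression.tsv --samples cohort/samples.tsv --out filt/
valvesex select --expression cohort/expression.tsv --samples cohort/samples.tsv --out sel/
valvesex select-ga --expression cohort/expression.tsv --samples cohort/samples.tsv \
    --genes sel/selected_genes.tsv --out ga/
valvesex classify --expression cohort/expression.tsv --samples cohort/samples.tsv \
    --genes sel/selected_genes.tsv --out models/
valvesex sexchrom --expression cohort/expression.tsv --samples cohort/samples.tsv \
    --annotation cohort/annotation.tsv --out xy/
valvesex run-all --seed 42 --out full_run/
```

File formats: expression TSV (`gene_id` + one column per sample), sample
sheet TSV (`sample_id`, `patient_id`, `sex` ∈ {M,F}, `tissue` ∈
{nondiseased, intermediate, calcified}), gene annotation TSV (`gene_id`,
`symbol`, `chromosome` ∈ {1–22, X, Y}), clinical CSV. A small seeded demo
cohort ships with the package (`valvesex.io.load_demo_cohort()`).

## Notes on reproducibility

The original patient-level microarray data are not public; the synthetic
generator is a stand-in with documented, configurable distributions, and
all gene-level results (specific gene lists, fold changes, enrichment
scores) are out of scope. Model hyperparameters are pinned in
`src/valvesex/model_defaults.yaml` so results do not drift with library
versions. All randomness flows from explicit seeds; a single pipeline seed
is fanned out per stage so earlier stages are unaffected by later ones.
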