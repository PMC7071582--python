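# dtscore

Druggability scoring of proteins with positive-unlabeled (PU) bagged random
forests.

Proteins are described by a unified feature table combining:

- precomputed sequence/annotation features (TSV input),
- a tissue-specificity feature: Shannon entropy of the expression profile
  across tissues, averaged over expression sources,
- five protein-interaction-network centralities (degree, betweenness,
  closeness, pagerank, eigenvector) computed on the top-scoring fraction of
  a STRING-style edge table,
- per-category ontology rank scores: gene sets are rank-ordered by their
  one-sided Fisher enrichment p-value against the approved-target training
  set, and each protein scores the mean of its three best set ranks.

Heavy-tailed columns are log(1+x)-transformed and every column is min-max
scaled to [0, 1]. Training positives are targets of approved drugs matching
an indication filter; clinical-trial-only targets form an independent
validation holdout; everything else (minus approved targets of any
indication) is the negative sampling pool. Many balanced random forests are
fitted against freshly sampled pseudo-negative sets; per-protein scores and
per-feature mean-decrease-Gini importances are averaged over the ensemble.

A synthetic scenario generator emulates all five inputs with controllable
effect sizes, so the whole pipeline is testable without any downloads.

## CLI

```bash
# generate a synthetic scenario (five inputs + ground-truth labels)
dtscore simulate --preset default --seed 1 --out data/

# full pipeline (features -> network -> ontology -> train -> evaluate)
dtscore run \
    --features data/features.tsv --features-meta data/features_meta.yaml \
    --expression data/expression_1.tsv --expression data/expression_2.tsv \
    --edges data/edges.tsv \
    --gmt data/biological_process.gmt --gmt data/molecular_function.gmt \
    --gmt data/signaling_pathway.gmt \
    --catalog data/catalog.tsv --indication oncology \
    --n-models 10000 --n-trees 1000 --seed 0 --out results/

# or with a YAML config (flags override file values)
dtscore run --config run.yaml
```

Outputs: `scores.tsv` (protein, averaged probability), `importances.tsv`
(feature, mean Gini decrease), `report.json` + `roc_points.tsv`
(clinical-holdout ROC/AUC), `feature_tests.tsv` (per-feature Wilcoxon /
chi-squared class differences) and `manifest.json` (config, input hashes,
timings, replicate seed derivation).

Stage subcommands (`features`, `network`, `ontology`, `train`, `evaluate`)
are individually invocable and compose via files; see `dtscore --help`.

## Input formats

| input       | format                                                          |
| ----------- | --------------------------------------------------------------- |
| features    | TSV, first column `protein_id`; YAML sidecar with `feature_kinds` (continuous/categorical) and `heavy_tailed` lists |
| expression  | TSV, first column `gene_id`, one column per tissue, >= 2 tissues |
| edges       | 3-column TSV `protein_a  protein_b  score` (header auto-detected) |
| ontologies  | GMT, one gene set per line (`set_id  description  members...`), one file per category |
| catalog     | TSV with header `target_id  drug_id  status  indication`, status in {approved, clinical, research, withdrawn} |

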