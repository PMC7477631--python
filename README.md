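# drugcombo

Similarity-based drug combination prediction. Drug pairs are scored by a
neighbor recommender over per-feature Tanimoto similarity matrices, the
per-channel scores are fused by a stacked logistic-regression ensemble, and
everything is evaluated with an imbalance-aware, leakage-guarded
cross-validation harness. A synthetic generator with planted cluster
structure makes the whole pipeline testable without any external data.

## What's inside

| Module | Purpose |
| --- | --- |
| `drugcombo.data_model` | Domain types (drug universe, profiles, similarity matrices, combination network, pair datasets, run config) and all file I/O |
| `drugcombo.similarity` | Tanimoto coefficient of set-valued profiles and per-channel matrix construction |
| `drugcombo.nrm` | Neighbor recommender scoring `y_ij = Σ S_ik a_kj / Σ S_ik` with link masking and a leakage-safe default |
| `drugcombo.baseline_classifiers` | GLM / naive Bayes / SVM baselines on per-pair similarity vectors |
| `drugcombo.feature_assessment` | Welch t-test, signed two-sample KS statistic, random-forest Gini importance, min–max normalization, channel selection |
| `drugcombo.ensemble` | Out-of-fold stacking of per-channel recommender scores under a logistic meta-classifier |
| `drugcombo.evaluation` | Negative downsampling, stratified folds, metric computation (recall/precision/F1/AUROC/AUPR), ratio sweeps, leave-one-drug-out |
| `drugcombo.synthetic_data` | Planted-cluster benchmark generator and plain-text fixture writer |

## CLI

All subcommands accept `--seed`, `--config cfg.yaml` and `--log-level`
before the subcommand name; every output file records the seed and a config
hash in a comment header.

```bash
# generate a synthetic benchmark (profiles, matrices, pair list, truth sidecar)
drugcombo --seed 7 simulate --n-drugs 120 --clusters 4 --channels 4 \
    --informative 2 --out fixtures/

# Tanimoto matrix from a set-valued profile (GMT-like or long TSV)
drugcombo similarity --profile fixtures/profile_channel1.tsv \
    --channel channel1 --out channel1.tsv

# neighbor-recommender scores for all candidate pairs
drugcombo nrm --matrix fixtures/similarity_channel1.tsv \
    --pairs fixtures/pairs.tsv --out scores.tsv

# channel screening: t-test, KS, RF importance, selection flags
drugcombo assess-features \
    --matrices fixtures/similarity_channel1.tsv \
    --matrices fixtures/similarity_channel2.tsv \
    --pairs fixtures/pairs.tsv --out assessment.tsv

# fit + serialize the stacked ensemble
drugcombo ensemble --matrices fixtures/similarity_channel1.tsv \
    --matrices fixtures/similarity_channel2.tsv \
    --pairs fixtures/pairs.tsv --out model.json

# repeated masked cross-validation for any model
drugcombo --seed 7 evaluate --model ensemble --k 5 --repeats 20 \
    --matrices fixtures/similarity_channel1.tsv \
    --matrices fixtures/similarity_channel2.tsv \
    --pairs fixtures/pairs.tsv --out report.tsv

# leave-one-drug-out candidate ranking for one drug
drugcombo predict --target D000 --threshold 0.5 \
    --matrices fixtures/similarity_channel1.tsv \
    --matrices fixtures/similarity_channel2.tsv \
    --pairs fixtures/pairs.tsv --out candidates.tsv
```

`evaluate --model` accepts `glm`, `nb`, `svm`, `ensemble`, or
`nrm:<channel>`. Baselines train on a fresh `ratio`:1 negative downsample
per repeat; the recommender and ensemble score the full pair set with
test-fold positives masked from the network before any score is computed.

## File formats

* **Similarity matrix** — square TSV/CSV, first row and column are drug ids;
  `scale="percent"` divides 0–100 scores by 100. Symmetrized by averaging
  (asymmetry beyond 1e-6 is an error); diagonal forced to 1.
* **Pair list** — two-column TSV, optional header; reversed duplicates
  collapse; self-pairs are rejected with their line number.
* **Profile** — GMT-like (`drug<TAB>token...`) or long (`drug<TAB>token`)
  TSV, auto-detected.
* **Config** — YAML/JSON with the `RunConfig` fields
  (`channels, k, ratio, repeats, threshold, seed, missing_policy`).
* **Report** — TSV, one row per (model, k, metric) with full-precision
  `mean`/`sd` columns and a rendered `mean ± sd` cell.

## Protocol notes

* The recommender's neighbor sum excludes the queried pair's own adjacency
  entry by default (`exclude_self=True`), so a pair's own label can never
  leak into its score during cross-validation; a strict textbook mode that
  only drops `k = j` is available for replication.
* Pair scores are `y_ij + y_ji ∈ [0, 2]`; the thresholded probability is
  `score / 2` so that the 0.5 decision rule is well-defined.
* Ensemble meta-features are out-of-fold recommender scores (proper
  stacking). An in-sample mode exists behind a flag and warns about leakage.
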