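# drivnet

Driver-gene prioritization from somatic mutation data and gene interaction
networks, combining *functional* information (network-propagated mutation
profiles) with *structural* information (struc2vec-style topological
embeddings).

Cancer cohorts yield binary mutation matrices — samples × genes, highly
heterogeneous, with true driver genes often mutated in only a few patients.
drivnet addresses this by (1) diffusing each sample's mutation indicator
vector over a protein–protein interaction network, F_t = αW′F_{t−1} +
(1−α)Y with W′ = D^{−1/2}AD^{−1/2}, which spreads weak signal across
functionally related genes; (2) building a **mutation integration network**
by linking gene pairs whose propagated profiles have similarity > 0.5;
(3) embedding every gene in that network as a 128-dimensional vector by
structural similarity — hop-wise degree sequences compared with dynamic
time warping, a multilayer graph with weights e^{−f_k}, biased random
walks, and a skip-gram model — so genes that play the same topological role
are near each other even when far apart in the graph; and (4) ranking genes
by the positive-class probability of classifiers (KNN, logistic regression,
SVM, random forest, XGBoost) trained on those vectors against a benchmark
driver catalog (CGC/NCG/IntOGen-style gene lists), evaluated by repeated
undersampled cross-validation (10 balanced draws × 10 stratified 80/20
splits = 100 runs).

The package is aimed at method developers and computational biologists who
want a transparent, fully seeded re-implementation of this pipeline that
runs at desk scale on synthetic cohorts and accepts real edge-list /
matrix / gene-list inputs.

## Worked example

Simulate a planted-driver cohort and run the full pipeline:

```bash
drivnet simulate --seed 7 --out-dir demo            # 300 genes, 120 samples, 25 drivers
drivnet run --network demo/network.tsv --mutations demo/mutations.tsv \
            --benchmark demo/drivers.txt --model xgbt --seed 7 --out-dir demo/out
```

The run prints (abridged):

```json
{
  "cv_summary": {
    "roc_auc":   {"mean": 0.9250, "std": 0.0848},
    "precision": {"mean": 0.8700, "std": 0.1315},
    "recall":    {"mean": 0.8340, "std": 0.1576}
  },
  "benchmark_overlap_top_n": 0.64
}
```

Reading: over 100 undersampled holdout runs the XGBoost model separates
planted drivers from passengers with mean ROC-AUC 0.92 (probability that a
random driver outranks a random passenger), and 64% of the top-25 ranked
genes are planted drivers. `demo/out/` contains the integration network,
the embeddings (word2vec text format), the full ranked gene list and a
manifest with per-stage timings and the exact configuration; rerunning the
same command reproduces it byte for byte.

The same stages are available as library functions
(`drivnet.propagate_all`, `drivnet.embed_network`,
`drivnet.run_repeated_eval`, …) and as stage-level subcommands
(`propagate`, `embed`, `classify`, `evaluate`, `sweep-alpha`).

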