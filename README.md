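# clusternet-smlm

Graph-based classification of single-molecule localization microscopy (SMLM)
point clouds.

SMLM (DNA-PAINT, dSTORM, PALM) produces a list of molecule coordinates with
nanometre precision rather than a pixel image. Classifying whole fields of
view — a DNA-origami structure, a cell — requires more than the shape of any
single cluster of localizations: it depends on the *supracluster structure*,
the spatial arrangement of many clusters. This package implements the
ClusterNet pipeline for that task, end to end:

1. **Preprocess** — quality-filter localizations (photon count, PSF width and
   fit p-value, localization precision), merge blinking events by temporal
   grouping, optionally split fields of view into cells from pre-made masks,
   and partition each ROI/cell into clusters (k-means or DBSCAN; clusters
   with ≤ 2 localizations are discarded).
2. **Featurize** — eight handcrafted features per cluster from its
   localizations: count, radius of gyration squared
   `rg² = ⟨|p − p̄|²⟩`, convex-hull perimeter, and PCA-eigenvalue shape
   descriptors with λ₀ ≥ λ₁ the variances along the principal components:
   linearity `(λ₀−λ₁)/λ₀`, planarity `λ₁/λ₀`, length `2.35·√λ₀`,
   area `2.35²·√(λ₀λ₁)`, density `count/area`.
3. **Graphify** — a hierarchical graph per ROI: localization nodes (positions
   only) belonging to cluster nodes (centroid position + optional features),
   undirected edges joining each cluster node to itself and its 5 nearest
   neighbours. Positions are normalized per graph to [−1, 1] preserving
   aspect ratio; features are min-max normalized to [0, 1] with statistics
   from the training set only.
4. **Classify** — ClusterNet: 4 PointTransformer-style vector-attention
   message-passing layers over the cluster graph, global max pooling, linear
   head, log-softmax. Cluster input features are either the handcrafted ones
   (ClusterNet-HCF) or an 8-dimensional embedding of each cluster's member
   localizations learned by LocNet, a per-cluster point-set network trained
   end to end with the classifier (ClusterNet-LCF).
5. **Explain** — UMAP embeddings of features at four levels (handcrafted,
   LocNet, post-message-passing, whole-graph) show how class separation
   emerges; SubgraphX (Monte-Carlo tree search with sampled Shapley scoring)
   finds the connected subgraph most responsible for a classification, and
   positive/negative fidelity quantify its necessity/sufficiency:
   `Fid⁺ = p(full) − p(graph − subgraph)`, `Fid⁻ = p(full) − p(subgraph)`.

A synthetic-data module generates labeled DNA-origami-like ROIs (binding-site
layouts + Gaussian scatter + Poisson counts + uniform background + per-site
misfolding dropout + random orientation), so the whole pipeline is testable
without any external data. The neural-network core runs on a small built-in
reverse-mode autodiff engine over numpy arrays (see `clusternet/engine.py`);
no GPU or deep-learning framework is required.

## Worked example

```python
import clusternet as cn
from clusternet.preprocess import ClusteringConfig, cluster
from clusternet.features import features_for_clusters
from clusternet.graphs import build_graph
from clusternet.models import ModelConfig
from clusternet.train import (SplitPlan, TrainConfig, evaluate, make_splits,
                              prepare_hcf_graphs, train)

library = cn.make_default_templates().subset(["grid", "digit1", "digit3", "letterO"])
tables = cn.sample_dataset(library, 40, cn.SimulationParams(seed=11))
graphs = []
for t in tables:
    cs = cluster(t, ClusteringConfig(seed=0))          # k-means, k = 12
    graphs.append(build_graph(cs, features=features_for_clusters(cs)))

fold = make_splits([g.label for g in graphs], SplitPlan(), seed=1)[0]
tr, va, te = ([graphs[i] for i in idx] for idx in (fold.train, fold.val, fold.test))
prepare_hcf_graphs(tr, va, te)                          # scaler fitted on train only
result = train(ModelConfig(n_classes=4, mode="HCF", hidden_dim=32, seed=0),
               tr, va, TrainConfig(epochs=40, batch_size=16, seed=0))
report = evaluate(result.model, te, result.class_to_index)
print(round(report.balanced_accuracy, 3), {k: round(v, 2) for k, v in report.recalls.items()})
```

prints

```
0.781 {'digit1': 0.75, 'digit3': 0.5, 'grid': 0.88, 'letterO': 1.0}
```

i.e. on this deliberately small run (160 ROIs, 40 epochs) the classifier
recovers 78% balanced accuracy — the arithmetic mean of the per-class
recalls — on the held-out 20% split; the letter separates first because its
sparse, well-separated site groups differ most from the digits' continuous
strokes. At full synthetic scale (200 ROIs/class, 50 epochs) ClusterNet-HCF
exceeds 95% and ClusterNet-LCF 90% (see `tests/test_acceptance.py`).

The same pipeline is scriptable from the shell:

```bash
clusternet generate --classes grid,digit1,digit3,letterO --n-per-class 40 --seed 11 --out data/
clusternet run --config config.toml --out runs/demo      # full pipeline + manifest
clusternet evaluate runs/demo --split test
clusternet explain subgraphx runs/demo 0 --rollouts 100 --seed 0
clusternet explain umap runs/demo --level whole_graph --seed 0
```

## Graph container format

Graphs are stored as `.npz` archives (version-tagged JSON header plus typed
arrays `loc_pos`, `loc_cluster`, `cluster_pos`, `edges`, optional
`cluster_features`). `clusternet.read_graph` / `write_graph` round-trip them
losslessly.

## Data

Everything here runs on synthetic data. The pipeline reads real
localization tables from Apache Parquet (label in the file metadata under
`gt_label`) or CSV (label as a repeated `gt_label` column); with the original
DNA-origami DNA-PAINT datasets and longer training the same pipeline is
designed to approach its published classification performance, but no
download is required for any test.
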