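"""End-to-end pipeline runner with config validation and a run manifest.

A single TOML config drives generate -> cluster -> featurize -> graphify ->
split -> train -> evaluate. Every run directory receives exactly one
``manifest.json`` recording the config snapshot, seeds, package version,
output hashes and timestamps; re-running with the same config reproduces the
outputs on the same platform.
"""

from __future__ import annotations

import hashlib
import json
import time
import tomllib
from pathlib import Path

import numpy as np

from . import __version__
from .exceptions import ConfigError
from .features import features_for_clusters
from .graphs import build_graph
from .io import write_graph
from .models import ModelConfig, save_model
from .preprocess import ClusteringConfig, cluster
from .synthetic import SimulationParams, make_default_templates, sample_dataset
from .train import (SplitPlan, TrainConfig, evaluate, make_splits,
                    prepare_hcf_graphs, train)

_SCHEMA = {
    "data": {"classes", "n_per_class", "locs_per_site_mean", "site_sigma",
             "background_rate", "misfold_prob", "rotation"},
    "cluster": {"method", "k", "eps", "min_pts", "min_cluster_size"},
    "graph": {"n_neighbors"},
    "model": {"mode", "n_classes", "embed_dim", "n_message_layers", "hidden_dim",
              "locnet_hidden", "locnet_blocks", "locnet_k"},
    "train": {"epochs", "lr", "weight_decay", "batch_size"},
    "run": {"seed"},
}


def load_config(path: str | Path) -> dict:
    """Read and validate a TOML config; unknown sections or keys raise
    :class:`ConfigError` before any computation starts."""
    with open(path, "rb") as fh:
        config = tomllib.load(fh)
    validate_config(config)
    return config


def validate_config(config: dict) -> None:
    for section, content in config.items():
        if section not in _SCHEMA:
            raise ConfigError(f"unknown config section {section!r}")
        unknown = set(content) - _SCHEMA[section]
        if unknown:
            raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {section!r}")
    if "seed" not in config.get("run", {}):
        raise ConfigError("configs must set run.seed explicitly")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Execute the full synthetic pipeline described by ``config``.

    Stages run in order; a failure in any stage aborts with the failing stage
    named, keeping partial outputs in the run directory for debugging.
    Returns the run directory.
    """
    validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = time.time()
    seed = int(config["run"]["seed"])
    stage = "setup"
    try:
        stage = "generate"
        data_cfg = dict(config.get("data", {}))
        class_names = data_cfg.pop("classes", ["grid", "digit1", "digit3", "letterO"])
        library = make_default_templates().subset(class_names)
        n_per_class = int(data_cfg.pop("n_per_class", 50))
        params = SimulationParams(seed=seed, **data_cfg)
        tables = sample_dataset(library, n_per_class, params)

        stage = "preprocess"
        clu_cfg = ClusteringConfig(seed=seed, **config.get("cluster", {}))
        cluster_sets = [cluster(t, clu_cfg) for t in tables]

        stage = "featurize+graphify"
        model_section = dict(config.get("model", {}))
        mode = model_section.pop("mode", "HCF")
        graph_kwargs = config.get("graph", {})
        graphs = []
        for cs in cluster_sets:
            feats = features_for_clusters(cs) if mode == "HCF" else None
            graphs.append(build_graph(cs, features=feats, **graph_kwargs))

        stage = "split"
        labels = [g.label for g in graphs]
        folds = make_splits(labels, SplitPlan(), seed=seed)
        fold = folds[0]
        train_graphs = [graphs[i] for i in fold.train]
        val_graphs = [graphs[i] for i in fold.val]
        test_graphs = [graphs[i] for i in fold.test]
        if mode == "HCF":
            prepare_hcf_graphs(train_graphs, val_graphs, test_graphs)

        stage = "write-graphs"
        graph_dir = out_dir / "graphs"
        for g in graphs:
            write_graph(g, graph_dir / f"{g.source_id}.npz")
        splits = {"train": fold.train.tolist(), "val": fold.val.tolist(),
                  "test": fold.test.tolist(),
                  "files": [f"graphs/{g.source_id}.npz" for g in graphs]}
        (out_dir / "splits.json").write_text(json.dumps(splits, indent=2))

        stage = "train"
        model_cfg = ModelConfig(mode=mode, n_classes=len(class_names), seed=seed,
                                **model_section)
        train_cfg = TrainConfig(seed=seed, **config.get("train", {}))
        result = train(model_cfg, train_graphs, val_graphs, train_cfg,
                       class_names=sorted(class_names))
        with open(out_dir / "training_log.jsonl", "w") as fh:
            for entry in result.log:
                fh.write(json.dumps(entry) + "\n")
        save_model(result.model, out_dir / "model.npz", result.class_to_index)

        stage = "evaluate"
        report = evaluate(result.model, test_graphs, result.class_to_index)
        metrics = {
            "balanced_accuracy": report.balanced_accuracy,
            "recalls": report.recalls,
            "auroc": report.auroc,
            "macro_auroc": report.macro_auroc,
            "best_epoch": result.best_epoch,
            "best_val_loss": result.best_val_loss,
        }
        (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
        np.savetxt(out_dir / "confusion.csv", report.confusion,
                   fmt="%d", delimiter=",",
                   header=",".join(report.class_names), comments="")
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    stage = "manifest"
    outputs = {
        str(p.relative_to(out_dir)): _sha256(p)
        for p in sorted(out_dir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "config": config,
        "seed": seed,
        "version": __version__,
        "started_unix": started,
        "finished_unix": time.time(),
        "output_hashes": outputs,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir
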