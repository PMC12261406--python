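"""End-to-end experiment runner: data -> model -> metrics -> artifacts.

``run_experiment`` accepts either a :class:`~ppibench.synthetic.SyntheticConfig`
(everything generated in memory) or a mapping of file paths (pair-table
TSVs per split, an HDF5 embedding store) and produces a reproducible
metrics report plus, when an output directory is given, a checkpoint,
a per-epoch log and a tab-separated metrics file.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import estimators as est_mod
from .estimators import make_model, registry_input_kind, registry_pca_components
from .io import EmbeddingStore, PairTable, length_filter, mean_pool, pca_reduce
from .synthetic import SyntheticConfig, make_dataset
from .training import MetricReport, TrainConfig

__all__ = [
    "run_experiment",
    "build_samples",
    "prepare_synthetic_samples",
    "sweep",
    "HIGH_SIGNAL_STRENGTH",
    "learnability_experiment",
    "null_experiment",
]

# the "clearly learnable" regime for the learnability contrast; other
# experiments use the SyntheticConfig default (see docs/methods.md)
HIGH_SIGNAL_STRENGTH = 20.0


def build_samples(
    pairs_df: pd.DataFrame, vectors: Mapping[str, np.ndarray]
) -> tuple[list[tuple[np.ndarray, np.ndarray]], np.ndarray]:
    """(X, y) for an estimator from a split DataFrame and an id->array map."""
    X = [(vectors[a], vectors[b]) for a, b in zip(pairs_df["idA"], pairs_df["idB"])]
    y = pairs_df["label"].to_numpy(dtype=int)
    return X, y


def _pooled(embeddings: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {pid: mean_pool(mat) for pid, mat in embeddings.items()}


def _apply_pca(
    vectors: Mapping[str, np.ndarray], n_components: int
) -> dict[str, np.ndarray]:
    # fitted jointly on every protein's mean embedding, mirroring the
    # benchmark protocol (documented as faithful rather than leakage-free)
    ids = sorted(vectors)
    matrix = np.vstack([vectors[pid] for pid in ids])
    reduced, _ = pca_reduce(matrix, n_components)
    return {pid: reduced[i] for i, pid in enumerate(ids)}


def prepare_synthetic_samples(
    config: SyntheticConfig, input_kind: str, pca_components: int | None = None
):
    """Per-split (X, y) plus the pair table for a synthetic benchmark."""
    records, _, pairs, embeddings = make_dataset(config)
    pairs = length_filter(pairs, records)  # no-op under the length cap; kept for parity
    if input_kind == "protein":
        vectors = _pooled(embeddings)
        if pca_components is not None:
            vectors = _apply_pca(vectors, pca_components)
    else:
        vectors = dict(embeddings)
    splits = {}
    for split in ("train", "validation", "test"):
        splits[split] = build_samples(pairs.split(split), vectors)
    return splits, pairs


def _prepare_file_samples(paths: Mapping[str, str], input_kind: str, pca_components):
    tables = []
    from .io import read_pair_table

    for split in ("train", "validation", "test"):
        tables.append(read_pair_table(paths[split], split))
    pairs = PairTable.concat(tables)
    pairs.validate_disjoint()
    with EmbeddingStore(paths["embeddings"], "r") as store:
        ids = sorted(pairs.protein_ids())
        if input_kind == "protein":
            try:
                vectors = {pid: store.read_vector(pid) for pid in ids}
            except KeyError:
                vectors = {pid: mean_pool(store.read_token(pid)) for pid in ids}
            if pca_components is not None:
                vectors = _apply_pca(vectors, pca_components)
        else:
            vectors = {pid: store.read_token(pid) for pid in ids}
    splits = {s: build_samples(pairs.split(s), vectors) for s in
              ("train", "validation", "test")}
    return splits, pairs


def run_experiment(
    registry_name: str,
    data_source: SyntheticConfig | Mapping[str, str],
    train_config: TrainConfig | None = None,
    out_dir: str | Path | None = None,
    model_overrides: Mapping | None = None,
) -> tuple[MetricReport, object]:
    """Build, train and test a registry model; optionally write artifacts."""
    input_kind = registry_input_kind(registry_name)
    pca_components = registry_pca_components(registry_name)
    model = make_model(registry_name, **(model_overrides or {}))
    if train_config is not None:
        overlap = {
            k: v
            for k, v in dataclasses.asdict(train_config).items()
            if k in model.get_params()
        }
        model.set_params(**overlap)

    if isinstance(data_source, SyntheticConfig):
        splits, pairs = prepare_synthetic_samples(
            data_source, input_kind, pca_components
        )
    else:
        splits, pairs = _prepare_file_samples(
            data_source, input_kind, pca_components
        )

    log_lines: list[str] = []
    model.fit(
        splits["train"][0],
        splits["train"][1],
        validation=splits["validation"],
        log_fn=log_lines.append,
    )
    report = model.evaluate(*splits["test"])
    report.best_epoch = getattr(model, "best_epoch_", None)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        row = {"model": registry_name, **report.as_row()}
        pd.DataFrame([row]).to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
        (out_dir / "history.log").write_text("\n".join(log_lines) + "\n")
        config_blob = {
            "model": registry_name,
            "params": model.get_params(),
            "data": (
                dataclasses.asdict(data_source)
                if isinstance(data_source, SyntheticConfig)
                else dict(data_source)
            ),
        }
        (out_dir / "config.json").write_text(
            json.dumps(config_blob, indent=2, default=str)
        )
        if hasattr(model, "net_"):
            est_mod.save_checkpoint(
                out_dir / "checkpoint.npz", model, registry_name
            )
    return report, model


def learnability_experiment(
    model_name: str,
    seed: int = 0,
    signal_strength: float = HIGH_SIGNAL_STRENGTH,
    max_epochs: int = 30,
):
    """Train on clearly learnable planted data; return the best history.

    For the per-protein model a two-point width/learning-rate grid is
    swept and the run with the best validation accuracy returned,
    mirroring the validation-driven hyperparameter selection of the
    shared protocol.  The convolutional baseline uses its tuned
    kernel/pooling configuration directly (one run; it is two orders
    of magnitude slower per epoch).
    """
    cfg = SyntheticConfig(seed=seed, signal_strength=signal_strength)
    if model_name == "Richoux-ESM-2":
        candidates = [
            {"hidden_reduce": 64, "hidden_joint": 64, "learning_rate": 3e-3},
            {"hidden_reduce": 512, "hidden_joint": 256, "learning_rate": 3e-3},
        ]
    elif model_name == "2d-baseline":
        # best configuration found for this family at this scale: global
        # average pooling (the grid mean factorizes into a pooled-embedding
        # statistic) with a wider reduction; see docs/methods.md
        candidates = [
            {"kernel_size": 3, "pool": "avg", "pool_kernel": 1000,
             "reduction_sizes": (64, 32, 32), "learning_rate": 1e-2},
        ]
    else:
        raise ValueError(f"no learnability recipe for {model_name!r}")
    best_history = None
    for overrides in candidates:
        overrides = dict(overrides)
        lr = overrides.pop("learning_rate")
        tc = TrainConfig(
            max_epochs=max_epochs, patience=max_epochs,
            learning_rate=lr, batch_size=16, seed=seed,
        )
        _, model = run_experiment(
            model_name, cfg, train_config=tc, model_overrides=overrides
        )
        history = model.history_
        if best_history is None or (
            history.best_val_accuracy > best_history.best_val_accuracy
        ):
            best_history = history
    return best_history


def null_experiment(seed: int = 0, max_epochs: int = 15):
    """Train the per-protein model on label-shuffled data.

    Shuffling labels within each split destroys the association with
    the planted latents while preserving balance; the final-epoch
    validation accuracy should sit at chance.
    """
    from .synthetic import shuffle_labels

    cfg = SyntheticConfig(seed=seed, signal_strength=HIGH_SIGNAL_STRENGTH)
    records, _, pairs, embeddings = make_dataset(cfg)
    null_pairs = shuffle_labels(pairs, seed=seed + 1)
    vectors = _pooled(embeddings)
    train = build_samples(null_pairs.split("train"), vectors)
    val = build_samples(null_pairs.split("validation"), vectors)
    model = make_model(
        "Richoux-ESM-2",
        hidden_reduce=64, hidden_joint=64,
        learning_rate=3e-3, batch_size=16,
        max_epochs=max_epochs, patience=max_epochs, seed=seed,
    )
    model.fit(train[0], train[1], validation=val)
    return model.history_


def sweep(
    registry_name: str,
    grid: Mapping[str, list],
    data_source,
    out_dir: str | Path,
    train_config: TrainConfig | None = None,
) -> pd.DataFrame:
    """Config-driven grid sweep; one metrics row per combination."""
    import itertools

    keys = sorted(grid)
    rows = []
    out_dir = Path(out_dir)
    for i, values in enumerate(itertools.product(*(grid[k] for k in keys))):
        overrides = dict(zip(keys, values))
        report, _ = run_experiment(
            registry_name,
            data_source,
            train_config=train_config,
            out_dir=out_dir / f"run_{i:03d}",
            model_overrides=overrides,
        )
        rows.append({**overrides, **report.as_row()})
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "sweep.tsv", sep="\t", index=False)
    return df
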