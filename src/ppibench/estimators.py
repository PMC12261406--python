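"""Scikit-learn-style estimators over the model zoo.

Every architecture is wrapped as a classifier with the familiar
``fit`` / ``predict`` / ``predict_proba`` surface so models compose
with sklearn pipelines and model selection.  ``X`` is a sequence of
``(embedding_A, embedding_B)`` pairs — per-token matrices for the
per-token families, pooled vectors for the per-protein ones — and
``y`` the binary interaction labels.  Validation data for early
stopping is passed to ``fit`` via ``validation=(X_val, y_val)``.

The registry maps the benchmark's published model names (for example
``"2d-Crossattention"`` or ``"TUnA-unpadded"``) to configured
estimators.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

from . import models
from .nn import Module
from .training import (
    TrainConfig,
    batch_scores,
    evaluate,
    fit_network,
    predict_scores,
)

__all__ = [
    "MapCapabilityError",
    "TwoDInteractionClassifier",
    "RichouxClassifier",
    "DScriptClassifier",
    "TunaClassifier",
    "RandomForestPairClassifier",
    "REGISTRY",
    "make_model",
    "registry_names",
    "save_checkpoint",
    "load_checkpoint",
]


class MapCapabilityError(TypeError):
    """Raised when an intermediate map is requested from a family without one."""


def _as_pair_list(X) -> list[tuple[np.ndarray, np.ndarray]]:
    return [(np.asarray(a, dtype=float), np.asarray(b, dtype=float)) for a, b in X]


class _NeuralPairClassifier(BaseEstimator, ClassifierMixin):
    """Shared fit/predict machinery for the deep families."""

    input_kind = "token"  # or "protein"
    exposes_map = False

    # subclasses implement -------------------------------------------------
    def _build_net(self, d_emb: int) -> Module:  # pragma: no cover - abstract
        raise NotImplementedError

    # sklearn surface -------------------------------------------------------
    def fit(self, X, y, validation=None, log_fn=None):
        X = _as_pair_list(X)
        y = np.asarray(y, dtype=int)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if validation is not None:
            X_val = _as_pair_list(validation[0])
            y_val = np.asarray(validation[1], dtype=int)
        else:  # fall back to monitoring the training split
            X_val, y_val = X, y
        d_emb = X[0][0].shape[-1]
        self.d_emb_ = int(d_emb)
        self.classes_ = np.array([0, 1])
        self.net_ = self._build_net(d_emb)
        cfg = self._train_config()
        samples = [(a, b, int(lbl)) for (a, b), lbl in zip(X, y)]
        val_samples = [(a, b, int(lbl)) for (a, b), lbl in zip(X_val, y_val)]
        self.history_ = fit_network(
            self.net_, samples, val_samples, cfg, log_fn=log_fn
        )
        self.best_epoch_ = self.history_.best_epoch
        return self

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            subsample_fraction=self.subsample_fraction,
            seed=self.seed,
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted; call fit() first")

    def score_pairs(self, X) -> np.ndarray:
        """Raw interaction probabilities in (0, 1)."""
        self._check_fitted()
        samples = [(a, b, 0) for a, b in _as_pair_list(X)]
        return predict_scores(self.net_, samples)

    def predict_proba(self, X) -> np.ndarray:
        s = self.score_pairs(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X) -> np.ndarray:
        return (self.score_pairs(X) > 0.5).astype(int)

    def predict_map(self, X) -> list[np.ndarray]:
        """Intermediate (L1', L2') maps for families that expose one."""
        if not self.exposes_map:
            raise MapCapabilityError(
                f"{type(self).__name__} does not expose an intermediate map"
            )
        self._check_fitted()
        self.net_.eval()
        return [self.net_(a, b)[1].data.copy() for a, b in _as_pair_list(X)]

    def evaluate(self, X, y, threshold: float = 0.5):
        report = evaluate(self.score_pairs(X), np.asarray(y, int), threshold)
        report.best_epoch = getattr(self, "best_epoch_", None)
        return report


class TwoDInteractionClassifier(_NeuralPairClassifier):
    """Outer-product convolutional classifier on per-token embeddings."""

    input_kind = "token"
    exposes_map = True

    def __init__(
        self,
        reduction_sizes=None,
        attention="none",
        encoder_position="none",
        spectral_norm=True,
        kernel_size=3,
        pool="max",
        pool_kernel=None,
        n_heads=8,
        ff_dim=None,
        dropout=0.1,
        learning_rate=1e-3,
        batch_size=16,
        max_epochs=50,
        patience=8,
        subsample_fraction=0.5,
        seed=0,
    ):
        self.reduction_sizes = reduction_sizes
        self.attention = attention
        self.encoder_position = encoder_position
        self.spectral_norm = spectral_norm
        self.kernel_size = kernel_size
        self.pool = pool
        self.pool_kernel = pool_kernel
        self.n_heads = n_heads
        self.ff_dim = ff_dim
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.subsample_fraction = subsample_fraction
        self.seed = seed

    def _build_net(self, d_emb: int) -> Module:
        return models.TwoDNet(
            d_emb,
            reduction_sizes=self.reduction_sizes,
            attention=self.attention,
            encoder_position=self.encoder_position,
            spectral_norm=self.spectral_norm,
            kernel_size=self.kernel_size,
            pool=self.pool,
            pool_kernel=self.pool_kernel,
            n_heads=self.n_heads,
            ff_dim=self.ff_dim,
            dropout=self.dropout,
            seed=self.seed,
        )


class RichouxClassifier(_NeuralPairClassifier):
    """Fully connected classifier on pooled per-protein embeddings."""

    input_kind = "protein"
    exposes_map = False

    def __init__(
        self,
        hidden_reduce=None,
        hidden_joint=None,
        attention="none",
        spectral_norm=False,
        n_heads=8,
        ff_dim=None,
        dropout=0.0,
        learning_rate=1e-3,
        batch_size=32,
        max_epochs=50,
        patience=8,
        subsample_fraction=0.5,
        seed=0,
    ):
        self.hidden_reduce = hidden_reduce
        self.hidden_joint = hidden_joint
        self.attention = attention
        self.spectral_norm = spectral_norm
        self.n_heads = n_heads
        self.ff_dim = ff_dim
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.subsample_fraction = subsample_fraction
        self.seed = seed

    def fit(self, X, y, validation=None, log_fn=None):
        first = np.asarray(next(iter(X))[0])
        if first.ndim != 1:
            raise TypeError(
                "Richoux consumes per-protein vectors; got a matrix input"
            )
        return super().fit(X, y, validation=validation, log_fn=log_fn)

    def _build_net(self, d_emb: int) -> Module:
        return models.RichouxNet(
            d_emb,
            hidden_reduce=self.hidden_reduce,
            hidden_joint=self.hidden_joint,
            attention=self.attention,
            spectral_norm=self.spectral_norm,
            n_heads=self.n_heads,
            ff_dim=self.ff_dim,
            dropout=self.dropout,
            seed=self.seed,
        )


class DScriptClassifier(_NeuralPairClassifier):
    """Pair-feature convolutional classifier with an interaction module."""

    input_kind = "token"
    exposes_map = True

    def __init__(
        self,
        d=None,
        h=None,
        kernel_size=3,
        dropout=0.1,
        attention="none",
        encoder_position="none",
        spectral_norm=True,
        n_heads=8,
        ff_dim=None,
        pool_kernel=None,
        learning_rate=1e-3,
        batch_size=16,
        max_epochs=50,
        patience=8,
        subsample_fraction=0.5,
        seed=0,
    ):
        self.d = d
        self.h = h
        self.kernel_size = kernel_size
        self.dropout = dropout
        self.attention = attention
        self.encoder_position = encoder_position
        self.spectral_norm = spectral_norm
        self.n_heads = n_heads
        self.ff_dim = ff_dim
        self.pool_kernel = pool_kernel
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.subsample_fraction = subsample_fraction
        self.seed = seed

    def _build_net(self, d_emb: int) -> Module:
        return models.DScriptNet(
            d_emb,
            d=self.d,
            h=self.h,
            kernel_size=self.kernel_size,
            dropout=self.dropout,
            attention=self.attention,
            encoder_position=self.encoder_position,
            spectral_norm=self.spectral_norm,
            n_heads=self.n_heads,
            ff_dim=self.ff_dim,
            pool_kernel=self.pool_kernel,
            seed=self.seed,
        )


class TunaClassifier(_NeuralPairClassifier):
    """Transformer-encoder classifier with an uncertainty-aware GP head."""

    input_kind = "token"
    exposes_map = False

    def __init__(
        self,
        d_att=64,
        n_heads=8,
        ff_dim=None,
        dropout=0.1,
        padded=True,
        pad_len=1000,
        attention="self",
        spectral_norm=True,
        n_rff=256,
        learning_rate=1e-3,
        batch_size=16,
        max_epochs=50,
        patience=8,
        subsample_fraction=0.5,
        seed=0,
    ):
        self.d_att = d_att
        self.n_heads = n_heads
        self.ff_dim = ff_dim
        self.dropout = dropout
        self.padded = padded
        self.pad_len = pad_len
        self.attention = attention
        self.spectral_norm = spectral_norm
        self.n_rff = n_rff
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.subsample_fraction = subsample_fraction
        self.seed = seed

    def _build_net(self, d_emb: int) -> Module:
        return models.TunaNet(
            d_emb,
            d_att=self.d_att,
            n_heads=self.n_heads,
            ff_dim=self.ff_dim,
            dropout=self.dropout,
            padded=self.padded,
            pad_len=self.pad_len,
            attention=self.attention,
            spectral_norm=self.spectral_norm,
            n_rff=self.n_rff,
            seed=self.seed,
        )

    def predict_uncertainty(self, X) -> np.ndarray:
        """Predictive variances of the GP head (always >= 0)."""
        self._check_fitted()
        self.net_.eval()
        return np.array(
            [self.net_(a, b)[1] for a, b in _as_pair_list(X)], dtype=float
        )


class RandomForestPairClassifier(BaseEstimator, ClassifierMixin):
    """Random-forest baseline on concatenated per-protein embeddings.

    100 trees; with ``feature_rule='all'`` each split sees the full
    ``2 * f_in`` concatenated feature vector (randomness enters through
    bootstrap only), ``'sqrt'`` uses the common square-root rule.
    """

    input_kind = "protein"
    exposes_map = False

    def __init__(self, n_trees=100, feature_rule="all", seed=0):
        self.n_trees = n_trees
        self.feature_rule = feature_rule
        self.seed = seed

    @staticmethod
    def _features(X) -> np.ndarray:
        rows = []
        width = None
        for a, b in X:
            v = np.concatenate([np.asarray(a, float).ravel(), np.asarray(b, float).ravel()])
            if width is None:
                width = v.size
            elif v.size != width:
                raise ValueError("inconsistent feature lengths across pairs")
            rows.append(v)
        return np.vstack(rows)

    def fit(self, X, y, validation=None, log_fn=None):
        if self.feature_rule not in ("all", "sqrt"):
            raise ValueError("feature_rule must be 'all' or 'sqrt'")
        feats = self._features(X)
        self.d_emb_ = feats.shape[1] // 2
        self.classes_ = np.array([0, 1])
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=None if self.feature_rule == "all" else "sqrt",
            random_state=self.seed,
        )
        self.forest_.fit(feats, np.asarray(y, int))
        self.best_epoch_ = None
        return self

    def score_pairs(self, X) -> np.ndarray:
        return self.forest_.predict_proba(self._features(X))[:, 1]

    def predict_proba(self, X) -> np.ndarray:
        s = self.score_pairs(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X) -> np.ndarray:
        return (self.score_pairs(X) > 0.5).astype(int)

    def predict_map(self, X):
        raise MapCapabilityError("random forest has no intermediate map")

    def evaluate(self, X, y, threshold: float = 0.5):
        return evaluate(self.score_pairs(X), np.asarray(y, int), threshold)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------
def _entry(cls, input_kind, pca=None, **params):
    return {"cls": cls, "params": params, "input": input_kind, "pca": pca}


REGISTRY: dict[str, dict] = {
    # baselines
    "RFC-mean": _entry(RandomForestPairClassifier, "protein"),
    "RFC-400": _entry(RandomForestPairClassifier, "protein", pca=200),
    "RFC-40": _entry(RandomForestPairClassifier, "protein", pca=20),
    "2d-baseline": _entry(TwoDInteractionClassifier, "token"),
    # attention variants of the 2d baseline
    "2d-Selfattention": _entry(
        TwoDInteractionClassifier, "token",
        attention="self", encoder_position="post_reduction",
    ),
    "2d-Crossattention": _entry(
        TwoDInteractionClassifier, "token",
        attention="cross", encoder_position="post_reduction", pool="avg",
    ),
    "2d-Selfattention-encoder-pre-reduction": _entry(
        TwoDInteractionClassifier, "token",
        attention="self", encoder_position="pre_reduction",
    ),
    "2d-Crossattention-encoder-pre-reduction": _entry(
        TwoDInteractionClassifier, "token",
        attention="cross", encoder_position="pre_reduction", pool="avg",
    ),
    "2d-Selfattention-no-spectral": _entry(
        TwoDInteractionClassifier, "token",
        attention="self", encoder_position="post_reduction", spectral_norm=False,
    ),
    "2d-Crossattention-no-spectral": _entry(
        TwoDInteractionClassifier, "token",
        attention="cross", encoder_position="post_reduction", pool="avg",
        spectral_norm=False,
    ),
    # Richoux family
    "Richoux-ESM-2": _entry(RichouxClassifier, "protein"),
    "Richoux-ESM-2-spectral": _entry(
        RichouxClassifier, "protein", spectral_norm=True
    ),
    "Richoux-ESM-2-encoder-spectral": _entry(
        RichouxClassifier, "protein", attention="self", spectral_norm=True
    ),
    "Richoux-ESM-2-encoder-no-spectral": _entry(
        RichouxClassifier, "protein", attention="self", spectral_norm=False
    ),
    # D-SCRIPT family
    "D-SCRIPT-ESM-2": _entry(DScriptClassifier, "token"),
    "D-SCRIPT-ESM-2-encoder-pre-reduction": _entry(
        DScriptClassifier, "token",
        attention="self", encoder_position="pre_reduction",
    ),
    "D-SCRIPT-ESM-2-encoder-post-reduction": _entry(
        DScriptClassifier, "token",
        attention="self", encoder_position="post_reduction",
    ),
    "D-SCRIPT-ESM-2-encoder-pre-reduction-no-spectral": _entry(
        DScriptClassifier, "token",
        attention="self", encoder_position="pre_reduction", spectral_norm=False,
    ),
    "D-SCRIPT-ESM-2-encoder-cross": _entry(
        DScriptClassifier, "token",
        attention="cross", encoder_position="post_reduction",
    ),
    # TUnA family
    "TUnA": _entry(TunaClassifier, "token"),
    "TUnA-unpadded": _entry(TunaClassifier, "token", padded=False),
    "TUnA-crossattention": _entry(TunaClassifier, "token", attention="cross"),
    "TUnA-no-spectral": _entry(TunaClassifier, "token", spectral_norm=False),
}


def registry_names() -> list[str]:
    return sorted(REGISTRY)


def _get_entry(name: str) -> dict:
    if name not in REGISTRY:
        raise KeyError(
            f"unknown model {name!r}; valid names: {', '.join(registry_names())}"
        )
    return REGISTRY[name]


def make_model(name: str, **overrides):
    """Instantiate a registry model by its published name."""
    entry = _get_entry(name)
    params = dict(entry["params"])
    params.update(overrides)
    return entry["cls"](**params)


def registry_input_kind(name: str) -> str:
    return _get_entry(name)["input"]


def registry_pca_components(name: str) -> int | None:
    return _get_entry(name)["pca"]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------
def save_checkpoint(path, estimator, registry_name: str | None = None) -> None:
    """Single-file archive: architecture config + weights."""
    spec = {
        "class": type(estimator).__name__,
        "registry_name": registry_name,
        "params": estimator.get_params(),
        "d_emb": getattr(estimator, "d_emb_", None),
        "best_epoch": getattr(estimator, "best_epoch_", None),
    }
    arrays = {}
    if hasattr(estimator, "net_"):
        arrays = {f"param::{k}": v for k, v in estimator.net_.state_dict().items()}
    elif hasattr(estimator, "forest_"):
        raise ValueError("random-forest checkpointing is not supported")
    np.savez(path, __spec__=json.dumps(spec, default=list), **arrays)


_CLASSES = {
    cls.__name__: cls
    for cls in (
        TwoDInteractionClassifier,
        RichouxClassifier,
        DScriptClassifier,
        TunaClassifier,
    )
}


def load_checkpoint(path):
    """Rebuild the exact architecture and load its weights."""
    with np.load(path, allow_pickle=False) as data:
        spec = json.loads(str(data["__spec__"]))
        state = {
            k[len("param::"):]: data[k] for k in data.files if k.startswith("param::")
        }
    cls = _CLASSES[spec["class"]]
    params = spec["params"]
    for key in ("reduction_sizes",):
        if isinstance(params.get(key), list):
            params[key] = tuple(params[key])
    est = cls(**params)
    est.d_emb_ = int(spec["d_emb"])
    est.classes_ = np.array([0, 1])
    est.net_ = est._build_net(est.d_emb_)
    est.net_.load_state_dict(state)
    est.net_.eval()
    est.best_epoch_ = spec.get("best_epoch")
    return est
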