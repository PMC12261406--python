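"""Shared training protocol and metric suite.

Every deep model is trained the same way: binary cross entropy, Adam
(default betas), a fresh random 50% subsample of the training split
per epoch, validation accuracy monitored each epoch, the
best-validation weights retained, and early stopping once the
validation accuracy has not improved for ``patience`` (default 8)
epochs.  Ties in validation accuracy keep the earlier epoch, so the
reported best epoch is well defined.

Per-token models process samples one at a time (sequences have
different lengths, no padding) while the loss is backpropagated for
the whole batch at once; per-protein models batch normally.
"""

from __future__ import annotations

import copy
import dataclasses
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import average_precision_score

from .autograd import Tensor, stack
from .nn import Adam, Module

__all__ = [
    "TrainConfig",
    "MetricReport",
    "TrainingHistory",
    "fit_network",
    "forward_unpadded_batch",
    "predict_scores",
    "batch_scores",
    "batch_logits",
    "bce_from_logits",
    "evaluate",
]

Sample = tuple[np.ndarray, np.ndarray, int]  # (input A, input B, label)


@dataclasses.dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 50
    patience: int = 8
    subsample_fraction: float = 0.5
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")


@dataclasses.dataclass
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    aupr: float
    bce_loss: float
    n: int
    degenerate: bool = False
    best_epoch: int | None = None

    def as_row(self) -> dict[str, float | int | None]:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class TrainingHistory:
    train_loss: list[float]
    val_accuracy: list[float]
    best_epoch: int  # 1-based
    n_epochs: int

    @property
    def best_val_accuracy(self) -> float:
        return self.val_accuracy[self.best_epoch - 1]

    @property
    def final_val_accuracy(self) -> float:
        return self.val_accuracy[-1]


# ---------------------------------------------------------------------------
# forward helpers
# ---------------------------------------------------------------------------
def forward_unpadded_batch(net: Module, samples: Sequence[Sample]) -> Tensor:
    """Per-sample forward passes stacked into one graph.

    Each sample is pushed through the network on its own (inputs have
    different shapes), but all scores live in a single autodiff graph,
    so one backward pass on the batch loss accumulates exactly the
    gradient of the mean loss over the batch.
    """
    scores = [net.score_pair(a, b) for a, b, _ in samples]
    return stack(scores, axis=0)


def batch_scores(net: Module, samples: Sequence[Sample]) -> Tensor:
    """Scores for a batch; vectorized when the net supports 2-D batches."""
    if getattr(net, "batched_input", False):
        a = np.stack([s[0] for s in samples])
        b = np.stack([s[1] for s in samples])
        return net(a, b)
    return forward_unpadded_batch(net, samples)


def batch_logits(net: Module, samples: Sequence[Sample]) -> Tensor:
    """Pre-sigmoid logits for a batch (the numerically safe training path)."""
    if getattr(net, "batched_input", False):
        a = np.stack([s[0] for s in samples])
        b = np.stack([s[1] for s in samples])
        return net.forward_logits(a, b)
    return stack([net.logit_pair(a, b) for a, b, _ in samples], axis=0)


def bce_from_scores(scores: Tensor, labels: np.ndarray, eps: float = 1e-12) -> Tensor:
    labels = np.asarray(labels, dtype=np.float64)
    s = scores * (1.0 - 2.0 * eps) + eps
    ll = Tensor(labels) * s.log() + Tensor(1.0 - labels) * (1.0 - s).log()
    return -ll.mean()


def bce_from_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean BCE computed from logits: softplus(z) - y*z (saturation-safe)."""
    labels = np.asarray(labels, dtype=np.float64)
    return (logits.softplus() - Tensor(labels) * logits).mean()


def predict_scores(net: Module, samples: Sequence[Sample]) -> np.ndarray:
    net.eval()
    return batch_scores(net, samples).data.copy()


def _accuracy(scores: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    pred = (scores > threshold).astype(int)  # strict: a tie scores label 0
    return float((pred == np.asarray(labels)).mean())


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------
def fit_network(
    net: Module,
    train_samples: Sequence[Sample],
    val_samples: Sequence[Sample],
    config: TrainConfig,
    val_accuracy_fn: Callable[[Module], float] | None = None,
    log_fn: Callable[[str], None] | None = None,
) -> TrainingHistory:
    """Train ``net`` under the shared protocol; restores the best weights."""
    if len(train_samples) == 0:
        raise ValueError("empty training split")
    if len(val_samples) == 0 and val_accuracy_fn is None:
        raise ValueError("empty validation split")
    opt = Adam(net.parameters(), lr=config.learning_rate)
    n_sub = max(1, int(config.subsample_fraction * len(train_samples)))
    val_labels = np.array([y for _, _, y in val_samples])

    history = TrainingHistory([], [], best_epoch=0, n_epochs=0)
    best_acc = -np.inf
    best_state: dict[str, np.ndarray] | None = None

    for epoch in range(1, config.max_epochs + 1):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, epoch]))
        idx = rng.choice(len(train_samples), size=n_sub, replace=False)
        net.train()
        epoch_losses = []
        for start in range(0, n_sub, config.batch_size):
            batch = [train_samples[i] for i in idx[start : start + config.batch_size]]
            logits = batch_logits(net, batch)
            loss = bce_from_logits(logits, np.array([y for _, _, y in batch]))
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(batch starting at {start}): {loss.data}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())

        net.eval()
        if val_accuracy_fn is not None:
            val_acc = float(val_accuracy_fn(net))
        else:
            val_scores = batch_scores(net, val_samples).data
            val_acc = _accuracy(val_scores, val_labels, config.threshold)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_accuracy.append(val_acc)
        history.n_epochs = epoch
        if log_fn is not None:
            log_fn(
                f"epoch={epoch}\ttrain_loss={history.train_loss[-1]:.6f}"
                f"\tval_accuracy={val_acc:.6f}"
            )
        if val_acc > best_acc:  # strict: ties keep the earlier epoch
            best_acc = val_acc
            history.best_epoch = epoch
            best_state = net.state_dict()
        elif epoch - history.best_epoch >= config.patience:
            break

    if best_state is not None:
        net.load_state_dict(best_state)
    net.eval()
    return history


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------
def evaluate(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricReport:
    """Threshold metrics plus threshold-free AUPR and BCE.

    AUPR is the step-wise integral of the precision-recall curve
    (average precision); precision/recall of a degenerate confusion
    matrix are reported as 0 with the ``degenerate`` flag set.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n = len(scores)
    pred = (scores > threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    accuracy = float((pred == labels).mean()) if n else 0.0
    degenerate = (tp + fp == 0) or (tp + fn == 0)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    if labels.min(initial=1) == labels.max(initial=0):
        aupr = float(labels.mean()) if n else 0.0  # single-class edge case
        degenerate = True
    else:
        aupr = float(average_precision_score(labels, scores))
    eps = 1e-12
    s = np.clip(scores, eps, 1 - eps)
    bce = float(-(labels * np.log(s) + (1 - labels) * np.log(1 - s)).mean()) if n else 0.0
    return MetricReport(
        accuracy=accuracy,
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        aupr=aupr,
        bce_loss=bce,
        n=n,
        degenerate=degenerate,
    )
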