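"""Neural building blocks used by the PPI model zoo.

Layers follow the familiar module pattern: a :class:`Module` owns
parameters (:class:`~ppibench.autograd.Tensor` with ``requires_grad``),
exposes ``train()``/``eval()`` and recursive ``parameters()``, and is
called like a function.  Initialisation is driven entirely by a
``numpy.random.Generator`` so every model is a pure function of its
seed.

Spectral normalization follows the usual power-iteration recipe: one
iteration per forward pass with persistent left/right vectors, the
estimated top singular value treated as a constant in the backward
pass.  The standalone :func:`spectral_normalize` runs power iteration
to convergence and is the operation the contract tests probe.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "BatchNorm",
    "Dropout",
    "MultiHeadAttention",
    "EncoderBlock",
    "Conv2D",
    "max_pool2d",
    "avg_pool2d",
    "softmax",
    "spectral_normalize",
    "Adam",
    "bce_loss",
]


# ---------------------------------------------------------------------------
# module machinery
# ---------------------------------------------------------------------------
class Module:
    """Base class: parameter discovery, train/eval mode, state export.

    Subclasses may list non-trainable state (running statistics,
    power-iteration vectors) in ``_buffers``; it is exported and
    restored alongside the parameters so eval-mode behaviour survives
    checkpointing and best-weights restoration.
    """

    _buffers: tuple[str, ...] = ()

    def __init__(self):
        self.training = True

    def modules(self) -> Iterable["Module"]:
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def _walk_modules(self) -> list[tuple[str, "Module"]]:
        out: list[tuple[str, Module]] = []

        def walk(mod: Module, prefix: str) -> None:
            out.append((prefix, mod))
            for name, value in mod.__dict__.items():
                full = f"{prefix}{name}"
                if isinstance(value, Module):
                    walk(value, full + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            walk(item, f"{full}.{i}.")

        walk(self, "")
        return out

    def named_parameters(self) -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        seen: set[int] = set()
        for prefix, mod in self._walk_modules():
            for name, value in mod.__dict__.items():
                if isinstance(value, Tensor) and value.requires_grad:
                    if id(value) not in seen:
                        seen.add(id(value))
                        out.append((f"{prefix}{name}", value))
        return out

    def named_buffers(self) -> list[tuple[str, "Module", str]]:
        out = []
        for prefix, mod in self._walk_modules():
            for name in mod._buffers:
                if getattr(mod, name, None) is not None:
                    out.append((f"{prefix}{name}", mod, name))
        return out

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, mod, attr in self.named_buffers():
            state[f"buffer::{name}"] = np.asarray(getattr(mod, attr)).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {f"buffer::{name}": (mod, attr) for name, mod, attr in self.named_buffers()}
        missing = (set(params) | set(buffers)) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data[...] = state[name]
        for key, (mod, attr) in buffers.items():
            setattr(mod, attr, state[key].copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


# ---------------------------------------------------------------------------
# spectral normalization
# ---------------------------------------------------------------------------
def spectral_normalize(
    weight: np.ndarray, n_iter: int = 200, tol: float = 1e-10
) -> tuple[np.ndarray, bool]:
    """Divide ``weight`` by its largest singular value (power iteration).

    Returns ``(normalized, degenerate)``; an all-zero matrix passes
    through unchanged with ``degenerate=True``.
    """
    w = np.asarray(weight, dtype=np.float64)
    if w.ndim != 2:
        raise ValueError("spectral_normalize expects a 2-D weight matrix")
    if not np.any(w):
        return w.copy(), True
    rng = np.random.default_rng(0)
    u = rng.standard_normal(w.shape[0])
    u /= np.linalg.norm(u)
    sigma = 0.0
    for _ in range(n_iter):
        v = w.T @ u
        v /= np.linalg.norm(v)
        u = w @ v
        nu = np.linalg.norm(u)
        u /= nu
        if abs(nu - sigma) < tol * max(1.0, sigma):
            sigma = nu
            break
        sigma = nu
    return w / sigma, False


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------
class Linear(Module):
    """Affine map ``x @ W + b`` with optional spectral normalization.

    ``W`` has shape (in_features, out_features); initialisation is
    Kaiming-uniform in fan-in, which behaves well under the ReLU stacks
    used throughout the zoo.
    """

    _buffers = ("_u",)

    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator,
        spectral: bool = False,
    ):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        bound = math.sqrt(6.0 / in_features)
        self.W = Tensor(
            rng.uniform(-bound, bound, size=(in_features, out_features)),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(out_features), requires_grad=True)
        self.spectral = spectral
        if spectral:
            u = rng.standard_normal(in_features)
            self._u = u / np.linalg.norm(u)

    def _sigma(self) -> float:
        # one power-iteration step on the raw weight; the persistent
        # vector advances only in training mode so eval passes are
        # deterministic and repeatable
        w = self.W.data
        v = w.T @ self._u
        v_norm = np.linalg.norm(v)
        if v_norm == 0.0:
            return 1.0
        v /= v_norm
        u = w @ v
        u_norm = np.linalg.norm(u)
        if u_norm == 0.0:
            return 1.0
        u = u / u_norm
        if self.training:
            self._u = u
        return float(u @ w @ v)

    def effective_weight(self) -> np.ndarray:
        """The weight actually applied at the next forward pass (eval view)."""
        if not self.spectral:
            return self.W.data.copy()
        normalized, _ = spectral_normalize(self.W.data)
        return normalized

    def converge_spectral(self, n_iter: int = 100) -> None:
        """Run extra power-iteration steps (tightens the sigma estimate)."""
        if not self.spectral:
            return
        w = self.W.data
        for _ in range(n_iter):
            v = w.T @ self._u
            norm_v = np.linalg.norm(v)
            if norm_v == 0.0:
                return
            u = w @ (v / norm_v)
            norm_u = np.linalg.norm(u)
            if norm_u == 0.0:
                return
            self._u = u / norm_u

    def forward(self, x: Tensor) -> Tensor:
        w = self.W
        if self.spectral:
            sigma = self._sigma()
            if sigma != 0.0:
                w = w * (1.0 / sigma)
        return x @ w + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.dim = dim
        self.eps = eps
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gain + self.bias


class BatchNorm(Module):
    """Normalize over all axes except the last (feature/channel) axis.

    Training mode uses the statistics of the current tensor and updates
    exponential running estimates; eval mode applies the running
    estimates.  With the unpadded per-sample regime the "batch" for a
    per-token model is the spatial extent of a single sample.
    """

    _buffers = ("running_mean", "running_var")

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.gain = Tensor(np.ones(num_features), requires_grad=True)
        self.bias = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            inv = (var + self.eps) ** -0.5
            return centered * inv * self.gain + self.bias
        mu = Tensor(self.running_mean)
        inv = Tensor(1.0 / np.sqrt(self.running_var + self.eps))
        return (x - mu) * inv * self.gain + self.bias


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant, for stability
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadAttention(Module):
    def __init__(
        self,
        dim: int,
        n_heads: int,
        rng: np.random.Generator,
        spectral: bool = False,
    ):
        super().__init__()
        if dim % n_heads != 0:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.dim = dim
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.wq = Linear(dim, dim, rng, spectral)
        self.wk = Linear(dim, dim, rng, spectral)
        self.wv = Linear(dim, dim, rng, spectral)
        self.wo = Linear(dim, dim, rng, spectral)

    def _split(self, x: Tensor, length: int) -> Tensor:
        # (L, dim) -> (heads, L, d_head)
        return x.reshape(length, self.n_heads, self.d_head).transpose(1, 0, 2)

    def forward(
        self,
        query: Tensor,
        keyvalue: Tensor,
        key_mask: np.ndarray | None = None,
    ) -> Tensor:
        lq = query.shape[0]
        lk = keyvalue.shape[0]
        q = self._split(self.wq(query), lq)
        k = self._split(self.wk(keyvalue), lk)
        v = self._split(self.wv(keyvalue), lk)
        scores = (q @ k.T) * (1.0 / math.sqrt(self.d_head))  # (h, Lq, Lk)
        if key_mask is not None:
            key_mask = np.asarray(key_mask, dtype=bool)
            if key_mask.shape != (lk,):
                raise ValueError("key mask length does not match context length")
            if not key_mask.any():
                raise ValueError("attention context is fully masked")
            bias = np.where(key_mask, 0.0, -1e30)
            scores = scores + Tensor(bias)
        attn = softmax(scores, axis=-1)
        out = attn @ v  # (h, Lq, d_head)
        out = out.transpose(1, 0, 2).reshape(lq, self.dim)
        return self.wo(out)


class EncoderBlock(Module):
    """Post-norm transformer encoder block (attention + FFN, residuals).

    ``mode='self'`` attends within the input; ``mode='cross'`` draws
    keys/values from a context sequence.  Boolean masks flag valid
    positions; masked positions neither contribute keys nor propagate
    into unmasked outputs (per-position LayerNorm and FFN keep rows
    independent).
    """

    def __init__(
        self,
        dim: int,
        n_heads: int,
        ff_dim: int,
        dropout: float,
        rng: np.random.Generator,
        spectral: bool = True,
    ):
        super().__init__()
        self.attn = MultiHeadAttention(dim, n_heads, rng, spectral)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_dim, rng, spectral)
        self.ff2 = Linear(ff_dim, dim, rng, spectral)
        self.drop = Dropout(dropout, rng)

    def forward(
        self,
        x: Tensor,
        context: Tensor | None = None,
        key_mask: np.ndarray | None = None,
        mode: str = "self",
    ) -> Tensor:
        if mode == "self":
            kv = x
        elif mode == "cross":
            if context is None:
                raise ValueError("cross mode requires a context sequence")
            kv = context
        else:
            raise ValueError(f"unknown attention mode {mode!r}")
        h = x + self.drop(self.attn(x, kv, key_mask=key_mask))
        h = self.norm1(h)
        h = h + self.drop(self.ff2(self.ff1(h).relu()))
        return self.norm2(h)


class Conv2D(Module):
    """2-D convolution on channels-last maps, stride 1, no padding.

    Input (H, W, C_in) -> output (H-k+1, W-k+1, C_out).  Implemented as
    a sum of shifted slice-matmuls so the autodiff engine handles the
    backward pass.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
    ):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = kernel_size * kernel_size * in_channels
        bound = math.sqrt(6.0 / fan_in)
        self.W = Tensor(
            rng.uniform(
                -bound, bound, size=(kernel_size, kernel_size, in_channels, out_channels)
            ),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(out_channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        h, w, _ = x.shape
        k = self.kernel_size
        if h < k or w < k:
            raise ValueError(
                f"input {h}x{w} smaller than convolution kernel {k}"
            )
        oh, ow = h - k + 1, w - k + 1
        out = None
        for di in range(k):
            for dj in range(k):
                patch = x[di : di + oh, dj : dj + ow, :]
                term = patch @ self.W[di, dj]
                out = term if out is None else out + term
        return out + self.b


def _pool(x: Tensor, k: int, reduce: str) -> Tensor:
    """Non-overlapping k x k pooling on an (H, W) map (edges cropped)."""
    h, w = x.shape
    if h < k or w < k:
        raise ValueError(f"map {h}x{w} smaller than pooling kernel {k}")
    hh, ww = (h // k) * k, (w // k) * k
    x = x[:hh, :ww]
    x = x.reshape(hh // k, k, ww // k, k)
    if reduce == "max":
        return x.max(axis=3).max(axis=1)
    return x.mean(axis=3).mean(axis=1)


def max_pool2d(x: Tensor, k: int) -> Tensor:
    return _pool(x, k, "max")


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    return _pool(x, k, "avg")


def bce_loss(score: Tensor, label: float, eps: float = 1e-12) -> Tensor:
    """Binary cross entropy on a probability score (scalar tensor)."""
    score = score * (1.0 - 2.0 * eps) + eps  # keep the log finite
    if label == 1:
        return -score.log()
    return -(1.0 - score).log()


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------
class Adam:
    """Adam with the standard defaults; only the learning rate is tuned."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g**2
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
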