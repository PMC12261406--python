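"""Architectures compared in the benchmark.

All families consume precomputed language-model embeddings and emit an
interaction probability; the map families additionally expose an
``(L1', L2')`` single-channel intermediate grid that can be read as an
implicit inter-chain distance/contact map.

Families
--------
``TwoDNet``
    Per-token baseline: shared three-layer ReLU reduction of the
    embedding dimension, channel-wise outer product of the two reduced
    matrices, one-channel convolution over the resulting grid, pooling,
    global max, sigmoid.  Attention variants insert a (spectrally
    normalized) transformer encoder before or after the reduction,
    with self- or cross-attention.
``RichouxNet``
    Per-protein fully connected classifier: unshared reduction layer
    per protein, concatenation, two joint layers down to width 1,
    sigmoid; every hidden layer followed by ReLU and batch norm.
``DScriptNet``
    Per-token: linear projection, broadcast |difference| / product pair
    features, two convolutions with batch norm + ReLU down to a
    single-channel map, then a pooled interaction module.
``TunaNet``
    Per-token, uncertainty-aware: shared intra-protein encoder,
    inter-protein encoder over both concatenation orders, masked means,
    position-wise max, and a random-Fourier-feature Gaussian-process
    head.  Symmetric in its two inputs by construction.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, as_tensor, concat, maximum, stack
from .nn import (
    Adam,
    BatchNorm,
    Conv2D,
    Dropout,
    EncoderBlock,
    LayerNorm,
    Linear,
    Module,
    avg_pool2d,
    max_pool2d,
    spectral_normalize,
)

__all__ = [
    "pairwise_outer_product",
    "dscript_pair_features",
    "InteractionModule",
    "RFEGPHead",
    "TwoDNet",
    "RichouxNet",
    "DScriptNet",
    "TunaNet",
    "default_reduction_sizes",
]


def default_reduction_sizes(d_emb: int) -> tuple[int, int, int]:
    """The 2d-family reduction ladder: d_emb/2, d_emb/4, 64."""
    return (max(1, d_emb // 2), max(1, d_emb // 4), 64)


# ---------------------------------------------------------------------------
# pair-combination ops
# ---------------------------------------------------------------------------
def pairwise_outer_product(a: Tensor | np.ndarray, b: Tensor | np.ndarray) -> Tensor:
    """Channel-wise outer product: ``T[i, j, c] = A[i, c] * B[j, c]``."""
    a, b = as_tensor(a), as_tensor(b)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError(
            f"feature dimensions must match, got {a.shape} and {b.shape}"
        )
    l1, k = a.shape
    l2 = b.shape[0]
    return a.reshape(l1, 1, k) * b.reshape(1, l2, k)


def dscript_pair_features(a: Tensor | np.ndarray, b: Tensor | np.ndarray) -> Tensor:
    """``F[i, j] = concat(|A[i] - B[j]|, A[i] * B[j])`` -> (L1, L2, 2d)."""
    a, b = as_tensor(a), as_tensor(b)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError(
            f"feature dimensions must match, got {a.shape} and {b.shape}"
        )
    l1, d = a.shape
    l2 = b.shape[0]
    ai = a.reshape(l1, 1, d)
    bj = b.reshape(1, l2, d)
    return concat([(ai - bj).abs(), ai * bj], axis=2)


class InteractionModule(Module):
    """Map -> probability: weighted max pooling, normalization, sigmoid.

    The map is scaled by a learned positive weight, max-pooled, and the
    pooled values are averaged (normalized by the pooled count, see the
    methods note for the choice of denominator) before a sigmoid with
    learnable positive gain and offset.  An all-zero map scores exactly
    ``sigmoid(offset)``.
    """

    def __init__(self, pool_kernel: int = 3, normalize: str = "all"):
        super().__init__()
        if normalize not in ("all", "nonzero"):
            raise ValueError("normalize must be 'all' or 'nonzero'")
        self.pool_kernel = pool_kernel
        self.normalize = normalize
        self.log_weight = Tensor(np.zeros(()), requires_grad=True)
        self.log_gain = Tensor(np.zeros(()), requires_grad=True)
        self.offset = Tensor(np.zeros(()), requires_grad=True)

    def logit(self, pair_map: Tensor | np.ndarray) -> Tensor:
        pair_map = as_tensor(pair_map)
        if pair_map.ndim != 2 or pair_map.data.size == 0:
            raise ValueError("interaction module expects a non-empty 2-D map")
        h, w = pair_map.shape
        k = min(self.pool_kernel, h, w)
        weighted = pair_map * self.log_weight.exp()
        pooled = max_pool2d(weighted, k)
        if self.normalize == "all":
            stat = pooled.mean()
        else:
            n_nonzero = max(1, int(np.count_nonzero(pooled.data)))
            stat = pooled.sum() * (1.0 / n_nonzero)
        return self.log_gain.exp() * stat + self.offset

    def forward(self, pair_map: Tensor | np.ndarray) -> Tensor:
        return self.logit(pair_map).sigmoid()


class RFEGPHead(Module):
    """Random-Fourier-feature Gaussian-process readout.

    ``phi(v) = sqrt(2/D) cos(W v + b)`` with ``W ~ N(0, I/lengthscale^2)``
    and ``b ~ U(0, 2pi)`` fixed at construction approximates an RBF
    kernel; a trainable linear readout on ``phi`` gives the mean logit.
    The predictive variance is ``phi^T Lambda^{-1} phi`` with ``Lambda``
    a ridge-regularized running feature second-moment accumulated over
    the training inputs.
    """

    _buffers = ("_precision",)

    def __init__(
        self,
        in_dim: int,
        n_features: int = 1024,
        rng: np.random.Generator | None = None,
        lengthscale: float = 1.0,
        ridge: float = 1.0,
    ):
        super().__init__()
        if n_features < 1:
            raise ValueError("n_features must be >= 1")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.n_features = n_features
        self.omega = rng.standard_normal((in_dim, n_features)) / lengthscale
        self.phase = rng.uniform(0.0, 2.0 * math.pi, size=n_features)
        self.readout = Linear(n_features, 1, rng)
        self.ridge = ridge
        self._precision = ridge * np.eye(n_features)

    def features(self, v: Tensor | np.ndarray) -> Tensor:
        v = as_tensor(v)
        return math.sqrt(2.0 / self.n_features) * (
            v @ Tensor(self.omega) + Tensor(self.phase)
        ).cos()

    def update_precision(self, phi: np.ndarray) -> None:
        self._precision += np.outer(phi, phi)

    def variance(self, phi: np.ndarray) -> float:
        return float(phi @ np.linalg.solve(self._precision, phi))

    def forward(self, v: Tensor | np.ndarray) -> tuple[Tensor, float]:
        phi = self.features(v)
        logit = self.readout(phi)[0]
        if self.training:
            self.update_precision(phi.data)
        return logit, self.variance(phi.data)


# ---------------------------------------------------------------------------
# 2d family
# ---------------------------------------------------------------------------
class TwoDNet(Module):
    def __init__(
        self,
        d_emb: int,
        reduction_sizes: tuple[int, ...] | None = None,
        attention: str = "none",  # none | self | cross
        encoder_position: str = "none",  # none | pre_reduction | post_reduction
        spectral_norm: bool = True,
        kernel_size: int = 3,
        pool: str = "max",
        pool_kernel: int | None = None,
        n_heads: int = 8,
        ff_dim: int | None = None,
        dropout: float = 0.1,
        seed: int = 0,
    ):
        super().__init__()
        if attention not in ("none", "self", "cross"):
            raise ValueError(f"unknown attention mode {attention!r}")
        if encoder_position not in ("none", "pre_reduction", "post_reduction"):
            raise ValueError(f"unknown encoder position {encoder_position!r}")
        if (attention == "none") != (encoder_position == "none"):
            raise ValueError("attention mode and encoder position must agree")
        if pool not in ("max", "avg"):
            raise ValueError("pool must be 'max' or 'avg'")
        rng = np.random.default_rng(seed)
        sizes = tuple(reduction_sizes or default_reduction_sizes(d_emb))
        self.attention = attention
        self.encoder_position = encoder_position
        self.kernel_size = kernel_size
        self.pool = pool
        # pooling kernel follows the convolution kernel unless tuned apart
        self.pool_kernel = pool_kernel if pool_kernel is not None else kernel_size
        dims = (d_emb,) + sizes
        self.reduce_layers = [
            Linear(dims[i], dims[i + 1], rng) for i in range(len(sizes))
        ]
        self.encoder = None
        if attention != "none":
            enc_dim = d_emb if encoder_position == "pre_reduction" else sizes[-1]
            heads = n_heads if enc_dim % n_heads == 0 else math.gcd(enc_dim, n_heads)
            self.encoder = EncoderBlock(
                enc_dim,
                max(1, heads),
                ff_dim or 4 * enc_dim,
                dropout,
                rng,
                spectral=spectral_norm,
            )
        self.conv = Conv2D(sizes[-1], 1, kernel_size, rng)

    def _reduce(self, x: Tensor) -> Tensor:
        for layer in self.reduce_layers:
            x = layer(x).relu()
        return x

    def _encode_pair(self, xa: Tensor, xb: Tensor) -> tuple[Tensor, Tensor]:
        if self.attention == "self":
            return self.encoder(xa), self.encoder(xb)
        return (
            self.encoder(xa, context=xb, mode="cross"),
            self.encoder(xb, context=xa, mode="cross"),
        )

    def _logit(self, emb_a, emb_b) -> tuple[Tensor, Tensor]:
        xa, xb = as_tensor(emb_a), as_tensor(emb_b)
        if self.encoder_position == "pre_reduction":
            xa, xb = self._encode_pair(xa, xb)
        xa, xb = self._reduce(xa), self._reduce(xb)
        if self.encoder_position == "post_reduction":
            xa, xb = self._encode_pair(xa, xb)
        grid = pairwise_outer_product(xa, xb)
        conv_out = self.conv(grid)  # (L1', L2', 1)
        pair_map = conv_out.reshape(conv_out.shape[0], conv_out.shape[1])
        k = min(self.pool_kernel, pair_map.shape[0], pair_map.shape[1])
        pooled = max_pool2d(pair_map, k) if self.pool == "max" else avg_pool2d(pair_map, k)
        return pooled.max(), pair_map

    def forward(self, emb_a, emb_b) -> tuple[Tensor, Tensor]:
        """Returns (score, intermediate_map)."""
        logit, pair_map = self._logit(emb_a, emb_b)
        return logit.sigmoid(), pair_map

    def logit_pair(self, emb_a, emb_b) -> Tensor:
        return self._logit(emb_a, emb_b)[0]

    def score_pair(self, emb_a, emb_b) -> Tensor:
        return self.forward(emb_a, emb_b)[0]


# ---------------------------------------------------------------------------
# Richoux family (per-protein vectors)
# ---------------------------------------------------------------------------
class RichouxNet(Module):
    batched_input = True  # consumes (N, d_emb) stacks, scores a batch at once

    def __init__(
        self,
        d_emb: int,
        hidden_reduce: int | None = None,
        hidden_joint: int | None = None,
        attention: str = "none",  # none | self
        spectral_norm: bool = False,
        n_heads: int = 8,
        ff_dim: int | None = None,
        dropout: float = 0.0,
        seed: int = 0,
    ):
        super().__init__()
        rng = np.random.default_rng(seed)
        h1 = hidden_reduce or d_emb
        h2 = hidden_joint or d_emb
        self.attention = attention
        self.encoder = None
        if attention == "self":
            heads = n_heads if d_emb % n_heads == 0 else math.gcd(d_emb, n_heads)
            self.encoder = EncoderBlock(
                d_emb, max(1, heads), ff_dim or 4 * d_emb, dropout, rng,
                spectral=spectral_norm,
            )
        elif attention != "none":
            raise ValueError("Richoux family supports attention in {'none','self'}")
        # two unshared reduction layers per protein, then two joint layers,
        # the last of width 1; ReLU + batch norm follow every hidden layer
        self.reduce_a = [
            Linear(d_emb, h1, rng, spectral_norm),
            Linear(h1, h1, rng, spectral_norm),
        ]
        self.reduce_b = [
            Linear(d_emb, h1, rng, spectral_norm),
            Linear(h1, h1, rng, spectral_norm),
        ]
        self.bn_a = [BatchNorm(h1), BatchNorm(h1)]
        self.bn_b = [BatchNorm(h1), BatchNorm(h1)]
        self.joint1 = Linear(2 * h1, h2, rng, spectral_norm)
        self.bn_joint = BatchNorm(h2)
        self.out = Linear(h2, 1, rng, spectral_norm)

    def forward_logits(self, vec_a, vec_b) -> Tensor:
        """Batched: (N, d_emb) inputs -> (N,) pre-sigmoid logits."""
        xa, xb = as_tensor(vec_a), as_tensor(vec_b)
        if xa.ndim != 2 or xb.ndim != 2:
            raise TypeError(
                "Richoux consumes batches of per-protein vectors (N, d_emb); "
                "per-token matrices are not accepted"
            )
        if self.encoder is not None:
            # the two protein vectors form a length-2 sequence per sample
            n = xa.shape[0]
            out_a, out_b = [], []
            for i in range(n):
                seq = stack([xa[i], xb[i]], axis=0)
                enc = self.encoder(seq)
                out_a.append(enc[0])
                out_b.append(enc[1])
            xa = stack(out_a, axis=0)
            xb = stack(out_b, axis=0)
        ha, hb = xa, xb
        for layer, bn in zip(self.reduce_a, self.bn_a):
            ha = bn(layer(ha).relu())
        for layer, bn in zip(self.reduce_b, self.bn_b):
            hb = bn(layer(hb).relu())
        h = concat([ha, hb], axis=1)
        h = self.bn_joint(self.joint1(h).relu())
        return self.out(h).reshape(h.shape[0])

    def forward(self, vec_a, vec_b) -> Tensor:
        """Batched: (N, d_emb) inputs -> (N,) scores."""
        return self.forward_logits(vec_a, vec_b).sigmoid()

    def score_pair(self, vec_a, vec_b) -> Tensor:
        return self.forward(
            as_tensor(vec_a).reshape(1, -1), as_tensor(vec_b).reshape(1, -1)
        )[0]


# ---------------------------------------------------------------------------
# D-SCRIPT family
# ---------------------------------------------------------------------------
class DScriptNet(Module):
    def __init__(
        self,
        d_emb: int,
        d: int | None = None,
        h: int | None = None,
        kernel_size: int = 3,
        dropout: float = 0.1,
        attention: str = "none",  # none | self | cross
        encoder_position: str = "none",  # none | pre_reduction | post_reduction
        spectral_norm: bool = True,
        n_heads: int = 8,
        ff_dim: int | None = None,
        pool_kernel: int | None = None,
        seed: int = 0,
    ):
        super().__init__()
        if attention not in ("none", "self", "cross"):
            raise ValueError(f"unknown attention mode {attention!r}")
        if (attention == "none") != (encoder_position == "none"):
            raise ValueError("attention mode and encoder position must agree")
        rng = np.random.default_rng(seed)
        self.d = d or min(100, d_emb)
        self.h = h or max(1, self.d // 2)
        self.kernel_size = kernel_size
        self.attention = attention
        self.encoder_position = encoder_position
        self.project = Linear(d_emb, self.d, rng)
        self.drop = Dropout(dropout, rng)
        self.encoder = None
        if attention != "none":
            enc_dim = d_emb if encoder_position == "pre_reduction" else self.d
            heads = n_heads if enc_dim % n_heads == 0 else math.gcd(enc_dim, n_heads)
            self.encoder = EncoderBlock(
                enc_dim, max(1, heads), ff_dim or 4 * enc_dim, dropout, rng,
                spectral=spectral_norm,
            )
        self.conv1 = Conv2D(2 * self.d, self.h, kernel_size, rng)
        self.bn1 = BatchNorm(self.h)
        self.conv2 = Conv2D(self.h, 1, kernel_size, rng)
        self.bn2 = BatchNorm(1)
        self.interaction = InteractionModule(pool_kernel or kernel_size)

    def _encode_pair(self, xa: Tensor, xb: Tensor) -> tuple[Tensor, Tensor]:
        if self.attention == "self":
            return self.encoder(xa), self.encoder(xb)
        return (
            self.encoder(xa, context=xb, mode="cross"),
            self.encoder(xb, context=xa, mode="cross"),
        )

    def _logit(self, emb_a, emb_b) -> tuple[Tensor, Tensor]:
        xa, xb = as_tensor(emb_a), as_tensor(emb_b)
        if min(xa.shape[0], xb.shape[0]) < 2 * self.kernel_size - 1:
            raise ValueError(
                "protein shorter than the receptive field of the convolutions"
            )
        if self.encoder_position == "pre_reduction":
            xa, xb = self._encode_pair(xa, xb)
        xa = self.drop(self.project(xa).relu())
        xb = self.drop(self.project(xb).relu())
        if self.encoder_position == "post_reduction":
            xa, xb = self._encode_pair(xa, xb)
        feats = dscript_pair_features(xa, xb)
        hmap = self.bn1(self.conv1(feats)).relu()
        cmap = self.bn2(self.conv2(hmap)).relu()
        pair_map = cmap.reshape(cmap.shape[0], cmap.shape[1])
        return self.interaction.logit(pair_map), pair_map

    def forward(self, emb_a, emb_b) -> tuple[Tensor, Tensor]:
        """Returns (score, intermediate_map); map entries are >= 0."""
        logit, pair_map = self._logit(emb_a, emb_b)
        return logit.sigmoid(), pair_map

    def logit_pair(self, emb_a, emb_b) -> Tensor:
        return self._logit(emb_a, emb_b)[0]

    def score_pair(self, emb_a, emb_b) -> Tensor:
        return self.forward(emb_a, emb_b)[0]


# ---------------------------------------------------------------------------
# TUnA family
# ---------------------------------------------------------------------------
class TunaNet(Module):
    def __init__(
        self,
        d_emb: int,
        d_att: int = 64,
        n_heads: int = 8,
        ff_dim: int | None = None,
        dropout: float = 0.1,
        padded: bool = True,
        pad_len: int = 1000,
        attention: str = "self",  # self | cross (intra encoders)
        spectral_norm: bool = True,
        n_rff: int = 256,
        seed: int = 0,
    ):
        super().__init__()
        if attention not in ("self", "cross"):
            raise ValueError("TUnA attention must be 'self' or 'cross'")
        rng = np.random.default_rng(seed)
        heads = n_heads if d_att % n_heads == 0 else math.gcd(d_att, n_heads)
        self.d_att = d_att
        self.padded = padded
        self.pad_len = pad_len
        self.attention = attention
        self.project = Linear(d_emb, d_att, rng, spectral_norm)
        self.intra = EncoderBlock(
            d_att, max(1, heads), ff_dim or 4 * d_att, dropout, rng, spectral_norm
        )
        self.inter = EncoderBlock(
            d_att, max(1, heads), ff_dim or 4 * d_att, dropout, rng, spectral_norm
        )
        self.head = RFEGPHead(d_att, n_rff, rng)

    def _prepare(self, emb: Tensor) -> tuple[Tensor, np.ndarray]:
        length = emb.shape[0]
        if not self.padded:
            return emb, np.ones(length, dtype=bool)
        if length > self.pad_len:
            raise ValueError(
                f"protein of length {length} exceeds pad_len={self.pad_len}"
            )
        pad = Tensor(np.zeros((self.pad_len - length, emb.shape[1])))
        mask = np.zeros(self.pad_len, dtype=bool)
        mask[:length] = True
        return concat([emb, pad], axis=0), mask

    @staticmethod
    def _masked_mean(x: Tensor, mask: np.ndarray) -> Tensor:
        idx = np.nonzero(mask)[0]
        return x[idx].mean(axis=0)

    def _logit(self, emb_a, emb_b) -> tuple[Tensor, float]:
        xa, mask_a = self._prepare(as_tensor(emb_a))
        xb, mask_b = self._prepare(as_tensor(emb_b))
        xa = self.project(xa)
        xb = self.project(xb)
        if self.attention == "self":
            xa = self.intra(xa, key_mask=mask_a)
            xb = self.intra(xb, key_mask=mask_b)
        else:
            xa, xb = (
                self.intra(xa, context=xb, key_mask=mask_b, mode="cross"),
                self.intra(xb, context=xa, key_mask=mask_a, mode="cross"),
            )
        x12 = concat([xa, xb], axis=0)
        x21 = concat([xb, xa], axis=0)
        mask12 = np.concatenate([mask_a, mask_b])
        mask21 = np.concatenate([mask_b, mask_a])
        e12 = self.inter(x12, key_mask=mask12)
        e21 = self.inter(x21, key_mask=mask21)
        v12 = self._masked_mean(e12, mask12)
        v21 = self._masked_mean(e21, mask21)
        v = maximum(v12, v21)
        return self.head(v)

    def forward(self, emb_a, emb_b) -> tuple[Tensor, float]:
        """Returns (score, predictive variance); symmetric in its inputs."""
        logit, variance = self._logit(emb_a, emb_b)
        return logit.sigmoid(), variance

    def logit_pair(self, emb_a, emb_b) -> Tensor:
        return self._logit(emb_a, emb_b)[0]

    def score_pair(self, emb_a, emb_b) -> Tensor:
        return self.forward(emb_a, emb_b)[0]
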