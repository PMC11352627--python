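"""The four trainable encoder branches.

* sequence: BiLSTM → stacked gMLP blocks per drug, then multi-head
  self-attention over the pointwise sum of the two drugs' sequences;
* molecular graph: a three-part GCN stack (3 layers on the order-1
  support, 2 on the order-2, 1 on the order-3), per-node concatenation,
  global max pooling; applied to drug 1, drug 2 and their block-diagonal
  pair graph, giving H = H_e1 || H_ec || H_e2;
* point cloud: residual 1-D convolutions through channels 3→32→64→128→160
  with batch norm and ReLU, pooled over cloud positions;
* cell line: a feed-forward reduction of z-scored expression factors
  concatenated with binary mutation indicators.

All encoders operate on batched, zero-padded arrays with explicit
position masks, and are deterministic in evaluation mode.
"""

from __future__ import annotations

import numpy as np

from .config import (CellEncoderConfig, CloudEncoderConfig, GraphEncoderConfig,
                     SequenceEncoderConfig)
from .nn import LSTM, BatchNorm1d, Conv1d, Linear, Module, Parameter, Tensor, concatenate
from .nn.layers import glorot

__all__ = [
    "zscore",
    "gcn_layer",
    "GMLPBlock",
    "SequenceDrugEncoder",
    "MultiHeadFusion",
    "GraphEncoder",
    "CloudEncoder",
    "CellEncoder",
    "global_max_pool",
]

_NEG = 1e9  # additive mask constant


def zscore(matrix: np.ndarray, axis: int = 0) -> np.ndarray:
    """Standardise to mean 0, population sd 1 along `axis`.

    Constant slices map to zeros rather than NaN.
    """
    m = np.asarray(matrix, dtype=np.float64)
    if m.size == 0:
        raise ValueError("cannot z-score an empty matrix")
    if not np.all(np.isfinite(m)):
        raise ValueError("z-score requires finite entries")
    mean = m.mean(axis=axis, keepdims=True)
    sd = m.std(axis=axis, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (m - mean) / sd


def gcn_layer(a_norm, h, w) -> Tensor:
    """One graph-convolution layer: ReLU(A_norm · H · W). Batch-aware."""
    a_norm = a_norm if isinstance(a_norm, Tensor) else Tensor(a_norm)
    h = h if isinstance(h, Tensor) else Tensor(h)
    w = w if isinstance(w, Tensor) else Tensor(w)
    return ((a_norm @ h) @ w).relu()


def global_max_pool(h: Tensor, node_mask: np.ndarray | None = None) -> Tensor:
    """Elementwise max over the node axis (axis -2); padded nodes excluded."""
    if node_mask is not None:
        h = h + Tensor((node_mask[..., None] - 1.0) * _NEG)
    return h.max(axis=-2)


class GMLPBlock(Module):
    """One gated-MLP block with a spatial gating unit.

    Z = act(h U); split Z into channel halves Z1, Z2;
    s(Z) = Z1 ⊙ (W Z2 + b) with W a (positions × positions) spatial map;
    Y = s(Z) V. V maps back to the input width so blocks stack.
    """

    def __init__(self, dim: int, gmlp_dim: int, seq_len: int,
                 rng: np.random.Generator, activation: str = "gelu"):
        super().__init__()
        if gmlp_dim % 2:
            raise ValueError(f"gmlp_dim must be even (split in half), got {gmlp_dim}")
        self.dim = dim
        self.gmlp_dim = gmlp_dim
        self.seq_len = seq_len
        self.activation = activation
        half = gmlp_dim // 2
        self.u = Parameter(glorot(rng, dim, gmlp_dim, (dim, gmlp_dim)))
        self.v = Parameter(glorot(rng, half, dim, (half, dim)))
        # near-identity gate at init, as in the gMLP recipe
        self.w_spatial = Parameter(rng.normal(scale=1e-3, size=(seq_len, seq_len)))
        self.b_spatial = Parameter(np.ones((seq_len, 1)))

    def forward(self, h: Tensor) -> Tensor:
        if h.shape[-1] != self.dim:
            raise ValueError(f"expected last dim {self.dim}, got {h.shape}")
        if h.shape[-2] != self.seq_len:
            raise ValueError(
                f"spatial gate is built for {self.seq_len} positions, "
                f"got {h.shape[-2]}")
        z = h @ self.u
        z = z.gelu() if self.activation == "gelu" else z.relu()
        half = self.gmlp_dim // 2
        z1 = z[..., :half]
        z2 = z[..., half:]
        gate = self.w_spatial @ z2 + self.b_spatial
        return (z1 * gate) @ self.v


class SequenceDrugEncoder(Module):
    """BiLSTM over atom features, then a stack of gMLP blocks (per drug).

    Both drugs of a pair share this encoder (Siamese weights). Output is
    per-position with width 2·lstm_units.
    """

    def __init__(self, in_features: int, seq_len: int,
                 cfg: SequenceEncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.seq_len = seq_len
        self.lstm = LSTM(in_features, cfg.lstm_units, rng, bidirectional=True)
        dim = 2 * cfg.lstm_units if cfg.gmlp_input == "full" else cfg.lstm_units
        self.gmlp_input = cfg.gmlp_input
        self.out_dim = dim
        self.blocks = [GMLPBlock(dim, cfg.gmlp_dim, seq_len, rng)
                       for _ in range(cfg.gmlp_layers)]

    def forward(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        h = self.lstm(x, mask=mask)
        if self.gmlp_input == "forward_half":
            h = h[..., :self.cfg.lstm_units]
        for block in self.blocks:
            h = block(h)
        return h


class MultiHeadFusion(Module):
    """Multi-head self-attention fusion of two drug sequence features.

    X_c = H_s1 ⊕ H_s2 (pointwise addition); per head i,
    Attention_i = softmax(Q_i K_iᵀ / √d_k) V_i; heads are concatenated and
    projected by W^o, then pooled over positions to a fixed vector.
    """

    def __init__(self, dim: int, cfg: SequenceEncoderConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.dim = dim
        h, dk = cfg.heads, cfg.head_dim
        self.w_q = [Parameter(glorot(rng, dim, dk, (dim, dk))) for _ in range(h)]
        self.w_k = [Parameter(glorot(rng, dim, dk, (dim, dk))) for _ in range(h)]
        self.w_v = [Parameter(glorot(rng, dim, dk, (dim, dk))) for _ in range(h)]
        self.w_o = Parameter(glorot(rng, h * dk, cfg.attn_out,
                                    (h * dk, cfg.attn_out)))

    def attention(self, x: Tensor, mask: np.ndarray | None = None
                  ) -> tuple[Tensor, list[np.ndarray]]:
        heads, weights = [], []
        scale = 1.0 / np.sqrt(self.cfg.head_dim)
        for wq, wk, wv in zip(self.w_q, self.w_k, self.w_v):
            q = x @ wq
            k = x @ wk
            v = x @ wv
            scores = (q @ k.swapaxes(-1, -2)) * scale
            if mask is not None:
                scores = scores + Tensor((mask[..., None, :] - 1.0) * _NEG)
            attn = scores.softmax(axis=-1)
            weights.append(attn.data)
            heads.append(attn @ v)
        out = concatenate(heads, axis=-1) @ self.w_o
        return out, weights

    def forward(self, h1: Tensor, h2: Tensor,
                mask: np.ndarray | None = None, pool: bool = True) -> Tensor:
        if h1.shape != h2.shape:
            raise ValueError(f"shape mismatch: {h1.shape} vs {h2.shape}")
        x = h1 + h2
        out, _ = self.attention(x, mask=mask)
        if not pool:
            return out
        if self.cfg.seq_pool == "max":
            return global_max_pool(out, mask)
        if mask is None:
            return out.mean(axis=-2)
        m = mask[..., None]
        total = out * Tensor(m)
        return total.sum(axis=-2) / Tensor(m.sum(axis=-2).clip(min=1.0))


class GraphEncoder(Module):
    """Three-part multi-scale GCN with global max pooling.

    Part 1 stacks three GCN layers on the order-1 support, part 2 two
    layers on the order-2 support, part 3 one layer on the order-3
    support; the per-node outputs are concatenated and max-pooled over
    nodes, giving a vector of width 3·width per graph.
    """

    PART_DEPTHS = (3, 2, 1)

    def __init__(self, in_features: int, cfg: GraphEncoderConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        parts = []
        for depth in self.PART_DEPTHS:
            part = []
            d = in_features
            for _ in range(depth):
                part.append(Parameter(glorot(rng, d, cfg.width, (d, cfg.width))))
                d = cfg.width
            parts.append(part)
        self.part1, self.part2, self.part3 = parts
        self.out_dim = 3 * cfg.width

    @property
    def _parts(self) -> tuple:
        return (self.part1, self.part2, self.part3)

    def forward(self, supports: tuple, features: Tensor,
                node_mask: np.ndarray | None = None) -> Tensor:
        """supports: (a1, a2, a3) normalised, each (..., N, N); features (..., N, C)."""
        parts = []
        for support, weights in zip(supports, self._parts):
            a = support if isinstance(support, Tensor) else Tensor(support)
            h = features
            for w in weights:
                h = gcn_layer(a, h, w)
            parts.append(h)
        stacked = concatenate(parts, axis=-1)
        return global_max_pool(stacked, node_mask)


class CloudEncoder(Module):
    """Residual 1-D conv stack over atomic point clouds.

    Channels run 3→32→64→128→160; each stage is Conv1d + BatchNorm1d +
    ReLU with a 1×1-projected residual connection, followed by pooling
    over the n cloud positions to a fixed 160-vector.

    Padding rows are exactly zero; with max pooling, adding more padding
    positions cannot change the output (the zero-input column response is
    already present once any padding exists).
    """

    def __init__(self, cfg: CloudEncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.convs: list[Conv1d] = []
        self.skips: list[Conv1d] = []
        self.norms: list[BatchNorm1d] = []
        c_in = 3
        for c_out in cfg.channels:
            self.convs.append(Conv1d(c_in, c_out, cfg.kernel_size, rng))
            self.skips.append(Conv1d(c_in, c_out, 1, rng))
            self.norms.append(BatchNorm1d(c_out))
            c_in = c_out
        self.out_dim = cfg.channels[-1]

    def forward(self, cloud: Tensor) -> Tensor:
        if cloud.ndim != 3 or cloud.shape[-1] != 3:
            raise ValueError(f"expected (B, n, 3) point cloud, got {cloud.shape}")
        x = cloud.swapaxes(1, 2)  # (B, 3, n)
        for conv, skip, norm in zip(self.convs, self.skips, self.norms):
            x = norm(conv(x)).relu() + skip(x)
        if self.cfg.pool == "mean":
            return x.mean(axis=2)
        return x.max(axis=2)


class CellEncoder(Module):
    """FNN reduction of G' || M (z-scored expression factors + mutations)."""

    def __init__(self, expr_width: int, mut_width: int,
                 cfg: CellEncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.expr_width = expr_width
        self.mut_width = mut_width
        in_width = expr_width + mut_width
        self.fc1 = Linear(in_width, cfg.hidden, rng)
        self.fc2 = Linear(cfg.hidden, cfg.out, rng)
        self.out_dim = cfg.out

    def forward(self, omics: Tensor) -> Tensor:
        """omics: (B, expr_width + mut_width), expression columns first."""
        expected = self.expr_width + self.mut_width
        if omics.shape[-1] != expected:
            raise ValueError(
                f"expected omics width {expected} "
                f"({self.expr_width} expression + {self.mut_width} mutation), "
                f"got {omics.shape[-1]}")
        return self.fc2(self.fc1(omics).relu()).relu()
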