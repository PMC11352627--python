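"""The full synergy regressor: branch assembly, loss, ablation variants.

The model predicts a real-valued Loewe-based synergy score for an ordered
(drug A, drug B, cell line) triple. Drug-pair features from the four
modalities (Morgan splice H_m, attention-fused sequence feature H_c,
multi-scale graph feature H = H_e1 || H_ec || H_e2, point-cloud features
H_D per drug) are concatenated with the cell-line feature F_cell and fed
to a three-layer head: FC+ReLU+BN → FC(half width)+ReLU+BN → FC(1).

Batching exploits the combinatorial structure of synergy screens: encoder
branches run once per *unique* drug / drug pair / cell line in a batch and
their outputs are gathered per example (gradients scatter-add back), which
makes CPU training of the full model practical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .chem_featurize import ATOM_FEATURE_WIDTH, DrugRecord, PairFeaturizer
from .config import ModelConfig
from .encoders import (CellEncoder, CloudEncoder, GraphEncoder, MultiHeadFusion,
                       SequenceDrugEncoder, global_max_pool)
from .graph_power import build_power_set, pair_graph
from .nn import Linear, Module, Tensor, concatenate, no_grad
from .nn.layers import BatchNorm1d, glorot
from .nn.autograd import Parameter

__all__ = [
    "VariantSpec",
    "VARIANTS",
    "SynergyModel",
    "FeatureStore",
    "ExampleBatch",
    "assemble_batch",
    "mse_loss",
    "build_variant",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class VariantSpec:
    """Which branches a model variant uses and how it fuses them."""

    branches: frozenset  # subset of {"morgan", "sequence", "graph", "cloud"}
    seq_attention: bool = True      # multi-head attention fuser for sequences
    graph_pair_fusion: bool = True  # include the pair-graph term H_ec
    cell_mode: str = "omics"        # omics | onehot | expr | mut
    fusion: str = "concat"          # concat | cross_attention | self_attention


_ALL = frozenset({"morgan", "sequence", "graph", "cloud"})
_BASE = frozenset({"morgan", "cloud"})

VARIANTS: dict[str, VariantSpec] = {
    "MMFSyn": VariantSpec(_ALL),
    "MMFSyn_base": VariantSpec(_BASE),
    "Seq_A": VariantSpec(_BASE | {"sequence"}, seq_attention=True),
    "Seq_B": VariantSpec(_BASE | {"sequence"}, seq_attention=False),
    "Graph_A": VariantSpec(_BASE | {"graph"}, graph_pair_fusion=True),
    "Graph_B": VariantSpec(_BASE | {"graph"}, graph_pair_fusion=False),
    "MMFSyn-CA": VariantSpec(_ALL, fusion="cross_attention"),
    "MMFSyn-SA": VariantSpec(_ALL, fusion="self_attention"),
    "Cell_base": VariantSpec(_ALL, cell_mode="onehot"),
    "Cell_gen": VariantSpec(_ALL, cell_mode="expr"),
    "Cell_mut": VariantSpec(_ALL, cell_mode="mut"),
}


def mse_loss(pred: Tensor, truth: np.ndarray | Tensor) -> Tensor:
    """Mean squared error (1/|T|) Σ (P − T)²."""
    truth = truth if isinstance(truth, Tensor) else Tensor(np.asarray(truth))
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if pred.data.size < 1:
        raise ValueError("empty prediction vector")
    diff = pred - truth
    return (diff * diff).mean()


# ---------------------------------------------------------------------------
# Feature store and batching
# ---------------------------------------------------------------------------


class FeatureStore:
    """Featurizes drugs once and serves padded arrays for batching.

    Per drug: atom-sequence matrix padded to ``max_atoms`` with a position
    mask, the three normalised power supports padded likewise, the point
    cloud and the Morgan fingerprint. Per ordered pair: the block-diagonal
    pair graph's supports (cached unpadded, padded per batch).
    """

    def __init__(self, drugs: dict[str, DrugRecord], config: ModelConfig):
        self.config = config
        cfg = config.featurizer
        self.max_atoms = cfg.max_atoms
        featurizer = PairFeaturizer(cfg)
        self.ids = sorted(drugs)
        self.index = {d: i for i, d in enumerate(self.ids)}
        n, L = len(self.ids), cfg.max_atoms
        self.seq = np.zeros((n, L, ATOM_FEATURE_WIDTH))
        self.seq_mask = np.zeros((n, L))
        self.supports = [np.zeros((n, L, L)) for _ in range(3)]
        self.clouds = np.zeros((n, cfg.cloud_points, 3))
        self.fps = np.zeros((n, cfg.fp_bits))
        self.graphs = {}
        for i, drug_id in enumerate(self.ids):
            f = featurizer.single(drugs[drug_id])
            m = f["seq"].length
            self.seq[i, :m] = f["seq"].features
            self.seq_mask[i, :m] = 1.0
            for k, a in enumerate((f["powers"].a1, f["powers"].a2, f["powers"].a3)):
                self.supports[k][i, :m, :m] = a
            self.clouds[i] = f["cloud"].coords
            self.fps[i] = f["fp"]
            self.graphs[drug_id] = f["graph"]
        self._pair_cache: dict[tuple[str, str], tuple] = {}

    def pair_supports(self, a: str, b: str) -> tuple:
        """Unpadded (supports, features, n_atoms) for the pair graph of (a, b)."""
        key = (a, b)
        if key not in self._pair_cache:
            g = pair_graph(self.graphs[a], self.graphs[b])
            cfg = self.config.featurizer
            p = build_power_set(g, power_mode=cfg.power_mode,
                                add_self_loops=cfg.add_self_loops)
            self._pair_cache[key] = ((p.a1, p.a2, p.a3), g.node_features,
                                     g.atom_count)
        return self._pair_cache[key]


@dataclass
class ExampleBatch:
    """Unique-entity arrays plus per-example gather indices."""

    drug_rows: np.ndarray        # (D,) rows into the store arrays
    pair_drug: np.ndarray        # (P, 2) indices into drug_rows order
    pair_supports: tuple         # 3 × (P, Np, Np)
    pair_feats: np.ndarray       # (P, Np, C)
    pair_mask: np.ndarray        # (P, Np)
    ex_pair: np.ndarray          # (B,) index into pairs
    ex_cell: np.ndarray          # (B,) index into cell matrix rows
    cell_matrix: np.ndarray      # (n_cells, omics width) model input rows
    y: np.ndarray                # (B,)


def assemble_batch(examples, store: FeatureStore, cell_matrix: np.ndarray,
                   cell_row) -> ExampleBatch:
    """Build an :class:`ExampleBatch` from (drug_a, drug_b, cell, score) rows.

    ``cell_row`` maps a cell id to its row in ``cell_matrix``.
    """
    drug_ids: list[str] = []
    drug_pos: dict[str, int] = {}
    pairs: list[tuple[str, str]] = []
    pair_pos: dict[tuple[str, str], int] = {}
    ex_pair, ex_cell, ys = [], [], []
    for ex in examples:
        a, b, cell, y = ex.drug_a, ex.drug_b, ex.cell_line, ex.score
        for d in (a, b):
            if d not in drug_pos:
                drug_pos[d] = len(drug_ids)
                drug_ids.append(d)
        key = (a, b)
        if key not in pair_pos:
            pair_pos[key] = len(pairs)
            pairs.append(key)
        ex_pair.append(pair_pos[key])
        ex_cell.append(cell_row[cell] if not isinstance(cell, (int, np.integer))
                       else int(cell))
        ys.append(y)

    drug_rows = np.array([store.index[d] for d in drug_ids], dtype=np.intp)
    pair_drug = np.array([[drug_pos[a], drug_pos[b]] for a, b in pairs],
                         dtype=np.intp)
    raw = [store.pair_supports(a, b) for a, b in pairs]
    npmax = max(r[2] for r in raw)
    P = len(pairs)
    sup = [np.zeros((P, npmax, npmax)) for _ in range(3)]
    feats = np.zeros((P, npmax, ATOM_FEATURE_WIDTH))
    mask = np.zeros((P, npmax))
    for i, (supports, node_feats, m) in enumerate(raw):
        for k in range(3):
            sup[k][i, :m, :m] = supports[k]
        feats[i, :m] = node_feats
        mask[i, :m] = 1.0
    return ExampleBatch(
        drug_rows=drug_rows, pair_drug=pair_drug,
        pair_supports=tuple(sup), pair_feats=feats, pair_mask=mask,
        ex_pair=np.asarray(ex_pair, dtype=np.intp),
        ex_cell=np.asarray(ex_cell, dtype=np.intp),
        cell_matrix=np.asarray(cell_matrix, dtype=np.float64),
        y=np.asarray(ys, dtype=np.float64),
    )


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------


class _TokenFusion(Module):
    """Single-block attention fusion over modality tokens (CA/SA variants).

    Each active drug modality vector and the cell vector are projected to a
    common width and treated as tokens. Self-attention attends all tokens
    to all tokens; cross-attention uses the cell token as the query over
    the drug-modality tokens. Interpretive minimal implementation.
    """

    def __init__(self, widths: list[int], mode: str, dim: int,
                 rng: np.random.Generator):
        super().__init__()
        self.mode = mode
        self.dim = dim
        self.projs = [Linear(w, dim, rng) for w in widths]
        self.w_q = Parameter(glorot(rng, dim, dim, (dim, dim)))
        self.w_k = Parameter(glorot(rng, dim, dim, (dim, dim)))
        self.w_v = Parameter(glorot(rng, dim, dim, (dim, dim)))

    def forward(self, parts: list[Tensor]) -> Tensor:
        from .nn import stack
        tokens = stack([proj(p) for proj, p in zip(self.projs, parts)], axis=1)
        scale = 1.0 / np.sqrt(self.dim)
        if self.mode == "cross_attention":
            q = tokens[:, -1:, :] @ self.w_q          # cell token queries
            kv = tokens[:, :-1, :]
        else:
            q = tokens @ self.w_q
            kv = tokens
        k = kv @ self.w_k
        v = kv @ self.w_v
        attn = ((q @ k.swapaxes(-1, -2)) * scale).softmax(axis=-1)
        out = attn @ v
        return out.mean(axis=1)


class SynergyModel(Module):
    """The assembled multimodal synergy regressor."""

    def __init__(self, config: ModelConfig, expr_width: int, mut_width: int,
                 n_cells: int):
        super().__init__()
        if config.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {config.variant!r}; valid: {sorted(VARIANTS)}")
        self.config = config
        self.spec = VARIANTS[config.variant]
        self.expr_width = expr_width
        self.mut_width = mut_width
        self.n_cells = n_cells
        rng = np.random.default_rng(config.seed)
        spec = self.spec
        widths: list[int] = []

        if "morgan" in spec.branches:
            widths.append(2 * config.featurizer.fp_bits)
        if "sequence" in spec.branches:
            self.seq_encoder = SequenceDrugEncoder(
                ATOM_FEATURE_WIDTH, config.featurizer.max_atoms,
                config.sequence, rng)
            if spec.seq_attention:
                self.seq_fusion = MultiHeadFusion(self.seq_encoder.out_dim,
                                                  config.sequence, rng)
                widths.append(config.sequence.attn_out)
            else:
                widths.append(self.seq_encoder.out_dim)
        if "graph" in spec.branches:
            self.graph_encoder = GraphEncoder(ATOM_FEATURE_WIDTH,
                                              config.graph, rng)
            per = self.graph_encoder.out_dim
            widths.append(3 * per if spec.graph_pair_fusion else 2 * per)
        if "cloud" in spec.branches:
            self.cloud_encoder = CloudEncoder(config.cloud, rng)
            widths.append(2 * self.cloud_encoder.out_dim)

        if spec.cell_mode == "onehot":
            cell_in_expr, cell_in_mut = n_cells, 0
        else:
            cell_in_expr, cell_in_mut = expr_width, mut_width
        self.cell_encoder = CellEncoder(cell_in_expr, cell_in_mut,
                                        config.cell, rng)

        self._drug_widths = widths
        if spec.fusion == "concat":
            head_in = sum(widths) + self.cell_encoder.out_dim
        else:
            self.token_fusion = _TokenFusion(
                widths + [self.cell_encoder.out_dim], spec.fusion,
                config.cell.out, rng)
            head_in = config.cell.out
        p = config.predictor_width
        self.fc1 = Linear(head_in, p, rng)
        self.bn1 = BatchNorm1d(p)
        self.fc2 = Linear(p, p // 2, rng)
        self.bn2 = BatchNorm1d(p // 2)
        self.fc3 = Linear(p // 2, 1, rng)

    # -- forward ------------------------------------------------------------

    def _cell_input(self, cell_matrix: np.ndarray) -> np.ndarray:
        mode = self.spec.cell_mode
        if mode == "onehot":
            return np.eye(self.n_cells)
        m = cell_matrix.copy()
        if mode == "expr":
            m[:, self.expr_width:] = 0.0
        elif mode == "mut":
            m[:, :self.expr_width] = 0.0
        return m

    def forward(self, batch: ExampleBatch, store: FeatureStore) -> Tensor:
        spec = self.spec
        rows = batch.drug_rows
        ia, ib = batch.pair_drug[:, 0], batch.pair_drug[:, 1]
        parts: list[Tensor] = []

        if "morgan" in spec.branches:
            fps = store.fps[rows]
            parts.append(Tensor(np.concatenate([fps[ia], fps[ib]], axis=1)))
        if "sequence" in spec.branches:
            x = Tensor(store.seq[rows])
            mask = store.seq_mask[rows]
            hs = self.seq_encoder(x, mask=mask)
            h1 = hs.take_rows(ia)
            h2 = hs.take_rows(ib)
            pair_mask = np.maximum(mask[ia], mask[ib])
            if spec.seq_attention:
                parts.append(self.seq_fusion(h1, h2, mask=pair_mask))
            else:
                # ablation: pointwise addition, masked mean over positions
                xc = h1 + h2
                m = pair_mask[..., None]
                pooled = (xc * Tensor(m)).sum(axis=-2) \
                    / Tensor(m.sum(axis=-2).clip(min=1.0))
                parts.append(pooled)
        if "graph" in spec.branches:
            supports = tuple(Tensor(s[rows]) for s in store.supports)
            he = self.graph_encoder(supports, Tensor(store.seq[rows]),
                                    node_mask=store.seq_mask[rows])
            he1 = he.take_rows(ia)
            he2 = he.take_rows(ib)
            if spec.graph_pair_fusion:
                hec = self.graph_encoder(
                    tuple(Tensor(s) for s in batch.pair_supports),
                    Tensor(batch.pair_feats), node_mask=batch.pair_mask)
                parts.append(concatenate([he1, hec, he2], axis=1))
            else:
                parts.append(concatenate([he1, he2], axis=1))
        if "cloud" in spec.branches:
            hd = self.cloud_encoder(Tensor(store.clouds[rows]))
            parts.append(concatenate([hd.take_rows(ia), hd.take_rows(ib)],
                                     axis=1))

        cell_in = Tensor(self._cell_input(batch.cell_matrix))
        f_cell = self.cell_encoder(cell_in).take_rows(batch.ex_cell)

        parts = [p.take_rows(batch.ex_pair) for p in parts]
        if spec.fusion == "concat":
            fused = concatenate(parts + [f_cell], axis=1)
        else:
            fused = self.token_fusion(parts + [f_cell])
        h = self.bn1(self.fc1(fused).relu())
        h = self.bn2(self.fc2(h).relu())
        out = self.fc3(h)
        pred = out.reshape(out.shape[0])
        if not np.all(np.isfinite(pred.data)):
            raise FloatingPointError("non-finite prediction in forward pass")
        return pred

    # -- inference ----------------------------------------------------------

    def predict(self, examples, store: FeatureStore, cell_matrix: np.ndarray,
                cell_row, average_orderings: bool | None = None) -> np.ndarray:
        """Eval-mode predictions; averages both drug orderings by default."""
        if average_orderings is None:
            average_orderings = self.config.order_augment
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                batch = assemble_batch(examples, store, cell_matrix, cell_row)
                pred = self.forward(batch, store).data
                if average_orderings:
                    swapped = [_swap(ex) for ex in examples]
                    batch2 = assemble_batch(swapped, store, cell_matrix, cell_row)
                    pred = 0.5 * (pred + self.forward(batch2, store).data)
        finally:
            if was_training:
                self.train()
        return pred

    # -- bookkeeping ---------------------------------------------------------

    def summary(self) -> dict[str, int]:
        counts = {name: int(p.data.size) for name, p in self.named_parameters()}
        counts["total"] = sum(counts.values())
        return counts

    def save(self, path) -> None:
        meta = {
            "version": CHECKPOINT_VERSION,
            "config": self.config.to_dict(),
            "expr_width": self.expr_width,
            "mut_width": self.mut_width,
            "n_cells": self.n_cells,
        }
        state = self.state_dict()
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path) -> "SynergyModel":
        try:
            with np.load(path) as data:
                meta = json.loads(bytes(data["__meta__"]).decode())
                state = {k: data[k] for k in data.files if k != "__meta__"}
        except Exception as exc:
            raise IOError(f"cannot read checkpoint {path}: {exc}") from exc
        if meta.get("version") != CHECKPOINT_VERSION:
            raise IOError(
                f"checkpoint version {meta.get('version')} is incompatible "
                f"with supported version {CHECKPOINT_VERSION}")
        config = ModelConfig.from_dict(meta["config"])
        model = cls(config, meta["expr_width"], meta["mut_width"],
                    meta["n_cells"])
        model.load_state_dict(state)
        return model


def _swap(ex):
    import dataclasses
    return dataclasses.replace(ex, drug_a=ex.drug_b, drug_b=ex.drug_a)


def build_variant(name: str, config: ModelConfig, expr_width: int,
                  mut_width: int, n_cells: int) -> SynergyModel:
    """Factory for the model and its ablation variants."""
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; valid: {sorted(VARIANTS)}")
    import dataclasses as _dc
    cfg = _dc.replace(config, variant=name)
    return SynergyModel(cfg, expr_width, mut_width, n_cells)
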