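"""Graph algebra for molecular graphs.

Molecular graphs here are undirected, unweighted, vertex-featured graphs
(atoms as vertices, bonds as edges). The multi-scale graph encoder passes
messages not only over bonds but over *power graphs*: the order-k power
graph connects every pair of atoms whose shortest-path distance lies
within k hops, widening the receptive field of a single GCN layer.

Two conventions exist for "the k-th power": cumulative (distance in
[1, k]) and exact (distance exactly k). Each power graph is used as a
standalone message-passing support, so the cumulative reading is the
default; both are available via ``power_mode``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InvalidGraphError",
    "MolecularGraph",
    "PowerGraphSet",
    "power_adjacency",
    "normalize_adjacency",
    "pair_graph",
    "build_power_set",
]


class InvalidGraphError(ValueError):
    """Raised for adjacency matrices that are not simple undirected graphs."""


@dataclass
class MolecularGraph:
    """Adjacency + per-atom features of one molecule (or a molecule pair)."""

    adjacency: np.ndarray  # (N, N) binary, symmetric, zero diagonal
    node_features: np.ndarray  # (N, C)

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=np.float64)
        self.node_features = np.asarray(self.node_features, dtype=np.float64)
        _check_simple(self.adjacency)
        if self.node_features.ndim != 2 or \
                self.node_features.shape[0] != self.adjacency.shape[0]:
            raise InvalidGraphError(
                "node_features must have one row per adjacency node")

    @property
    def atom_count(self) -> int:
        return self.adjacency.shape[0]

    @property
    def feature_width(self) -> int:
        return self.node_features.shape[1]


@dataclass
class PowerGraphSet:
    """Degree-normalised supports of orders 1, 2 and 3 for one graph."""

    a1: np.ndarray
    a2: np.ndarray
    a3: np.ndarray


def _check_simple(adjacency: np.ndarray) -> None:
    a = np.asarray(adjacency)
    if a.ndim != 2 or a.shape[0] != a.shape[1] or a.shape[0] < 1:
        raise InvalidGraphError(f"adjacency must be square and non-empty, got {a.shape}")
    if not np.array_equal(a, a.T):
        raise InvalidGraphError("adjacency must be symmetric")
    if not np.all(np.isin(a, (0, 1))):
        raise InvalidGraphError("adjacency must be binary")
    if np.any(np.diag(a) != 0):
        raise InvalidGraphError("adjacency diagonal must be zero")


def power_adjacency(adjacency: np.ndarray, order: int,
                    power_mode: str = "cumulative") -> np.ndarray:
    """Binary adjacency of the order-k power graph.

    cumulative: edge (u, v) iff shortest-path distance d(u, v) in [1, order];
    exact: iff d(u, v) == order. Computed by boolean matrix powers, so cost
    is O(order * N^3) — fine for molecules.
    """
    _check_simple(adjacency)
    if order not in (1, 2, 3):
        raise ValueError(f"order must be 1, 2 or 3, got {order}")
    if power_mode not in ("cumulative", "exact"):
        raise ValueError(f"unknown power_mode {power_mode!r}")
    a = np.asarray(adjacency, dtype=bool)
    n = a.shape[0]
    reach_prev = np.eye(n, dtype=bool)  # distance <= k-1
    reach = np.eye(n, dtype=bool) | a   # distance <= k
    for _ in range(order - 1):
        reach_prev = reach
        reach = reach | (reach @ a)
    if power_mode == "cumulative":
        out = reach & ~np.eye(n, dtype=bool)
    else:
        out = reach & ~reach_prev
    return out.astype(np.float64)


def normalize_adjacency(adjacency: np.ndarray,
                        add_self_loops: bool = False) -> np.ndarray:
    """Symmetric degree normalisation D^{-1/2} A D^{-1/2}.

    Zero-degree nodes (isolated atoms/ions) have their degree clamped to 1,
    leaving an all-zero row instead of NaN. With ``add_self_loops`` the
    common A+I variant is returned instead.
    """
    _check_simple(adjacency)
    a = np.asarray(adjacency, dtype=np.float64)
    if add_self_loops:
        a = a + np.eye(a.shape[0])
    deg = a.sum(axis=1)
    deg = np.where(deg > 0, deg, 1.0)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return a * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def pair_graph(g1: MolecularGraph, g2: MolecularGraph) -> MolecularGraph:
    """Block-diagonal union of two molecules: the drug-combination graph.

    No cross-drug edges are introduced; node features are stacked in order
    (drug 1 rows first).
    """
    if g1.feature_width != g2.feature_width:
        raise InvalidGraphError(
            f"feature width mismatch: {g1.feature_width} vs {g2.feature_width}")
    n1, n2 = g1.atom_count, g2.atom_count
    adjacency = np.zeros((n1 + n2, n1 + n2))
    adjacency[:n1, :n1] = g1.adjacency
    adjacency[n1:, n1:] = g2.adjacency
    features = np.vstack([g1.node_features, g2.node_features])
    return MolecularGraph(adjacency=adjacency, node_features=features)


def build_power_set(graph: MolecularGraph, power_mode: str = "cumulative",
                    add_self_loops: bool = False) -> PowerGraphSet:
    """Normalised order-1/2/3 supports for one molecular graph."""
    mats = [
        normalize_adjacency(power_adjacency(graph.adjacency, k, power_mode),
                            add_self_loops=add_self_loops)
        for k in (1, 2, 3)
    ]
    return PowerGraphSet(a1=mats[0], a2=mats[1], a3=mats[2])
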