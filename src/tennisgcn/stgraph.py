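"""Spatial skeleton graph and the graph-convolution primitive.

The skeleton of a tennis player holding a racket is modelled as an undirected
graph G = (V, E) with 19 nodes: 17 body joints plus two racket nodes (handle
and head) attached to the dominant hand.  Spatial aggregation follows the
degree-normalized adjacency

    A_norm = Lambda^{-1/2} (A + I) Lambda^{-1/2},   Lambda_ii = sum_j (A + I)_ij,

so a graph convolution of node features f (V x C_in) with weights W
(C_in x C_out) is simply ``A_norm @ f @ W``.  Temporal structure is handled
outside this module by ordinary convolution along the time axis of the
(C, V, T) attribute tensor.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CANONICAL_NODE_NAMES",
    "CANONICAL_EDGES",
    "SkeletonGraph",
    "NeighborSpec",
    "build_graph",
    "canonical_graph",
    "normalize_adjacency",
    "neighbor_set",
    "graph_conv",
]

#: Canonical 19-node skeleton: axial chain, two arms, two legs, racket chain.
CANONICAL_NODE_NAMES: tuple[str, ...] = (
    "head",
    "neck",
    "spine_upper",
    "spine_lower",
    "pelvis",
    "shoulder_l",
    "elbow_l",
    "hand_l",
    "shoulder_r",
    "elbow_r",
    "hand_r",
    "hip_l",
    "knee_l",
    "foot_l",
    "hip_r",
    "knee_r",
    "foot_r",
    "racket_handle",
    "racket_head",
)

#: 18 spatial edges (name pairs).  The racket hangs off the canonical dominant
#: (right) hand; left-handed subjects are mirrored upstream so this holds.
CANONICAL_EDGES: tuple[tuple[str, str], ...] = (
    ("head", "neck"),
    ("neck", "spine_upper"),
    ("spine_upper", "spine_lower"),
    ("spine_lower", "pelvis"),
    ("neck", "shoulder_l"),
    ("shoulder_l", "elbow_l"),
    ("elbow_l", "hand_l"),
    ("neck", "shoulder_r"),
    ("shoulder_r", "elbow_r"),
    ("elbow_r", "hand_r"),
    ("pelvis", "hip_l"),
    ("hip_l", "knee_l"),
    ("knee_l", "foot_l"),
    ("pelvis", "hip_r"),
    ("hip_r", "knee_r"),
    ("knee_r", "foot_r"),
    ("hand_r", "racket_handle"),
    ("racket_handle", "racket_head"),
)


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Return ``Lambda^{-1/2} (A + I) Lambda^{-1/2}``.

    ``A`` must be a square, symmetric, nonnegative adjacency matrix.  The
    identity adds a self-link to every node, so every row degree is strictly
    positive and the result is well defined for isolated nodes too.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(A < 0):
        raise ValueError("adjacency must be nonnegative")
    AI = A + np.eye(A.shape[0])
    inv_sqrt_deg = 1.0 / np.sqrt(AI.sum(axis=1))
    return AI * inv_sqrt_deg[:, None] * inv_sqrt_deg[None, :]


@dataclass(frozen=True)
class NeighborSpec:
    """Maximum path length D defining the neighbor set of a node (D=1 here)."""

    D: int = 1

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be >= 0")


@dataclass(frozen=True)
class SkeletonGraph:
    """Immutable skeleton graph with cached adjacency products.

    Attributes
    ----------
    node_names:
        Ordered node names; index in this tuple is the canonical node id.
    edges:
        Frozenset of unordered id pairs (the spatial edge set E, no self-loops).
    A, I, Lambda, A_norm:
        Binary adjacency, identity (self-links), diagonal degree matrix of
        A + I, and the normalized adjacency used by the convolution.
    """

    node_names: tuple[str, ...]
    edges: frozenset[frozenset[int]]
    A: np.ndarray = field(repr=False)
    I: np.ndarray = field(repr=False)
    Lambda: np.ndarray = field(repr=False)
    A_norm: np.ndarray = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def node_id(self, name: str) -> int:
        return self.node_names.index(name)

    def adjacency_list(self) -> dict[int, set[int]]:
        out: dict[int, set[int]] = {i: set() for i in range(self.n_nodes)}
        for e in self.edges:
            i, j = tuple(e)
            out[i].add(j)
            out[j].add(i)
        return out

    def adjacency_csv(self, normalized: bool = False) -> str:
        """Adjacency (or normalized adjacency) as CSV with node-name headers."""
        M = self.A_norm if normalized else self.A
        lines = ["node," + ",".join(self.node_names)]
        for name, row in zip(self.node_names, M):
            lines.append(name + "," + ",".join(f"{v:.10g}" for v in row))
        return "\n".join(lines) + "\n"

    def to_edge_list_text(self) -> str:
        """Serialize edges as one ``nameA nameB`` pair per line."""
        lines = sorted(
            " ".join(sorted((self.node_names[i], self.node_names[j])))
            for e in self.edges
            for i, j in [tuple(e)]
        )
        return "\n".join(lines) + "\n"


def build_graph(
    node_names: list[str] | tuple[str, ...],
    edges: list[tuple[str, str]] | tuple[tuple[str, str], ...],
) -> SkeletonGraph:
    """Build a :class:`SkeletonGraph` from node names and name-pair edges.

    Raises ``ValueError`` on duplicate node names, dangling edges or
    self-loops.
    """
    names = tuple(node_names)
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate node names: {dupes}")
    index = {n: i for i, n in enumerate(names)}
    V = len(names)
    A = np.zeros((V, V))
    id_edges: set[frozenset[int]] = set()
    for a, b in edges:
        if a not in index or b not in index:
            missing = a if a not in index else b
            raise ValueError(f"edge ({a!r}, {b!r}) references unknown node {missing!r}")
        if a == b:
            raise ValueError(f"self-loop on node {a!r} not allowed in E")
        i, j = index[a], index[b]
        A[i, j] = A[j, i] = 1.0
        id_edges.add(frozenset((i, j)))
    I = np.eye(V)
    Lambda = np.diag((A + I).sum(axis=1))
    return SkeletonGraph(
        node_names=names,
        edges=frozenset(id_edges),
        A=A,
        I=I,
        Lambda=Lambda,
        A_norm=normalize_adjacency(A),
    )


def canonical_graph() -> SkeletonGraph:
    """The default 19-node / 18-edge human+racket skeleton."""
    return build_graph(CANONICAL_NODE_NAMES, CANONICAL_EDGES)


def neighbor_set(graph: SkeletonGraph, node: int | str, spec: NeighborSpec = NeighborSpec()) -> set[int]:
    """All node ids within path distance ``spec.D`` of ``node`` (inclusive)."""
    if isinstance(node, str):
        node = graph.node_id(node)
    if not 0 <= node < graph.n_nodes:
        raise ValueError(f"invalid node id {node}")
    adj = graph.adjacency_list()
    seen = {node}
    frontier = deque([(node, 0)])
    while frontier:
        u, d = frontier.popleft()
        if d == spec.D:
            continue
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                frontier.append((v, d + 1))
    return seen


def graph_conv(features: np.ndarray, graph: SkeletonGraph, W: np.ndarray) -> np.ndarray:
    """Single-frame spatial graph convolution ``A_norm @ features @ W``.

    ``features`` has shape (V, C_in) and ``W`` shape (C_in, C_out).  The
    result equals the per-node sum over the distance-1 neighbor set with
    weights ``A_norm[i, j] * W``.
    """
    features = np.asarray(features, dtype=float)
    W = np.asarray(W, dtype=float)
    if features.ndim != 2 or features.shape[0] != graph.n_nodes:
        raise ValueError(
            f"features must be (V={graph.n_nodes}, C_in), got {features.shape}"
        )
    if W.ndim != 2 or W.shape[0] != features.shape[1]:
        raise ValueError(f"weight shape {W.shape} incompatible with C_in={features.shape[1]}")
    return graph.A_norm @ features @ W
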