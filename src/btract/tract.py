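"""Behavioral tractography on the 3D multilayer network.

The 20 embedded items are duplicated into two temporal layers (TL1 at z=0,
TL2 at z=1).  Cross-sectional edges connect nodes within a layer, lagged
edges run TL1 -> TL2 only, and every edge gets a graph length 1/|weight| so
strong couplings of either sign conduct paths.  For each ordered item pair
the minimum-length TL1 -> TL2 path is computed by Dijkstra with
deterministic tie-breaking (fewer hops, then lexicographic node names); a
path is summarized by the XYZ coordinates of four anchors (start, exit of
TL1, entry into TL2, end) and paths are clustered into "bundles" by k-means
on those 12 coordinates.  Per-node diffusion vectors and longitudinal
betweenness counts describe how paths flow through individual items.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .embedding import NetworkEmbedding
from .network import NetworkMatrix

__all__ = [
    "Node3D",
    "Edge3D",
    "MLN3D",
    "BehavioralPath",
    "PathAnchorVector",
    "Bundle",
    "DiffusionVector",
    "assemble_3d",
    "shortest_interlayer_paths",
    "extract_anchors",
    "cluster_bundles",
    "behavioral_diffusion",
    "longitudinal_betweenness",
]

NodeKey = tuple[str, str]  # (item, layer)


def node_name(key: NodeKey) -> str:
    return f"{key[0]}@{key[1]}"


def parse_node_name(name: str) -> NodeKey:
    item, _, layer = name.rpartition("@")
    return item, layer


@dataclass
class Node3D:
    item: str
    layer: str  # "TL1" or "TL2"
    x: float
    y: float
    z: float

    @property
    def key(self) -> NodeKey:
        return (self.item, self.layer)

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Edge3D:
    u: NodeKey
    v: NodeKey
    weight: float
    length: float
    kind: str  # "within" or "between"


@dataclass(eq=False)
class MLN3D:
    """3D two-layer network: node coordinates plus weighted, lengthed edges.

    Within-layer edges are undirected (stored once, traversable both ways);
    between-layer edges are directed TL1 -> TL2.
    """

    nodes: list[Node3D]
    edges: list[Edge3D]
    provenance: Optional[NetworkMatrix] = None

    def __post_init__(self) -> None:
        self.coordinates: dict[NodeKey, np.ndarray] = {
            n.key: n.xyz for n in self.nodes
        }
        for e in self.edges:
            if e.length <= 0:
                raise ValueError(f"edge {e.u}->{e.v} has non-positive length")
            lu, lv = e.u[1], e.v[1]
            if e.kind == "within" and lu != lv:
                raise ValueError("within-layer edge connects different layers")
            if e.kind == "between" and (lu, lv) != ("TL1", "TL2"):
                raise ValueError("between-layer edges must go TL1 -> TL2")
        # adjacency: node -> list of (neighbor, length, hop-cost irrelevant)
        adj: dict[NodeKey, list[tuple[NodeKey, float]]] = {
            n.key: [] for n in self.nodes
        }
        for e in self.edges:
            adj[e.u].append((e.v, e.length))
            if e.kind == "within":
                adj[e.v].append((e.u, e.length))
        for nbrs in adj.values():
            nbrs.sort(key=lambda t: t[0])
        self.adjacency = adj

    def node_keys(self) -> list[NodeKey]:
        return [n.key for n in self.nodes]

    def items(self) -> list[str]:
        return [n.item for n in self.nodes if n.layer == "TL1"]


@dataclass(eq=False)
class PathAnchorVector:
    """Start/exit/entry/end XYZ coordinates of one path (12 reals)."""

    start: np.ndarray
    exit_tl1: np.ndarray
    entry_tl2: np.ndarray
    end: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.start, self.exit_tl1, self.entry_tl2, self.end])


@dataclass(eq=False)
class BehavioralPath:
    """An interlayer shortest path with its anchor decomposition."""

    start_item: str
    end_item: str
    node_sequence: list[NodeKey]
    coordinates: list[np.ndarray]
    total_length: float
    anchors: Optional[PathAnchorVector] = None

    def __post_init__(self) -> None:
        if self.anchors is None and self.node_sequence:
            self.anchors = extract_anchors(self)


@dataclass(eq=False)
class Bundle:
    id: int
    member_paths: list[BehavioralPath]
    centroid: np.ndarray
    label: str


@dataclass(eq=False)
class DiffusionVector:
    node: NodeKey
    direction: np.ndarray  # mean (dx, dy, dz)
    n_paths: int


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_3d(
    embedding: NetworkEmbedding,
    multilayer: NetworkMatrix,
    length_transform: str = "inverse_abs",
) -> MLN3D:
    """Instantiate the 3D two-layer network from an embedding and a 40x40 matrix.

    Every retained (non-zero) matrix entry becomes an edge of length
    1/|weight|; pruned pairs get no edge.  TL1 sits at z=0, TL2 at z=1.
    """
    if length_transform != "inverse_abs":
        raise ValueError(f"unknown length transform {length_transform!r}")
    if multilayer.kind != "multilayer":
        raise ValueError("assemble_3d expects the 40x40 multilayer matrix")
    k = multilayer.n_nodes // 2
    items = [lbl.rsplit("@", 1)[0] for lbl in multilayer.labels[:k]]
    missing = [i for i in items if i not in set(embedding.items)]
    if missing:
        raise ValueError(f"embedding lacks coordinates for items {missing}")

    nodes = []
    for layer, z in (("TL1", 0.0), ("TL2", 1.0)):
        for item in items:
            x, y = embedding.xy(item)
            nodes.append(Node3D(item, layer, x, y, z))

    W, M = multilayer.weights, multilayer.mask
    edges: list[Edge3D] = []

    def _length(w: float) -> float:
        if w == 0.0:
            raise ValueError("retained edge with weight 0: inconsistent mask")
        return 1.0 / abs(w)

    # within-layer edges from the (symmetric) TL1 block, stored once per layer
    for i in range(k):
        for j in range(i + 1, k):
            if M[i, j]:
                w = W[i, j]
                for layer in ("TL1", "TL2"):
                    edges.append(
                        Edge3D((items[i], layer), (items[j], layer), w,
                               _length(w), "within")
                    )
    # between-layer lagged edges: TL1 predictor -> TL2 outcome
    for i in range(k):
        for j in range(k):
            if M[i, k + j]:
                w = W[i, k + j]
                edges.append(
                    Edge3D((items[i], "TL1"), (items[j], "TL2"), w,
                           _length(w), "between")
                )
    return MLN3D(nodes=nodes, edges=edges, provenance=multilayer)


# ---------------------------------------------------------------------------
# Shortest paths
# ---------------------------------------------------------------------------

def _dijkstra_from(
    mln: MLN3D, source: NodeKey
) -> dict[NodeKey, tuple[float, int, tuple[NodeKey, ...]]]:
    """Single-source Dijkstra with (length, hops, lexicographic) tie-breaking."""
    best: dict[NodeKey, tuple[float, int, tuple[NodeKey, ...]]] = {}
    heap: list[tuple[float, int, tuple[NodeKey, ...]]] = [(0.0, 0, (source,))]
    while heap:
        d, hops, path = heapq.heappop(heap)
        node = path[-1]
        if node in best:
            continue
        best[node] = (d, hops, path)
        for nbr, length in mln.adjacency[node]:
            if nbr not in best:
                heapq.heappush(heap, (d + length, hops + 1, path + (nbr,)))
    return best


def shortest_interlayer_paths(
    mln: MLN3D, return_unreachable: bool = False
) -> Union[list[BehavioralPath], tuple[list[BehavioralPath], list[tuple[str, str]]]]:
    """Minimum-length TL1 -> TL2 path for every ordered, reachable item pair.

    Edge directionality guarantees exactly one interlayer transition per
    path.  Unreachable pairs are omitted (and returned separately when
    ``return_unreachable`` is set).
    """
    items = mln.items()
    paths: list[BehavioralPath] = []
    unreachable: list[tuple[str, str]] = []
    for start in items:
        best = _dijkstra_from(mln, (start, "TL1"))
        for end in items:
            hit = best.get((end, "TL2"))
            if hit is None:
                unreachable.append((start, end))
                continue
            d, _, seq = hit
            paths.append(
                BehavioralPath(
                    start_item=start,
                    end_item=end,
                    node_sequence=list(seq),
                    coordinates=[mln.coordinates[kk] for kk in seq],
                    total_length=float(d),
                )
            )
    if return_unreachable:
        return paths, unreachable
    return paths


def extract_anchors(path: BehavioralPath) -> PathAnchorVector:
    """Start / TL1-exit / TL2-entry / end coordinates of a path.

    For a direct (single lagged edge) path start == exit and entry == end.
    """
    layers = [k[1] for k in path.node_sequence]
    if "TL1" not in layers or "TL2" not in layers:
        raise ValueError("path never transitions between temporal layers")
    exit_idx = max(i for i, l in enumerate(layers) if l == "TL1")
    entry_idx = min(i for i, l in enumerate(layers) if l == "TL2")
    coords = path.coordinates
    return PathAnchorVector(
        start=np.asarray(coords[0], dtype=float),
        exit_tl1=np.asarray(coords[exit_idx], dtype=float),
        entry_tl2=np.asarray(coords[entry_idx], dtype=float),
        end=np.asarray(coords[-1], dtype=float),
    )


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

def _quadrant(xy: np.ndarray) -> str:
    h = "left" if xy[0] < 0 else "right"
    v = "lower" if xy[1] < 0 else "upper"
    return f"{v}-{h}"


def _auto_k(X: np.ndarray, seed: int, k_range=(4, 12)) -> int:
    lo, hi = k_range
    hi = min(hi, len(X) - 1)
    best_k, best_s = None, -np.inf
    for k in range(lo, hi + 1):
        if k < 2 or k >= len(X):
            continue
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        if len(np.unique(km.labels_)) < 2:
            continue
        s = silhouette_score(X, km.labels_)
        if s > best_s:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("could not select a bundle count automatically")
    return best_k


def cluster_bundles(
    paths: Sequence[BehavioralPath],
    k: Union[int, str] = "auto",
    seed: int = 0,
) -> list[Bundle]:
    """k-means bundles of paths by their 12-dimensional anchor vectors.

    ``k="auto"`` maximizes mean silhouette over k in [4, 12]; 50 restarts,
    deterministic given ``seed``.
    """
    if len(paths) == 0:
        raise ValueError("no paths to cluster")
    X = np.vstack([p.anchors.vector for p in paths])
    if k == "auto":
        k = _auto_k(X, seed)
    k = int(k)
    if k > len(paths):
        raise ValueError(f"k={k} exceeds the number of paths ({len(paths)})")
    if k == 1:
        labels = np.zeros(len(paths), dtype=int)
        centers = X.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=k, n_init=50, random_state=seed).fit(X)
        labels, centers = km.labels_, km.cluster_centers_
    bundles = []
    for b in range(k):
        members = [p for p, l in zip(paths, labels) if l == b]
        if not members:
            continue
        centroid = np.vstack([p.anchors.vector for p in members]).mean(axis=0)
        label = f"{_quadrant(centroid[0:2])}->{_quadrant(centroid[9:11])}"
        bundles.append(Bundle(id=b, member_paths=members, centroid=centroid,
                              label=label))
    return bundles


# ---------------------------------------------------------------------------
# Diffusion and betweenness
# ---------------------------------------------------------------------------

def behavioral_diffusion(
    node: NodeKey, paths: Sequence[BehavioralPath]
) -> DiffusionVector:
    """Mean 3D displacement of shortest paths through a node.

    For every traversing path the displacement is successor-minus-node; a
    terminal TL2 node contributes its predecessor-to-node displacement
    instead, so time (dz) never runs backwards.
    """
    disps = []
    for p in paths:
        seq = p.node_sequence
        for i, kk in enumerate(seq):
            if kk != node:
                continue
            if i + 1 < len(seq):
                disps.append(p.coordinates[i + 1] - p.coordinates[i])
            elif i > 0:
                disps.append(p.coordinates[i] - p.coordinates[i - 1])
            break
    if not disps:
        return DiffusionVector(node=node, direction=np.zeros(3), n_paths=0)
    return DiffusionVector(
        node=node,
        direction=np.mean(np.vstack(disps), axis=0),
        n_paths=len(disps),
    )


def longitudinal_betweenness(
    mln: MLN3D, paths: Sequence[BehavioralPath]
) -> tuple[dict[NodeKey, int], dict[tuple[NodeKey, NodeKey], int]]:
    """Counts of shortest paths through each node and along each edge.

    Endpoints count for their own paths.  Edge counts are keyed by the
    stored orientation (either traversal direction of a within-layer edge
    increments the same key).
    """
    node_counts: dict[NodeKey, int] = {kk: 0 for kk in mln.node_keys()}
    stored = {}
    for e in mln.edges:
        stored[(e.u, e.v)] = (e.u, e.v)
        if e.kind == "within":
            stored[(e.v, e.u)] = (e.u, e.v)
    edge_counts: dict[tuple[NodeKey, NodeKey], int] = {
        (e.u, e.v): 0 for e in mln.edges
    }
    for p in paths:
        for kk in p.node_sequence:
            node_counts[kk] += 1
        for a, b in zip(p.node_sequence[:-1], p.node_sequence[1:]):
            edge_counts[stored[(a, b)]] += 1
    return node_counts, edge_counts
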