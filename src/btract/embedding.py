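"""PCA embedding of the cross-sectional network (network dimensionality reduction).

Nodes are treated as observations whose features are their connectivity
profiles (rows of the symmetrized adjacency matrix); their loadings on the
first two principal components give the 2D layout used inside each temporal
layer of the 3D multilayer network.  Embedding fidelity is the Pearson
correlation, over unordered node pairs, between 2D Euclidean distance and
edge weight - strongly co-occurring items should sit close together, so a
good layout gives a clearly negative correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .items import COGNITIVE_ANCHOR, DISTRESS_ITEMS
from .network import NetworkMatrix

__all__ = ["NetworkEmbedding", "embed_network", "embedding_accuracy"]


@dataclass
class NetworkEmbedding:
    """2D node layout with its variance fractions and fidelity statistics."""

    coordinates: pd.DataFrame        # item -> (x, y[, ...])
    explained_variance: np.ndarray   # fraction per retained component
    accuracy_r: float
    accuracy_p: float

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(self.coordinates.index)

    def xy(self, item: str) -> tuple[float, float]:
        row = self.coordinates.loc[item]
        return float(row.iloc[0]), float(row.iloc[1])


def _prepare_adjacency(net: NetworkMatrix, diagonal: str) -> np.ndarray:
    A = np.array(net.weights, dtype=float)
    if not np.allclose(A, A.T):
        raise ValueError("embedding requires a symmetric cross-sectional matrix")
    if np.allclose(A, 0):
        raise ValueError("cannot embed an all-zero network")
    n = A.shape[0]
    off = ~np.eye(n, dtype=bool)
    if diagonal == "mean_offdiag":
        # per-node mean off-diagonal weight keeps the diagonal from
        # dominating component 1 while preserving symmetry
        np.fill_diagonal(A, A[off].reshape(n, n - 1).mean(axis=1))
    elif diagonal == "zero":
        np.fill_diagonal(A, 0.0)
    else:
        raise ValueError(f"unknown diagonal convention {diagonal!r}")
    return A


def embed_network(
    net: NetworkMatrix,
    n_dims: int = 2,
    diagonal: str = "mean_offdiag",
    anchor_item: str = COGNITIVE_ANCHOR,
    distress_items: Sequence[str] = DISTRESS_ITEMS,
) -> NetworkEmbedding:
    """Embed network nodes by PCA of the (symmetric) adjacency matrix.

    Coordinates are the node projections on the first ``n_dims`` components,
    scaled per axis to max |value| = 1 so XY distances are commensurate with
    the unit inter-layer gap of the 3D assembly.  Axis signs are anchored
    for reproducibility: the designated cognitive anchor item gets negative
    x and the distress items a positive mean y.
    """
    A = _prepare_adjacency(net, diagonal)
    n = A.shape[0]
    if n_dims < 1 or n_dims > n:
        raise ValueError("n_dims out of range")
    pca = PCA(n_components=n_dims)
    coords = pca.fit_transform(A)

    labels = list(net.labels)
    if anchor_item in labels and coords[labels.index(anchor_item), 0] > 0:
        coords[:, 0] *= -1
    present = [i for i in distress_items if i in labels]
    if n_dims >= 2 and present:
        idx = [labels.index(i) for i in present]
        if coords[idx, 1].mean() < 0:
            coords[:, 1] *= -1
    # per-axis scaling to max |value| = 1
    for c in range(n_dims):
        m = np.max(np.abs(coords[:, c]))
        if m > 0:
            coords[:, c] = coords[:, c] / m

    axis_names = ["x", "y", "z3", "z4"][:n_dims] if n_dims <= 4 else [
        f"c{i+1}" for i in range(n_dims)
    ]
    frame = pd.DataFrame(coords, index=labels, columns=axis_names)
    emb = NetworkEmbedding(
        coordinates=frame,
        explained_variance=pca.explained_variance_ratio_,
        accuracy_r=np.nan,
        accuracy_p=np.nan,
    )
    emb.accuracy_r, emb.accuracy_p = embedding_accuracy(emb, net)
    return emb


def embedding_accuracy(emb: NetworkEmbedding, net: NetworkMatrix) -> tuple[float, float]:
    """Pearson (distance, weight) correlation over all unordered node pairs."""
    labels = list(net.labels)
    if set(labels) - set(emb.items):
        raise ValueError("embedding lacks coordinates for some network nodes")
    xy = emb.coordinates.loc[labels].to_numpy(dtype=float)[:, :2]
    pairs = list(combinations(range(len(labels)), 2))
    if len(pairs) < 3:
        raise ValueError("need at least 3 node pairs")
    dist = np.array([np.linalg.norm(xy[i] - xy[j]) for i, j in pairs])
    w = np.array([net.weights[i, j] for i, j in pairs])
    if np.ptp(dist) == 0 or np.ptp(w) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(dist, w)
    return float(r), float(p)
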