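"""Two-population tractography and the permutation divergence test.

Two subgroups get their own temporal networks and shortest paths, computed
on a shared (pooled-sample) embedding so coordinates are comparable.  Paths
are matched across populations by their (start item, end item) pair; the
matched pairs are clustered into bundles on 18-dimensional vectors (shared
start, each population's TL1-exit and TL2-entry, shared end).  A bundle's
divergence statistic is the ratio of the mean between-population anchor
distance (across its matched pairs) to the mean within-population pairwise
distance; its null distribution comes from reassigning subjects to the two
populations at random (preserving group sizes), rebuilding both networks
and paths, and recomputing the ratio on the bundle's fixed pair set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .config import AnalysisConfig
from .embedding import NetworkEmbedding, embed_network
from .network import build_networks
from .panel import EMAPanel
from .tract import BehavioralPath, MLN3D, assemble_3d, shortest_interlayer_paths, _auto_k

__all__ = [
    "TwoPopulationBundle",
    "DivergenceResult",
    "TwoPopulationTract",
    "two_population_cluster",
    "two_population_tractography",
    "bundle_divergence_test",
    "bundle_divergence_tests",
]

PairKey = tuple[str, str]


@dataclass(eq=False)
class TwoPopulationBundle:
    """A bundle of matched path pairs shared by both populations."""

    id: int
    pair_keys: list[PairKey]
    centroid: np.ndarray                       # 18 reals
    paths_a: dict[PairKey, BehavioralPath]
    paths_b: dict[PairKey, BehavioralPath]


@dataclass(eq=False)
class DivergenceResult:
    bundle_id: int
    ratio: float
    p: float
    n_permutations: int
    seed: int
    n_pairs: int
    perm_ratios: Optional[np.ndarray] = None


@dataclass
class TwoPopulationTract:
    embedding: NetworkEmbedding
    paths_a: dict[PairKey, BehavioralPath]
    paths_b: dict[PairKey, BehavioralPath]
    bundles: list[TwoPopulationBundle]
    group_names: tuple[str, str]


def _path_index(paths: Sequence[BehavioralPath]) -> dict[PairKey, BehavioralPath]:
    return {(p.start_item, p.end_item): p for p in paths}


def _pair_vector(pa: BehavioralPath, pb: BehavioralPath) -> np.ndarray:
    """18-dim matched-pair vector: start, exit-A, exit-B, entry-A, entry-B, end."""
    a, b = pa.anchors, pb.anchors
    return np.concatenate(
        [a.start, a.exit_tl1, b.exit_tl1, a.entry_tl2, b.entry_tl2, a.end]
    )


def two_population_cluster(
    paths_a: Sequence[BehavioralPath],
    paths_b: Sequence[BehavioralPath],
    k: Union[int, str] = "auto",
    seed: int = 0,
) -> list[TwoPopulationBundle]:
    """k-means bundles over matched (start, end) pairs of both populations."""
    ia, ib = _path_index(paths_a), _path_index(paths_b)
    keys = sorted(set(ia) & set(ib))
    if not keys:
        raise ValueError("no (start, end) pair is reachable in both populations")
    X = np.vstack([_pair_vector(ia[kk], ib[kk]) for kk in keys])
    if k == "auto":
        k = _auto_k(X, seed)
    k = int(k)
    if k > len(keys):
        raise ValueError(f"k={k} exceeds the number of matched pairs ({len(keys)})")
    if k == 1:
        labels = np.zeros(len(keys), dtype=int)
    else:
        labels = KMeans(n_clusters=k, n_init=50, random_state=seed).fit_predict(X)
    bundles = []
    for b in range(k):
        members = [kk for kk, l in zip(keys, labels) if l == b]
        if not members:
            continue
        centroid = np.vstack(
            [_pair_vector(ia[kk], ib[kk]) for kk in members]
        ).mean(axis=0)
        bundles.append(
            TwoPopulationBundle(
                id=b,
                pair_keys=members,
                centroid=centroid,
                paths_a={kk: ia[kk] for kk in members},
                paths_b={kk: ib[kk] for kk in members},
            )
        )
    return bundles


# ---------------------------------------------------------------------------
# Pipeline helpers
# ---------------------------------------------------------------------------

def _group_path_index(
    panel: EMAPanel,
    subject_ids: Sequence,
    config: AnalysisConfig,
    embedding: NetworkEmbedding,
) -> dict[PairKey, BehavioralPath]:
    """Networks + shortest paths for one subject subset on a fixed embedding."""
    import warnings

    sub = panel.subject_panel(subject_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nets = build_networks(sub, config)
    mln = assemble_3d(embedding, nets["multilayer"], config.length_transform)
    return _path_index(shortest_interlayer_paths(mln))


def pooled_embedding(panel: EMAPanel, config: AnalysisConfig) -> NetworkEmbedding:
    """Cross-sectional network embedding of the full (pooled) sample."""
    nets = build_networks(panel, config)
    return embed_network(
        nets["cross_sectional"], diagonal=config.embedding_diagonal
    )


def two_population_tractography(
    panel: EMAPanel,
    groups: pd.Series,
    config: Optional[AnalysisConfig] = None,
    embedding: Optional[NetworkEmbedding] = None,
) -> TwoPopulationTract:
    """Group-specific paths and shared bundles for a binary subject grouping."""
    config = config or AnalysisConfig()
    names = sorted(pd.unique(groups.dropna()))
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, got {names}")
    if embedding is None:
        embedding = pooled_embedding(panel, config)
    ids_a = list(groups.index[groups == names[0]])
    ids_b = list(groups.index[groups == names[1]])
    pa = _group_path_index(panel, ids_a, config, embedding)
    pb = _group_path_index(panel, ids_b, config, embedding)
    bundles = two_population_cluster(
        list(pa.values()), list(pb.values()), k=config.n_bundles,
        seed=config.rng_seed,
    )
    return TwoPopulationTract(
        embedding=embedding,
        paths_a=pa,
        paths_b=pb,
        bundles=bundles,
        group_names=(names[0], names[1]),
    )


# ---------------------------------------------------------------------------
# Divergence statistic and permutation null
# ---------------------------------------------------------------------------

def _divergence_ratio(
    pair_keys: Sequence[PairKey],
    pa: dict[PairKey, BehavioralPath],
    pb: dict[PairKey, BehavioralPath],
) -> Optional[float]:
    """Between/within anchor-distance ratio on the bundle's matched pairs.

    Pairs unreachable in either population are dropped; returns None when
    fewer than 2 pairs survive.  A zero within-group spread yields +inf if
    the populations differ, else 0.
    """
    keys = [kk for kk in pair_keys if kk in pa and kk in pb]
    if len(keys) < 2:
        return None
    va = np.vstack([pa[kk].anchors.vector for kk in keys])
    vb = np.vstack([pb[kk].anchors.vector for kk in keys])
    between = float(np.mean(np.linalg.norm(va - vb, axis=1)))
    within_d = [
        np.linalg.norm(V[i] - V[j])
        for V in (va, vb)
        for i, j in combinations(range(len(keys)), 2)
    ]
    within = float(np.mean(within_d))
    if within == 0.0:
        return np.inf if between > 0 else 0.0
    return between / within


def bundle_divergence_tests(
    panel: EMAPanel,
    groups: pd.Series,
    config: Optional[AnalysisConfig] = None,
    tract: Optional[TwoPopulationTract] = None,
    keep_perm_ratios: bool = False,
) -> list[DivergenceResult]:
    """Permutation divergence test for every bundle.

    One permutation loop serves all bundles: each permutation reassigns
    subjects to the two populations (sizes preserved), rebuilds both
    networks and paths on the fixed pooled embedding, and recomputes each
    bundle's ratio on its fixed (start, end) pair set.  p is the proportion
    of permuted ratios >= the observed one; a permutation whose ratio is
    undefined counts as not exceeding.
    """
    config = config or AnalysisConfig()
    if tract is None:
        tract = two_population_tractography(panel, groups, config)
    name_a, name_b = tract.group_names
    ids = list(groups.dropna().index)
    labels = groups.dropna()
    n_a = int((labels == name_a).sum())

    observed: dict[int, float] = {}
    for b in tract.bundles:
        if len(b.pair_keys) < 2:
            raise ValueError(f"bundle {b.id} has fewer than 2 matched pairs")
        obs = _divergence_ratio(b.pair_keys, tract.paths_a, tract.paths_b)
        observed[b.id] = obs if obs is not None else np.nan

    rng = np.random.default_rng(config.rng_seed)
    perm_ratios: dict[int, list[float]] = {b.id: [] for b in tract.bundles}
    for _ in range(config.n_permutations):
        perm = rng.permutation(ids)
        ids_a, ids_b = perm[:n_a], perm[n_a:]
        pa = _group_path_index(panel, ids_a, config, tract.embedding)
        pb = _group_path_index(panel, ids_b, config, tract.embedding)
        for b in tract.bundles:
            r = _divergence_ratio(b.pair_keys, pa, pb)
            perm_ratios[b.id].append(-np.inf if r is None else r)

    results = []
    for b in tract.bundles:
        ratios = np.array(perm_ratios[b.id])
        obs = observed[b.id]
        p = float(np.mean(ratios >= obs)) if np.isfinite(obs) else np.nan
        results.append(
            DivergenceResult(
                bundle_id=b.id,
                ratio=obs,
                p=p,
                n_permutations=config.n_permutations,
                seed=config.rng_seed,
                n_pairs=len(b.pair_keys),
                perm_ratios=ratios if keep_perm_ratios else None,
            )
        )
    return results


def bundle_divergence_test(
    panel: EMAPanel,
    groups: pd.Series,
    bundle_id: int,
    config: Optional[AnalysisConfig] = None,
    tract: Optional[TwoPopulationTract] = None,
) -> DivergenceResult:
    """Permutation divergence test for a single bundle id."""
    results = bundle_divergence_tests(panel, groups, config, tract)
    for r in results:
        if r.bundle_id == bundle_id:
            return r
    raise KeyError(f"no bundle with id {bundle_id}")
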