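"""3D assembly, shortest paths, anchors, bundles, diffusion, betweenness."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import btract as bt
from btract.embedding import NetworkEmbedding
from btract.network import NetworkMatrix, assemble_multilayer
from btract.tract import (
    BehavioralPath,
    PathAnchorVector,
    behavioral_diffusion,
    extract_anchors,
    longitudinal_betweenness,
)


def build_mln(items, cross, lagged, coords=None):
    """Assemble an MLN3D from raw cross/lagged weight matrices."""
    k = len(items)
    cross = np.asarray(cross, dtype=float)
    lagged = np.asarray(lagged, dtype=float)
    cn = NetworkMatrix("cross_sectional", cross, tuple(items), cross != 0)
    ln = NetworkMatrix("lagged", lagged, tuple(items), lagged != 0)
    ml = assemble_multilayer(cn, ln)
    if coords is None:
        ang = np.linspace(0, 2 * np.pi, k, endpoint=False)
        coords = np.column_stack([np.cos(ang), np.sin(ang)])
    emb = NetworkEmbedding(
        pd.DataFrame(coords, index=list(items), columns=["x", "y"]),
        np.array([0.5, 0.3]), np.nan, np.nan,
    )
    return bt.assemble_3d(emb, ml)


class TestAssemble3D:
    def test_all_zero_network_has_isolated_nodes(self):
        mln = build_mln(("A", "B"), np.zeros((2, 2)), np.zeros((2, 2)))
        assert len(mln.nodes) == 4 and len(mln.edges) == 0

    def test_inverse_abs_length(self):
        lag = np.array([[0.5, 0], [0, 0]])
        mln = build_mln(("A", "B"), np.zeros((2, 2)), lag)
        (edge,) = mln.edges
        assert edge.length == pytest.approx(2.0)
        assert edge.kind == "between"

    def test_edge_counts_match_masks(self, coupled_networks):
        emb = bt.embed_network(coupled_networks["cross_sectional"])
        mln = bt.assemble_3d(emb, coupled_networks["multilayer"])
        cross_mask = coupled_networks["cross_sectional"].mask
        lag_mask = coupled_networks["lagged"].mask
        n_within = sum(1 for e in mln.edges if e.kind == "within")
        n_between = sum(1 for e in mln.edges if e.kind == "between")
        assert n_within == cross_mask.sum()  # upper triangle x 2 layers
        assert n_between == lag_mask.sum()

    def test_negative_weights_conduct(self):
        lag = np.array([[-0.25, 0], [0, 0]])
        mln = build_mln(("A", "B"), np.zeros((2, 2)), lag)
        assert mln.edges[0].length == pytest.approx(4.0)


class TestShortestPaths:
    def test_direct_lagged_edge(self):
        lag = np.array([[1.0, 0], [0, 0]])
        mln = build_mln(("A", "B"), np.zeros((2, 2)), lag)
        paths = bt.shortest_interlayer_paths(mln)
        assert len(paths) == 1
        (p,) = paths
        assert p.node_sequence == [("A", "TL1"), ("A", "TL2")]
        a = p.anchors
        np.testing.assert_array_equal(a.start, a.exit_tl1)
        np.testing.assert_array_equal(a.entry_tl2, a.end)

    def test_detour_beats_weak_direct_edge(self):
        # direct A->A lagged length 5; detour A-B (1) + B->B lagged (1) + B-A (1) = 3
        cross = np.array([[0, 1.0], [1.0, 0]])
        lagged = np.array([[0.2, 0], [0, 1.0]])
        mln = build_mln(("A", "B"), cross, lagged)
        paths = {(p.start_item, p.end_item): p for p in bt.shortest_interlayer_paths(mln)}
        p = paths[("A", "A")]
        assert p.total_length == pytest.approx(3.0)
        assert p.node_sequence == [("A", "TL1"), ("B", "TL1"),
                                   ("B", "TL2"), ("A", "TL2")]

    def test_unreachable_pairs_counted(self):
        lag = np.array([[1.0, 0], [0, 0]])
        mln = build_mln(("A", "B"), np.zeros((2, 2)), lag)
        paths, unreachable = bt.shortest_interlayer_paths(mln, return_unreachable=True)
        assert len(paths) == 1 and len(unreachable) == 3

    def test_matches_exhaustive_enumeration(self):
        """Dijkstra agrees with brute-force simple-path search on random graphs."""
        rng = np.random.default_rng(0)
        for _ in range(30):
            k = rng.integers(3, 7)
            items = tuple(f"I{i}" for i in range(k))
            cross = np.zeros((k, k))
            iu = np.triu_indices(k, 1)
            w = np.where(rng.random(len(iu[0])) < 0.5,
                         rng.uniform(0.2, 1.5, len(iu[0])), 0.0)
            cross[iu] = w
            cross += cross.T
            lagged = np.where(rng.random((k, k)) < 0.3,
                              rng.uniform(0.2, 1.5, (k, k)), 0.0)
            mln = build_mln(items, cross, lagged)
            got = {(p.start_item, p.end_item): p.total_length
                   for p in bt.shortest_interlayer_paths(mln)}
            want = _enumerate_shortest(mln, items)
            assert set(got) == set(want)
            for key in want:
                assert got[key] == pytest.approx(want[key], rel=1e-9)

    def test_scaling_covariance(self, coupled_networks):
        emb = bt.embed_network(coupled_networks["cross_sectional"])
        ml = coupled_networks["multilayer"]
        mln1 = bt.assemble_3d(emb, ml)
        scaled = NetworkMatrix(ml.kind, ml.weights * 3.0, ml.labels, ml.mask)
        mln2 = bt.assemble_3d(emb, scaled)
        p1 = bt.shortest_interlayer_paths(mln1)
        p2 = bt.shortest_interlayer_paths(mln2)
        assert [p.node_sequence for p in p1] == [p.node_sequence for p in p2]
        for a, b in zip(p1, p2):
            assert b.total_length == pytest.approx(a.total_length / 3.0)


def _enumerate_shortest(mln, items):
    g = nx.DiGraph()
    for u, nbrs in mln.adjacency.items():
        for v, length in nbrs:
            g.add_edge(u, v, length=length)
    out = {}
    for s in items:
        for t in items:
            src, dst = (s, "TL1"), (t, "TL2")
            if src not in g or dst not in g:
                continue
            best = np.inf
            for path in nx.all_simple_paths(g, src, dst):
                total = sum(g[a][b]["length"] for a, b in zip(path, path[1:]))
                best = min(best, total)
            if np.isfinite(best):
                out[(s, t)] = best
    return out


class TestAnchors:
    def test_multi_hop_anchor_selection(self):
        cross = np.array([[0, 1.0, 0], [1.0, 0, 0], [0, 0, 0]])
        lagged = np.zeros((3, 3))
        lagged[1, 2] = 1.0
        coords = np.array([[0, 0], [1, 0], [1, 1.0]])
        mln = build_mln(("A", "B", "C"), cross, lagged, coords)
        paths = {(p.start_item, p.end_item): p
                 for p in bt.shortest_interlayer_paths(mln)}
        p = paths[("A", "C")]
        a = p.anchors
        np.testing.assert_allclose(a.start, [0, 0, 0])
        np.testing.assert_allclose(a.exit_tl1, [1, 0, 0])   # B leaves TL1
        np.testing.assert_allclose(a.entry_tl2, [1, 1, 1])  # C enters TL2
        assert {a.start[2], a.exit_tl1[2]} == {0.0}
        assert {a.entry_tl2[2], a.end[2]} == {1.0}

    def test_no_transition_rejected(self):
        p = BehavioralPath("A", "B", [("A", "TL1"), ("B", "TL1")],
                           [np.zeros(3), np.ones(3)], 1.0,
                           anchors=PathAnchorVector(*[np.zeros(3)] * 4))
        p.anchors = None
        with pytest.raises(ValueError, match="transition"):
            extract_anchors(p)


def _synthetic_path(start_xy, end_xy, jitter, rng):
    s = np.array([*start_xy, 0.0]) + np.r_[rng.normal(0, jitter, 2), 0]
    e = np.array([*end_xy, 1.0]) + np.r_[rng.normal(0, jitter, 2), 0]
    return BehavioralPath(
        "A", "B", [("A", "TL1"), ("B", "TL2")], [s, e],
        total_length=1.0,
    )


class TestBundles:
    def test_two_separated_families_recovered(self):
        rng = np.random.default_rng(0)
        fam1 = [_synthetic_path((-5, -5), (-5, 5), 0.3, rng) for _ in range(25)]
        fam2 = [_synthetic_path((5, 5), (5, -5), 0.3, rng) for _ in range(25)]
        bundles = bt.cluster_bundles(fam1 + fam2, k=2, seed=0)
        labels = np.zeros(50, dtype=int)
        for b in bundles:
            for p in b.member_paths:
                labels[(fam1 + fam2).index(p)] = b.id
        truth = [0] * 25 + [1] * 25
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_single_bundle_centroid_is_mean(self):
        rng = np.random.default_rng(1)
        paths = [_synthetic_path((0, 0), (1, 1), 0.5, rng) for _ in range(10)]
        (b,) = bt.cluster_bundles(paths, k=1, seed=0)
        np.testing.assert_allclose(
            b.centroid, np.vstack([p.anchors.vector for p in paths]).mean(axis=0)
        )

    def test_duplication_leaves_centroids_unchanged(self):
        rng = np.random.default_rng(2)
        fam1 = [_synthetic_path((-5, -5), (-5, 5), 0.3, rng) for _ in range(10)]
        fam2 = [_synthetic_path((5, 5), (5, -5), 0.3, rng) for _ in range(10)]
        b1 = bt.cluster_bundles(fam1 + fam2, k=2, seed=0)
        b2 = bt.cluster_bundles(fam1 + fam2 + fam1 + fam2, k=2, seed=0)
        c1 = sorted(tuple(np.round(b.centroid, 8)) for b in b1)
        c2 = sorted(tuple(np.round(b.centroid, 8)) for b in b2)
        assert c1 == c2

    def test_k_exceeding_paths_rejected(self):
        rng = np.random.default_rng(3)
        paths = [_synthetic_path((0, 0), (1, 1), 0.1, rng) for _ in range(3)]
        with pytest.raises(ValueError, match="exceeds"):
            bt.cluster_bundles(paths, k=5, seed=0)


class TestDiffusion:
    def test_single_successor_displacement(self):
        p = BehavioralPath(
            "A", "A", [("A", "TL1"), ("A", "TL2")],
            [np.array([0.0, 0, 0]), np.array([1.0, 0, 1])], 1.0,
        )
        d = behavioral_diffusion(("A", "TL1"), [p])
        np.testing.assert_allclose(d.direction, [1, 0, 1])
        assert d.n_paths == 1

    def test_mean_of_two_paths(self):
        p1 = BehavioralPath("A", "A", [("A", "TL1"), ("A", "TL2")],
                            [np.zeros(3), np.array([1.0, 0, 1])], 1.0)
        p2 = BehavioralPath("A", "B", [("A", "TL1"), ("B", "TL2")],
                            [np.zeros(3), np.array([0.0, 1, 1])], 1.0)
        d = behavioral_diffusion(("A", "TL1"), [p1, p2])
        np.testing.assert_allclose(d.direction, [0.5, 0.5, 1.0])

    def test_untraversed_node_flagged(self):
        d = behavioral_diffusion(("Z", "TL1"), [])
        assert d.n_paths == 0 and not d.direction.any()

    def test_dz_never_negative(self, coupled_networks):
        emb = bt.embed_network(coupled_networks["cross_sectional"])
        mln = bt.assemble_3d(emb, coupled_networks["multilayer"])
        paths = bt.shortest_interlayer_paths(mln)
        for key in mln.node_keys():
            d = behavioral_diffusion(key, paths)
            assert d.direction[2] >= 0


class TestBetweenness:
    def test_bottleneck_item_dominates(self):
        # all TL1 items connect to H; only H has a lagged edge; H fans out in TL2
        items = ("A", "B", "H")
        cross = np.zeros((3, 3))
        cross[0, 2] = cross[2, 0] = 1.0
        cross[1, 2] = cross[2, 1] = 1.0
        lagged = np.zeros((3, 3))
        lagged[2, 2] = 1.0
        mln = build_mln(items, cross, lagged)
        paths = bt.shortest_interlayer_paths(mln)
        node_counts, _ = longitudinal_betweenness(mln, paths)
        assert node_counts[("H", "TL1")] == max(
            node_counts[k] for k in node_counts if k[1] == "TL1"
        )
        assert node_counts[("H", "TL2")] == max(
            node_counts[k] for k in node_counts if k[1] == "TL2"
        )

    def test_empty_path_set(self):
        mln = build_mln(("A", "B"), np.zeros((2, 2)), np.zeros((2, 2)))
        node_counts, edge_counts = longitudinal_betweenness(mln, [])
        assert not any(node_counts.values()) and not edge_counts

    def test_counts_lower_bound(self, coupled_networks):
        emb = bt.embed_network(coupled_networks["cross_sectional"])
        mln = bt.assemble_3d(emb, coupled_networks["multilayer"])
        paths = bt.shortest_interlayer_paths(mln)
        node_counts, _ = longitudinal_betweenness(mln, paths)
        assert sum(node_counts.values()) >= 2 * len(paths)
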