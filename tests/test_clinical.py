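"""Clinical dimensions: rare-item filter, PCA, subgroups, group statistics."""

import numpy as np
import pandas as pd
import pytest

import btract as bt
from btract.panel import SIPSTable
from conftest import make_panel


def _sips(matrix, items=None, subjects=None):
    matrix = np.asarray(matrix, dtype=float)
    items = items or [f"I{j}" for j in range(matrix.shape[1])]
    subjects = subjects or [f"s{i}" for i in range(matrix.shape[0])]
    return SIPSTable(pd.DataFrame(matrix, index=subjects, columns=items))


class TestFilterRareItems:
    def test_all_zero_item_dropped(self):
        X = np.ones((68, 3))
        X[:, 1] = 0
        out = bt.filter_rare_items(_sips(X), 0.10)
        assert out.item_names == ("I0", "I2")
        assert out.dropped_items == ("I1",)

    def test_strictly_greater_retention(self):
        # nonzero in 7/68 = 10.3% > 10% -> retained; 6/68 = 8.8% -> dropped
        X = np.zeros((68, 3))
        X[:, 0] = 1
        X[:7, 1] = 1
        X[:6, 2] = 1
        out = bt.filter_rare_items(_sips(X), 0.10)
        assert out.item_names == ("I0", "I1")

    def test_rare_grandiosity_like_item_excluded(self):
        # an item endorsed by <=10% of subjects is excluded, like SIPS P3
        X = np.ones((68, 2))
        X[6:, 1] = 0  # 6/68 = 8.8%
        out = bt.filter_rare_items(_sips(X, items=["P1", "P3"]), 0.10)
        assert "P3" in out.dropped_items

    def test_all_items_dropped_is_error(self):
        with pytest.raises(ValueError, match="every item"):
            bt.filter_rare_items(_sips(np.zeros((10, 2))), 0.10)


class TestSipsPCA:
    def test_retained_counts_components_above_threshold(self):
        rng = np.random.default_rng(0)
        # one dominant factor + one moderate factor + noise
        f1, f2 = rng.normal(size=(2, 200))
        X = np.clip(np.round(3 + np.outer(f1, np.full(6, 1.2))
                             + np.outer(f2, [1, -1, 1, -1, 0, 0]) * 0.6
                             + rng.normal(0, 0.3, (200, 6))), 0, 6)
        model = bt.fit_sips_pca(_sips(X), threshold=0.10)
        frac = model.explained_variance
        assert model.retained == int(np.sum(frac > 0.10))
        assert model.retained >= 2

    def test_rank_one_case(self):
        base = np.tile(np.arange(6.0), 2)[:10]
        X = np.column_stack([base, base, np.full(10, 3.0)])
        model = bt.fit_sips_pca(_sips(X))
        assert model.explained_variance[0] == pytest.approx(1.0)

    def test_explained_variance_matches_eigendecomposition(self):
        rng = np.random.default_rng(3)
        X = np.round(np.clip(rng.normal(3, 1.2, (20, 6)), 0, 6))
        model = bt.fit_sips_pca(_sips(X))
        eig = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        np.testing.assert_allclose(model.explained_variance[: len(eig)],
                                   eig / eig.sum(), atol=1e-10)

    def test_severity_orientation(self):
        rng = np.random.default_rng(4)
        f = rng.normal(size=100)
        X = np.clip(np.round(2 + np.outer(f, np.full(5, 1.0))
                             + rng.normal(0, 0.2, (100, 5))), 0, 6)
        model = bt.fit_sips_pca(_sips(X))
        assert (model.loadings.iloc[:, 0] > 0).all()

    def test_reconstruction_with_all_components(self):
        rng = np.random.default_rng(5)
        X = np.round(np.clip(rng.normal(3, 1.0, (15, 4)), 0, 6))
        model = bt.fit_sips_pca(_sips(X))
        recon = model.scores.to_numpy() @ model.loadings.to_numpy().T
        np.testing.assert_allclose(recon + model.column_means.to_numpy(), X,
                                   atol=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            bt.fit_sips_pca(_sips(np.full((5, 3), 2.0)))


class TestAssignSubgroups:
    def test_separated_clusters(self):
        scores = pd.Series([-1, -1, -1, 5, 5], index=list("abcde"), dtype=float)
        sub = bt.assign_subgroups(scores, k=2, seed=0)
        assert sorted(sub.group("low")) == ["a", "b", "c"]
        assert sorted(sub.group("high")) == ["d", "e"]

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            bt.assign_subgroups(pd.Series(np.ones(10)), k=2, seed=0)

    def test_matches_best_threshold_split(self):
        """1-D 2-means equals the exhaustive best single-threshold split."""
        rng = np.random.default_rng(8)
        x = np.sort(np.concatenate([rng.normal(-1, 1, 120), rng.normal(2, 1, 80)]))
        scores = pd.Series(x, index=range(200))
        sub = bt.assign_subgroups(scores, k=2, seed=0)
        got = (scores[sub.labels == "high"].min()
               + scores[sub.labels == "low"].max()) / 2

        best_inertia, best_cut = np.inf, None
        for i in range(1, 200):
            lo, hi = x[:i], x[i:]
            inertia = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
            if inertia < best_inertia:
                best_inertia, best_cut = inertia, (x[i - 1] + x[i]) / 2
        assert got == pytest.approx(best_cut)

    def test_label_exchange_under_sign_flip(self):
        rng = np.random.default_rng(2)
        scores = pd.Series(rng.normal(size=30).round(3), index=range(30))
        a = bt.assign_subgroups(scores, seed=0)
        b = bt.assign_subgroups(-scores, seed=0)
        assert set(a.group("high")) == set(b.group("low"))


class TestGroupStatistics:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[0, 52], [4, 12]], 13.81),   # psychotic-disorder counts
            ([[30, 22], [11, 5]], 0.62),   # ADHD counts
            ([[27, 25], [10, 6]], 0.55),   # sex split, severity subgroups
            ([[21, 12], [16, 19]], 2.20),  # sex split, valence subgroups
        ],
    )
    def test_chi_square_published_counts(self, table, expected):
        assert bt.chi_square_2x2(table).statistic == pytest.approx(expected, abs=0.005)

    def test_chi_square_identical_rows_is_zero(self):
        assert bt.chi_square_2x2([[13, 8], [13, 8]]).statistic == pytest.approx(0)

    def test_chi_square_symmetries(self):
        t = np.array([[9, 4], [3, 11]])
        base = bt.chi_square_2x2(t).statistic
        for variant in (t[::-1], t[:, ::-1], t.T):
            assert bt.chi_square_2x2(variant).statistic == pytest.approx(base)

    def test_chi_square_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            bt.chi_square_2x2([[0, 0], [3, 4]])

    def test_t_from_published_summaries(self):
        res = bt.two_sample_t((19.48, 5.17, 52), (18.88, 5.36, 16))
        assert res.statistic == pytest.approx(0.40, abs=0.005)
        assert res.p == pytest.approx(0.69, abs=0.005)

    def test_t_identical_summaries_zero(self):
        assert bt.two_sample_t((3.0, 1.0, 10), (3.0, 1.0, 10)).statistic == 0

    def test_t_identical_raw_vectors_zero(self):
        v = np.array([1.0, 2.0, 3.0])
        assert bt.two_sample_t(v, v).statistic == 0

    def test_t_raw_matches_summary_route(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1.2, 15)
        raw = bt.two_sample_t(a, b)
        summ = bt.two_sample_t((a.mean(), a.std(ddof=1), 20),
                               (b.mean(), b.std(ddof=1), 15))
        assert raw.statistic == pytest.approx(summ.statistic)


class TestIntensityAssociations:
    def _panel_from_means(self, means):
        rows = []
        for i, m in enumerate(means):
            rows.append((f"s{i}", 1, 1, {"A": m, "B": 4}))
        return make_panel(rows, items=("A", "B"))

    def test_perfect_correlation(self):
        means = [1, 2, 3, 4, 5]
        panel = self._panel_from_means(means)
        scores = pd.Series(means, index=[f"s{i}" for i in range(5)], dtype=float)
        assoc = {a.item: a for a in bt.correlate_item_intensity(panel, scores)}
        assert assoc["A"].r == pytest.approx(1.0)

    def test_constant_item_flagged_excluded(self):
        panel = self._panel_from_means([1, 2, 3, 4, 5])
        scores = pd.Series([1, 2, 3, 4, 5.0], index=[f"s{i}" for i in range(5)])
        assoc = {a.item: a for a in bt.correlate_item_intensity(panel, scores)}
        assert assoc["B"].excluded and np.isnan(assoc["B"].r)

    def test_permuted_scores_center_on_zero(self):
        rng = np.random.default_rng(0)
        means = rng.integers(1, 8, 30).astype(float)
        panel = self._panel_from_means(means)
        scores = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        rs = []
        for _ in range(100):
            perm = pd.Series(rng.permutation(scores.to_numpy()), index=scores.index)
            rs.append(bt.correlate_item_intensity(panel, perm)[0].r)
        assert abs(np.mean(rs)) < 0.1

    def test_subgroup_t_test_attached(self, null_cohort):
        panel = null_cohort.panel
        sids = panel.subjects
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.normal(size=len(sids)), index=sids)
        sub = bt.assign_subgroups(scores, seed=0)
        assoc = bt.correlate_item_intensity(panel, scores, sub)
        with_t = [a for a in assoc if a.t_p is not None]
        assert len(with_t) >= 5
        assert all(0 <= a.t_p <= 1 for a in with_t)
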