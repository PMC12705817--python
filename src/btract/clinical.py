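"""Clinical-interview side of the pipeline.

Rare-item filtering, PCA decomposition of interview scores into a severity
dimension and a positive-vs-negative contrast, k-means subgrouping on a
single dimension, and the subgroup/intensity statistics reported alongside
(chi-square tests on diagnosis counts, pooled two-sample t tests, Pearson
correlations of per-subject mean EMA intensity with dimension scores).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .panel import EMAPanel, SIPSTable

__all__ = [
    "DimensionModel",
    "SubgroupAssignment",
    "GroupComparisonResult",
    "IntensityAssociation",
    "filter_rare_items",
    "fit_sips_pca",
    "assign_subgroups",
    "chi_square_2x2",
    "two_sample_t",
    "correlate_item_intensity",
]


@dataclass
class DimensionModel:
    """PCA decomposition of the clinical item matrix."""

    loadings: pd.DataFrame            # item x component
    explained_variance: np.ndarray    # fraction per component (all components)
    scores: pd.DataFrame              # subject x component
    retained: int
    column_means: pd.Series
    standardized: bool = False

    def score(self, component: int) -> pd.Series:
        """Per-subject score on a 1-based component index."""
        return self.scores.iloc[:, component - 1]


@dataclass
class SubgroupAssignment:
    dimension: int
    labels: pd.Series          # subject -> low/high (or neg/pos)
    centroids: tuple[float, float]

    def group(self, name: str) -> list:
        return list(self.labels.index[self.labels == name])


@dataclass
class GroupComparisonResult:
    variable: str
    kind: str                  # "chi2_2x2" or "two_sample_t"
    statistic: float
    p: float
    group_summaries: dict


@dataclass
class IntensityAssociation:
    item: str
    r: float
    p: float
    n_subjects: int
    group_means: Optional[dict] = None
    t_p: Optional[float] = None
    excluded: bool = False


# ---------------------------------------------------------------------------

def filter_rare_items(
    sips: SIPSTable, min_nonzero_fraction: float = 0.10
) -> SIPSTable:
    """Drop items endorsed (non-zero) in at most the given fraction of subjects.

    Retention is strict: an item survives only when its non-zero rate is
    strictly greater than the threshold.
    """
    if not (0.0 < min_nonzero_fraction < 1.0):
        raise ValueError("min_nonzero_fraction must lie in (0, 1)")
    frac = (sips.data > 0).mean(axis=0)
    keep = frac[frac > min_nonzero_fraction].index
    dropped = tuple(c for c in sips.data.columns if c not in set(keep))
    if len(keep) == 0:
        raise ValueError("rare-item filter would drop every item")
    return SIPSTable(sips.data[list(keep)], dropped_items=sips.dropped_items + dropped)


def fit_sips_pca(
    sips: SIPSTable,
    threshold: float = 0.10,
    standardize: bool = False,
) -> DimensionModel:
    """Mean-centered (unscaled by default) PCA of the clinical item matrix.

    Components are ordered by explained variance; a component is retained
    when its variance fraction strictly exceeds ``threshold``.  Component 1
    is oriented so its mean loading is positive, i.e. it reads as overall
    severity.
    """
    X = sips.data.to_numpy(dtype=float)
    n, m = X.shape
    if n < 3 or m < 2:
        raise ValueError("need at least 3 subjects and 2 items")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant item; cannot standardize")
        X = X / sd
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("zero-variance matrix")
    pca = PCA()
    scores = pca.fit_transform(X)
    loadings = pca.components_.T            # item x component
    # orient component 1 as severity (mean loading positive); other
    # components keep sklearn's deterministic svd_flip orientation
    if loadings[:, 0].mean() < 0:
        loadings[:, 0] *= -1
        scores[:, 0] *= -1
    frac = pca.explained_variance_ratio_
    retained = int(np.sum(frac > threshold))
    comp_names = [f"Dim{c+1}" for c in range(loadings.shape[1])]
    return DimensionModel(
        loadings=pd.DataFrame(loadings, index=sips.data.columns, columns=comp_names),
        explained_variance=frac,
        scores=pd.DataFrame(scores, index=sips.data.index, columns=comp_names),
        retained=retained,
        column_means=pd.Series(pca.mean_, index=sips.data.columns),
        standardized=standardize,
    )


def assign_subgroups(
    scores: pd.Series,
    k: int = 2,
    seed: int = 0,
    dimension: int = 1,
    label_names: Optional[tuple[str, str]] = None,
) -> SubgroupAssignment:
    """1-D k-means subgrouping on a single dimension score.

    With the default k=2 the higher-centroid group is labeled "high" (or
    "pos" when ``dimension`` is 2, matching the positive-vs-negative
    contrast); 50 restarts, deterministic given ``seed``.
    """
    x = scores.to_numpy(dtype=float)
    if k < 2 or len(x) <= k:
        raise ValueError("need k >= 2 and more points than clusters")
    if len(np.unique(x)) < k:
        raise ValueError(f"fewer than {k} distinct score values")
    km = KMeans(n_clusters=k, n_init=50, random_state=seed)
    raw = km.fit_predict(x[:, None])
    centers = km.cluster_centers_.ravel()
    if label_names is None:
        label_names = ("neg", "pos") if dimension == 2 else ("low", "high")
    if k != 2:
        names = [f"g{r+1}" for r in np.argsort(np.argsort(centers))]
    else:
        order = np.argsort(centers)  # low centroid first
        names = [None, None]
        names[order[0]], names[order[1]] = label_names
    labels = pd.Series([names[c] for c in raw], index=scores.index, name="subgroup")
    return SubgroupAssignment(
        dimension=dimension,
        labels=labels,
        centroids=tuple(np.sort(centers)[:2]) if k == 2 else tuple(np.sort(centers)),
    )


def chi_square_2x2(
    table: Sequence[Sequence[int]], variable: str = ""
) -> GroupComparisonResult:
    """Pearson chi-square on a 2x2 count table, df=1, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 nonnegative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square undefined with a zero marginal")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return GroupComparisonResult(
        variable=variable,
        kind="chi2_2x2",
        statistic=float(stat),
        p=float(p),
        group_summaries={"counts": t.astype(int).tolist()},
    )


def two_sample_t(
    a: Union[tuple[float, float, int], np.ndarray],
    b: Union[tuple[float, float, int], np.ndarray],
    variable: str = "",
) -> GroupComparisonResult:
    """Pooled-variance (Student) two-sample t test.

    Accepts either ``(mean, sd, n)`` summaries or raw vectors.
    """
    def _summ(v):
        if isinstance(v, tuple) and len(v) == 3:
            return float(v[0]), float(v[1]), int(v[2])
        arr = np.asarray(v, dtype=float)
        return float(arr.mean()), float(arr.std(ddof=1)), len(arr)

    m1, s1, n1 = _summ(a)
    m2, s2, n2 = _summ(b)
    if n1 < 2 or n2 < 2 or s1 < 0 or s2 < 0:
        raise ValueError("each group needs n >= 2 and sd >= 0")
    if s1 == 0 and s2 == 0:
        if m1 != m2:
            stat, p = np.inf * np.sign(m1 - m2), 0.0
        else:
            stat, p = 0.0, 1.0
    else:
        stat, p = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return GroupComparisonResult(
        variable=variable,
        kind="two_sample_t",
        statistic=float(stat),
        p=float(p),
        group_summaries={
            "a": {"mean": m1, "sd": s1, "n": n1},
            "b": {"mean": m2, "sd": s2, "n": n2},
        },
    )


def correlate_item_intensity(
    panel: EMAPanel,
    scores: pd.Series,
    subgroups: Optional[SubgroupAssignment] = None,
) -> list[IntensityAssociation]:
    """Pearson r between per-subject mean item intensity and a dimension score.

    Optionally adds an observation-level two-sample t test across the given
    subgroups (this pools prompts within groups, trading independence for
    the large printed-table sample sizes; see the methods note).  A subject
    missing an item at every prompt is excluded for that item; an item with
    no between-subject variance is flagged and excluded.
    """
    means = panel.subject_means()
    common = [s for s in means.index if s in scores.index]
    if len(common) < 3:
        raise ValueError("need at least 3 subjects with both EMA and scores")
    means = means.loc[common]
    sc = scores.loc[common].to_numpy(dtype=float)

    label_of = subgroups.labels if subgroups is not None else None
    out: list[IntensityAssociation] = []
    for item in panel.item_names:
        v = means[item].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        n = int(ok.sum())
        if n < 3 or np.ptp(v[ok]) == 0:
            out.append(IntensityAssociation(item=item, r=np.nan, p=np.nan,
                                            n_subjects=n, excluded=True))
            continue
        r, p = stats.pearsonr(v[ok], sc[ok])
        group_means = None
        t_p = None
        if label_of is not None:
            obs = panel.data[["subject_id", item]].dropna()
            obs = obs[obs["subject_id"].isin(label_of.index)]
            g = obs["subject_id"].map(label_of)
            names = sorted(label_of.unique())
            vecs = [obs.loc[g == name, item].to_numpy(dtype=float) for name in names]
            group_means = {
                name: {"mean": float(v_.mean()), "sd": float(v_.std(ddof=1)),
                       "n": len(v_)}
                for name, v_ in zip(names, vecs) if len(v_)
            }
            if all(len(v_) >= 2 for v_ in vecs) and len(vecs) == 2:
                t_p = two_sample_t(vecs[0], vecs[1], variable=item).p
        out.append(
            IntensityAssociation(item=item, r=float(r), p=float(p), n_subjects=n,
                                 group_means=group_means, t_p=t_p)
        )
    return out
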