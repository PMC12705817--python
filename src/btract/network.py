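"""Edge estimation and network assembly.

Each edge of the temporal symptom network is the fixed slope of a
random-intercept mixed regression of one item on another: contemporaneous
(same prompt) for cross-sectional edges, lag-1 (consecutive prompts) for
longitudinal edges.  Slopes whose Wald p-values fail a Benjamini-Hochberg
step-up at level q are set to zero, one family per matrix kind.  The
cross-sectional matrix is symmetrized by averaging the two directional
slopes; the 40x40 multilayer matrix stacks two copies of it (temporal layers
TL1 and TL2) and places the lagged matrix in the TL1->TL2 block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .mixedlm import MixedFit, fit_random_intercept
from .panel import EMAPanel

__all__ = [
    "EdgeEstimate",
    "NetworkMatrix",
    "ModerationMatrix",
    "fit_edge",
    "fit_moderated_edge",
    "pair_lagged",
    "bh_fdr_mask",
    "build_networks",
    "build_moderated_networks",
]


@dataclass
class EdgeEstimate:
    """A fitted (possibly moderated) pairwise association."""

    outcome_item: str
    predictor_item: str
    lagged: bool
    beta0: float
    beta1: float
    se: float
    p: float
    n_obs: int
    n_subjects: int
    beta2: Optional[float] = None   # moderator main effect
    beta3: Optional[float] = None   # moderation (interaction) coefficient
    q_significant: Optional[bool] = None
    ols_fallback: bool = False

    @property
    def reported_coefficient(self) -> float:
        """beta3 for moderated models, otherwise beta1."""
        return self.beta1 if self.beta3 is None else self.beta3


@dataclass
class NetworkMatrix:
    """Square edge-weight matrix with its significance mask.

    ``weights[i, j]`` is 0 wherever ``mask[i, j]`` is False.  For
    ``kind="lagged"`` row i is the predictor at time t and column j the
    outcome at t+1.  The multilayer matrix is 40x40 with labels tagged
    ``@TL1`` / ``@TL2`` and a structurally zero TL2->TL1 block.
    """

    kind: str
    weights: np.ndarray
    labels: tuple[str, ...]
    mask: np.ndarray
    p_values: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = len(self.labels)
        if self.weights.shape != (n, n) or self.mask.shape != (n, n):
            raise ValueError("weights/mask shape does not match labels")
        if np.any(self.weights[~self.mask] != 0.0):
            raise ValueError("weights must be 0 where the mask is False")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)


@dataclass
class ModerationMatrix:
    """Per-dimension moderation effects (interaction slopes beta3)."""

    dimension: int
    cross_effects: NetworkMatrix
    lagged_effects: NetworkMatrix
    node_effects: Optional[pd.Series] = None


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = np.std(v)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (v - np.mean(v)) / sd


# ---------------------------------------------------------------------------
# Single-edge fits
# ---------------------------------------------------------------------------

def fit_edge(
    y: np.ndarray,
    x: np.ndarray,
    subject_ids: np.ndarray,
    lagged: bool = False,
    outcome_item: str = "y",
    predictor_item: str = "x",
    standardize: bool = False,
) -> EdgeEstimate:
    """Fixed slope of ``y ~ x`` with a per-subject random intercept (REML).

    With a single subject the fit degenerates to ordinary least squares.
    ``standardize`` z-scores x and y over the pooled observations first.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    subject_ids = np.asarray(subject_ids)
    keep = ~(np.isnan(y) | np.isnan(x))
    y, x, subject_ids = y[keep], x[keep], subject_ids[keep]
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant; edge not identifiable")
    if standardize:
        x, y = _zscore(x), _zscore(y)
    X = np.column_stack([np.ones_like(x), x])
    fit = fit_random_intercept(y, X, subject_ids)
    return EdgeEstimate(
        outcome_item=outcome_item,
        predictor_item=predictor_item,
        lagged=lagged,
        beta0=float(fit.beta[0]),
        beta1=float(fit.beta[1]),
        se=float(fit.se[1]),
        p=float(fit.p[1]),
        n_obs=fit.n_obs,
        n_subjects=fit.n_groups,
        ols_fallback=fit.ols_fallback,
    )


def fit_moderated_edge(
    y: np.ndarray,
    x: np.ndarray,
    subject_ids: np.ndarray,
    s: np.ndarray,
    lagged: bool = False,
    outcome_item: str = "y",
    predictor_item: str = "x",
    standardize_s: bool = True,
) -> EdgeEstimate:
    """Fit ``y ~ x + s + x*s`` with a random intercept; reports beta3.

    ``s`` is a per-observation copy of the subject-level dimension score
    (constant within subject), z-scored across subjects by default.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    subject_ids = np.asarray(subject_ids)
    keep = ~(np.isnan(y) | np.isnan(x) | np.isnan(s))
    y, x, s, subject_ids = y[keep], x[keep], s[keep], subject_ids[keep]
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant; edge not identifiable")
    if np.ptp(s) == 0:
        raise ValueError("moderator score is constant; moderation not identifiable")
    if standardize_s:
        # z-score over subjects, not observations, so unequal prompt counts
        # do not reweight the scale
        df = pd.DataFrame({"sid": subject_ids, "s": s})
        per_subj = df.groupby("sid")["s"].first()
        mu, sd = per_subj.mean(), per_subj.std(ddof=0)
        if sd == 0:
            raise ValueError("moderator score is constant across subjects")
        s = (s - mu) / sd
    X = np.column_stack([np.ones_like(x), x, s, x * s])
    fit = fit_random_intercept(y, X, subject_ids)
    return EdgeEstimate(
        outcome_item=outcome_item,
        predictor_item=predictor_item,
        lagged=lagged,
        beta0=float(fit.beta[0]),
        beta1=float(fit.beta[1]),
        beta2=float(fit.beta[2]),
        beta3=float(fit.beta[3]),
        se=float(fit.se[3]),
        p=float(fit.p[3]),
        n_obs=fit.n_obs,
        n_subjects=fit.n_groups,
        ols_fallback=fit.ols_fallback,
    )


# ---------------------------------------------------------------------------
# Lag pairing
# ---------------------------------------------------------------------------

def lagged_row_pairs(panel: EMAPanel, rule: str = "same_day_consecutive") -> np.ndarray:
    """Row-index pairs (t, t+1) of consecutive completed prompts.

    Under ``same_day_consecutive`` two rows pair only when they are the same
    subject, the same day, and adjacent prompt slots; a missed intermediate
    prompt breaks the pair.  ``any_consecutive`` additionally pairs the last
    slot of a day with the first slot of the next day.
    """
    df = panel.data
    sid = df["subject_id"].to_numpy()
    day = df["day"].to_numpy()
    prompt = df["prompt"].to_numpy()
    # panel rows are sorted by subject, day, prompt
    a = np.arange(len(df) - 1)
    b = a + 1
    same_subject = sid[a] == sid[b]
    same_day_next = (day[a] == day[b]) & (prompt[b] == prompt[a] + 1)
    if rule == "same_day_consecutive":
        ok = same_subject & same_day_next
    elif rule == "any_consecutive":
        overnight = (
            (day[b] == day[a] + 1)
            & (prompt[a] == panel.design.prompts_per_day)
            & (prompt[b] == 1)
        )
        ok = same_subject & (same_day_next | overnight)
    else:
        raise ValueError(f"unknown lag rule {rule!r}")
    return np.column_stack([a[ok], b[ok]])


def pair_lagged(
    panel: EMAPanel,
    item_y: str,
    item_x: str,
    rule: str = "same_day_consecutive",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lag-1 pairs: predictor x at prompt t, outcome y at prompt t+1.

    Returns ``(y_next, x_now, subject_ids)`` restricted to pairs where both
    items are observed.  Raises when no valid pair exists.
    """
    pairs = lagged_row_pairs(panel, rule)
    df = panel.data
    x_now = df[item_x].to_numpy(dtype=float)[pairs[:, 0]] if len(pairs) else np.empty(0)
    y_next = df[item_y].to_numpy(dtype=float)[pairs[:, 1]] if len(pairs) else np.empty(0)
    sid = df["subject_id"].to_numpy()[pairs[:, 0]] if len(pairs) else np.empty(0, dtype=object)
    keep = ~(np.isnan(x_now) | np.isnan(y_next))
    if not keep.any():
        raise ValueError(
            f"no valid lag-1 pairs for ({item_x!r} -> {item_y!r}) under rule {rule!r}"
        )
    return y_next[keep], x_now[keep], sid[keep]


# ---------------------------------------------------------------------------
# FDR and network assembly
# ---------------------------------------------------------------------------

def bh_fdr_mask(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up retention mask (True = retained)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def _item_values(panel: EMAPanel, usable: Sequence[str]) -> dict[str, np.ndarray]:
    """Pooled z-scored item columns (NaN preserved)."""
    out = {}
    for item in usable:
        v = panel.data[item].to_numpy(dtype=float)
        m = ~np.isnan(v)
        mu, sd = v[m].mean(), v[m].std()
        z = np.full_like(v, np.nan)
        z[m] = (v[m] - mu) / sd
        out[item] = z
    return out


def _usable_items(panel: EMAPanel, items: Sequence[str]) -> list[str]:
    usable = []
    for item in items:
        v = panel.data[item].to_numpy(dtype=float)
        v = v[~np.isnan(v)]
        if len(np.unique(v)) < 3:
            warnings.warn(
                f"item {item!r} has fewer than 3 distinct values; dropped from "
                "network estimation"
            )
        else:
            usable.append(item)
    return usable


def _fit_families(
    panel: EMAPanel,
    config: AnalysisConfig,
    moderator: Optional[pd.Series] = None,
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit all ordered-pair edges; returns items and the four coefficient/p grids."""
    items = _usable_items(panel, panel.item_names)
    k = len(items)
    if k < 2:
        raise ValueError("need at least 2 usable items")
    vals = _item_values(panel, items)
    sid_all = panel.data["subject_id"].to_numpy()
    pairs_idx = lagged_row_pairs(panel, config.lag_rule)

    s_obs = None
    if moderator is not None:
        mod = moderator.astype(float)
        mu, sd = mod.mean(), mod.std(ddof=0)
        if sd == 0:
            raise ValueError("moderator score is constant across subjects")
        mod = (mod - mu) / sd
        s_obs = pd.Series(sid_all).map(mod).to_numpy(dtype=float)

    def _one_fit(y, x, sid, s):
        keep = ~(np.isnan(y) | np.isnan(x))
        if s is not None:
            keep &= ~np.isnan(s)
        y, x, sid = y[keep], x[keep], sid[keep]
        if len(y) < 4 or np.ptp(x) == 0 or np.ptp(y) == 0:
            return 0.0, 1.0
        if s is None:
            X = np.column_stack([np.ones_like(x), x])
            col = 1
        else:
            sv = s[keep]
            X = np.column_stack([np.ones_like(x), x, sv, x * sv])
            col = 3
        try:
            fit = fit_random_intercept(y, X, sid)
        except np.linalg.LinAlgError:
            return 0.0, 1.0
        return float(fit.beta[col]), float(fit.p[col])

    # cross-sectional family: ordered pairs, i != j
    cross_b = np.zeros((k, k))
    cross_p = np.ones((k, k))
    for i, yi in enumerate(items):        # outcome
        for j, xj in enumerate(items):    # predictor
            if i == j:
                continue
            b, p = _one_fit(vals[yi], vals[xj], sid_all, s_obs)
            cross_b[i, j], cross_p[i, j] = b, p

    # lagged family: ordered pairs including self-loops; weights[predictor, outcome]
    lag_b = np.zeros((k, k))
    lag_p = np.ones((k, k))
    if len(pairs_idx):
        t0, t1 = pairs_idx[:, 0], pairs_idx[:, 1]
        sid_lag = sid_all[t0]
        for j, xj in enumerate(items):    # predictor at t
            x_now = vals[xj][t0]
            if s_obs is not None:
                s_lag = s_obs[t0]
            else:
                s_lag = None
            for i, yi in enumerate(items):  # outcome at t+1
                b, p = _one_fit(vals[yi][t1], x_now, sid_lag, s_lag)
                lag_b[j, i], lag_p[j, i] = b, p
    return items, cross_b, cross_p, lag_b, lag_p


def build_networks(
    panel: EMAPanel,
    config: Optional[AnalysisConfig] = None,
) -> dict[str, NetworkMatrix]:
    """Estimate cross-sectional, lagged and multilayer network matrices.

    All items are z-scored over pooled observations before fitting so slopes
    share a scale.  BH-FDR is applied separately to the cross-sectional
    family (all ordered pairs, i != j) and the lagged family (all ordered
    pairs including self-loops).  The cross-sectional matrix is symmetrized
    by averaging the two retained directional slopes (a pruned direction
    counts as 0).
    """
    config = config or AnalysisConfig()
    items, cross_b, cross_p, lag_b, lag_p = _fit_families(panel, config)
    k = len(items)

    off = ~np.eye(k, dtype=bool)
    cross_mask = np.zeros((k, k), dtype=bool)
    cross_mask[off] = bh_fdr_mask(cross_p[off], config.fdr_q)
    cross_dir = np.where(cross_mask, cross_b, 0.0)
    sym = 0.5 * (cross_dir + cross_dir.T)
    cross = NetworkMatrix(
        kind="cross_sectional",
        weights=sym,
        labels=tuple(items),
        mask=sym != 0.0,
        p_values=cross_p,
    )

    lag_mask = bh_fdr_mask(lag_p.ravel(), config.fdr_q).reshape(k, k)
    lagged = NetworkMatrix(
        kind="lagged",
        weights=np.where(lag_mask, lag_b, 0.0),
        labels=tuple(items),
        mask=lag_mask,
        p_values=lag_p,
    )

    multilayer = assemble_multilayer(cross, lagged)
    return {"cross_sectional": cross, "lagged": lagged, "multilayer": multilayer}


def assemble_multilayer(cross: NetworkMatrix, lagged: NetworkMatrix) -> NetworkMatrix:
    """Stack TL1/TL2 cross-sectional blocks with the TL1->TL2 lagged block.

    The TL2->TL1 block is structurally zero: time only moves forward.
    """
    if cross.labels != lagged.labels:
        raise ValueError("cross-sectional and lagged matrices index different items")
    k = cross.n_nodes
    W = np.zeros((2 * k, 2 * k))
    M = np.zeros((2 * k, 2 * k), dtype=bool)
    W[:k, :k] = cross.weights
    W[k:, k:] = cross.weights
    W[:k, k:] = lagged.weights
    M[:k, :k] = cross.mask
    M[k:, k:] = cross.mask
    M[:k, k:] = lagged.mask
    labels = tuple(f"{it}@TL1" for it in cross.labels) + tuple(
        f"{it}@TL2" for it in cross.labels
    )
    return NetworkMatrix(kind="multilayer", weights=W, labels=labels, mask=M)


def build_moderated_networks(
    panel: EMAPanel,
    scores: pd.Series,
    config: Optional[AnalysisConfig] = None,
    dimension: int = 1,
    node_effects: Optional[pd.Series] = None,
) -> ModerationMatrix:
    """Moderation (beta3) matrices for one clinical dimension score.

    Unlike the plain cross-sectional network, moderation effects stay
    directional: the matrix holds beta3 per ordered (outcome, predictor)
    pair, zeroed where the BH-FDR mask rejects.
    """
    config = config or AnalysisConfig()
    items, cross_b, cross_p, lag_b, lag_p = _fit_families(
        panel, config, moderator=scores
    )
    k = len(items)
    off = ~np.eye(k, dtype=bool)
    cross_mask = np.zeros((k, k), dtype=bool)
    cross_mask[off] = bh_fdr_mask(cross_p[off], config.fdr_q)
    cross = NetworkMatrix(
        kind="cross_sectional",
        weights=np.where(cross_mask, cross_b, 0.0),
        labels=tuple(items),
        mask=cross_mask,
        p_values=cross_p,
    )
    lag_mask = bh_fdr_mask(lag_p.ravel(), config.fdr_q).reshape(k, k)
    lagged = NetworkMatrix(
        kind="lagged",
        weights=np.where(lag_mask, lag_b, 0.0),
        labels=tuple(items),
        mask=lag_mask,
        p_values=lag_p,
    )
    return ModerationMatrix(
        dimension=dimension,
        cross_effects=cross,
        lagged_effects=lagged,
        node_effects=node_effects,
    )
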