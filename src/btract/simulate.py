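"""Synthetic experience-sampling cohorts with known generative truth.

The generator mirrors the model class the estimation stage assumes: latent
item states follow a first-order vector autoregression with per-subject
random intercepts and Gaussian innovations, discretized onto the 1-7 Likert
scale by fixed thresholds.  Each scheduled prompt is completed independently
with a fixed compliance probability, emulating the ~52% completion rate
(about 25 of 48 prompts) of a typical adolescent EMA protocol.  The latent
state re-initializes toward the subject mean each morning, so the default
same-day lag pairing downstream matches the generative process.

Nothing here claims real EMA data are linear-Gaussian; the generator exists
so every downstream stage can be tested against known couplings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .items import BINARY_ITEM, EMA_ITEMS, SIPS_ITEMS, SIPS_NEGATIVE, SIPS_POSITIVE
from .panel import CohortMetadata, EMAPanel, SIPSTable, StudyDesign

__all__ = [
    "GenerativeSpec",
    "SyntheticCohort",
    "generate_cohort",
    "latent_to_likert",
    "generate_sips_from_traits",
    "default_loading_matrix",
]

#: Default Likert thresholds: unit-width bins centered on 0.
DEFAULT_CUTS = (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5)


@dataclass
class GenerativeSpec:
    """Ground-truth parameters of a synthetic cohort.

    ``cross_coupling[i, j]`` mixes item j's innovation into item i at the
    same prompt; ``lag_coupling[i, j]`` carries item i at prompt t into item
    j at prompt t+1.  ``group_coupling_delta`` is added to the lag coupling
    of group-B subjects.  ``compliance`` is the per-prompt completion
    probability; the 0.52 default emulates ~25 completed of 48 scheduled
    prompts.
    """

    n_subjects: int = 68
    item_names: Sequence[str] = EMA_ITEMS
    days: int = 6
    prompts_per_day: int = 8
    cross_coupling: Optional[np.ndarray] = None
    lag_coupling: Optional[np.ndarray] = None
    intercept_sd: float = 0.8
    noise_sd: float = 1.0
    compliance: float = 0.52
    group_labels: Optional[Mapping[object, str]] = None
    group_coupling_delta: Optional[np.ndarray] = None
    likert_cuts: Sequence[float] = DEFAULT_CUTS
    p_alone: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        self.item_names = tuple(self.item_names)
        k = self.n_latent
        if self.cross_coupling is None:
            self.cross_coupling = np.zeros((k, k))
        if self.lag_coupling is None:
            self.lag_coupling = np.zeros((k, k))
        self.cross_coupling = np.asarray(self.cross_coupling, dtype=float)
        self.lag_coupling = np.asarray(self.lag_coupling, dtype=float)
        if self.cross_coupling.shape != (k, k) or self.lag_coupling.shape != (k, k):
            raise ValueError(f"coupling matrices must be {k}x{k}")
        if not (0.0 < self.compliance <= 1.0):
            raise ValueError("compliance must lie in (0, 1]")
        cuts = np.asarray(self.likert_cuts, dtype=float)
        if cuts.shape != (6,) or np.any(np.diff(cuts) <= 0):
            raise ValueError("likert_cuts must be 6 strictly increasing thresholds")
        for B in self._group_lag_matrices().values():
            rho = np.max(np.abs(np.linalg.eigvals(B)))
            if rho >= 1.0:
                raise ValueError(
                    f"lag coupling spectral radius {rho:.3f} >= 1; dynamics "
                    "would be non-stationary"
                )

    @property
    def likert_items(self) -> tuple[str, ...]:
        return tuple(i for i in self.item_names if i != BINARY_ITEM)

    @property
    def n_latent(self) -> int:
        return len(self.likert_items)

    @property
    def subject_ids(self) -> list[str]:
        return [f"S{i+1:03d}" for i in range(self.n_subjects)]

    def _group_lag_matrices(self) -> dict[str, np.ndarray]:
        if self.group_coupling_delta is None:
            return {"A": self.lag_coupling, "B": self.lag_coupling}
        delta = np.asarray(self.group_coupling_delta, dtype=float)
        return {"A": self.lag_coupling, "B": self.lag_coupling + delta}

    def label_of(self, subject_id: str) -> str:
        if self.group_labels is None:
            return "A"
        return self.group_labels.get(subject_id, "A")


@dataclass
class SyntheticCohort:
    """A generated panel + clinical table + metadata, with the truth retained."""

    panel: EMAPanel
    sips: SIPSTable
    meta: CohortMetadata
    truth: GenerativeSpec

    def group_assignment(self) -> pd.Series:
        sids = self.panel.subjects
        return pd.Series({s: self.truth.label_of(s) for s in sids}, name="group")


def latent_to_likert(latent: np.ndarray, cuts: Sequence[float] = DEFAULT_CUTS) -> np.ndarray:
    """Discretize latent values: score = 1 + number of thresholds strictly below."""
    cuts = np.asarray(cuts, dtype=float)
    if np.any(np.diff(cuts) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    return 1 + np.sum(np.asarray(latent, dtype=float)[..., None] > cuts, axis=-1)


def generate_cohort(spec: GenerativeSpec) -> SyntheticCohort:
    """Simulate a full cohort; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    k = spec.n_latent
    mix = np.eye(k) + spec.cross_coupling  # innovation mixing matrix
    lag_by_group = spec._group_lag_matrices()
    design = StudyDesign(prompts_per_day=spec.prompts_per_day, days=spec.days)

    rows = []
    has_alone = BINARY_ITEM in spec.item_names
    intercepts = {
        sid: rng.normal(scale=spec.intercept_sd, size=k) for sid in spec.subject_ids
    }
    for sid in spec.subject_ids:
        B = lag_by_group[spec.label_of(sid)]
        a_j = intercepts[sid]
        for day in range(1, spec.days + 1):
            z = None
            for prompt in range(1, spec.prompts_per_day + 1):
                eps = mix @ rng.normal(scale=spec.noise_sd, size=k)
                if z is None:  # morning re-initialization toward the subject mean
                    z = a_j + eps
                else:
                    z = a_j + B.T @ (z - a_j) + eps
                completed = rng.random() < spec.compliance
                alone = int(rng.random() < spec.p_alone) if has_alone else None
                if not completed:
                    continue
                scores = latent_to_likert(z, spec.likert_cuts)
                row = {"subject_id": sid, "day": day, "prompt": prompt}
                row.update(dict(zip(spec.likert_items, scores.astype(float))))
                if has_alone:
                    row[BINARY_ITEM] = float(alone)
                rows.append(row)

    cols = ["subject_id", "day", "prompt"] + list(spec.item_names)
    df = pd.DataFrame(rows, columns=cols)
    panel = EMAPanel(df, spec.item_names, design)

    # SIPS: the severity trait is the subject's standardized mean intercept
    # level, so higher-severity subjects also run hotter moment-to-moment;
    # the valence trait is an independent contrast.
    level = np.array([intercepts[s].mean() for s in spec.subject_ids])
    sd = level.std()
    severity = (level - level.mean()) / sd if sd > 0 else np.zeros_like(level)
    valence = rng.normal(size=spec.n_subjects)
    traits = np.column_stack([severity, valence])
    sips = generate_sips_from_traits(
        dict(zip(spec.subject_ids, traits)),
        default_loading_matrix(),
        noise_sd=0.5,
        seed=int(rng.integers(2**31)),
    )

    meta = _generate_metadata(spec, panel, rng)
    return SyntheticCohort(panel=panel, sips=sips, meta=meta, truth=spec)


def default_loading_matrix(item_names: Sequence[str] = None) -> np.ndarray:
    """18x2 default loadings: a severity column and a positive-vs-negative contrast.

    Column 1 is all-positive (overall severity); column 2 loads positive
    symptoms negatively and negative symptoms positively.
    """
    items = list(item_names) if item_names is not None else [
        i for i in SIPS_ITEMS if i != "P3"
    ]
    L = np.zeros((len(items), 2))
    L[:, 0] = 0.7
    for r, it in enumerate(items):
        if it in SIPS_POSITIVE:
            L[r, 1] = -0.5
        elif it in SIPS_NEGATIVE:
            L[r, 1] = 0.5
    return L


def generate_sips_from_traits(
    trait_scores: Mapping[object, np.ndarray],
    loading_matrix: np.ndarray,
    noise_sd: float,
    seed: int,
    baseline: float = 1.5,
    item_names: Optional[Sequence[str]] = None,
) -> SIPSTable:
    """Clinical item scores: round-and-clip of baseline + loadings @ traits + noise."""
    L = np.asarray(loading_matrix, dtype=float)
    if L.ndim != 2 or L.shape[1] != 2:
        raise ValueError(f"loading matrix must be (n_items, 2), got {L.shape}")
    if item_names is None:
        item_names = [i for i in SIPS_ITEMS if i != "P3"][: L.shape[0]]
    if len(item_names) != L.shape[0]:
        raise ValueError("item_names length does not match loading matrix")
    rng = np.random.default_rng(seed)
    subjects = list(trait_scores)
    rowsm = []
    for sid in subjects:
        t = np.asarray(trait_scores[sid], dtype=float)
        if t.shape != (2,):
            raise ValueError("each trait score must be a 2-vector")
        raw = baseline + L @ t + rng.normal(scale=noise_sd, size=L.shape[0])
        rowsm.append(np.clip(np.round(raw), 0, 6))
    df = pd.DataFrame(rowsm, index=pd.Index(subjects, name="subject_id"),
                      columns=list(item_names))
    return SIPSTable(df)


def _generate_metadata(
    spec: GenerativeSpec, panel: EMAPanel, rng: np.random.Generator
) -> CohortMetadata:
    n = spec.n_subjects
    counts = panel.data.groupby("subject_id").size()
    df = pd.DataFrame(
        {
            "age": np.round(np.clip(rng.normal(19.3, 5.2, n), 12, 35), 1),
            "sex": rng.choice(["M", "F"], size=n),
            "fsiq": np.round(np.clip(rng.normal(73, 13, n), 40, 120)),
            "n_assessments": [int(counts.get(s, 0)) for s in spec.subject_ids],
            "psychotic_disorder": (rng.random(n) < 0.09).astype(int),
            "adhd": (rng.random(n) < 0.60).astype(int),
            "anxiety_disorder": (rng.random(n) < 0.46).astype(int),
            "depressive_disorder": (rng.random(n) < 0.13).astype(int),
        },
        index=pd.Index(spec.subject_ids, name="subject_id"),
    )
    return CohortMetadata(df)
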