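"""Analysis configuration shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import yaml

LAG_RULES = ("same_day_consecutive", "any_consecutive")
LENGTH_TRANSFORMS = ("inverse_abs",)
DIAGONAL_MODES = ("mean_offdiag", "zero")


@dataclass
class AnalysisConfig:
    """Knobs of the full analysis pipeline.

    Parameters
    ----------
    fdr_q : float
        Benjamini-Hochberg level used to prune non-significant edges.
    variance_retention_threshold : float
        A PCA component is retained when it explains strictly more than this
        fraction of total variance.
    min_nonzero_fraction : float
        SIPS items endorsed (non-zero) in at most this fraction of subjects
        are dropped before PCA.
    n_bundles : int or "auto"
        Number of k-means path bundles; "auto" picks k in [4, 12] by mean
        silhouette.
    n_permutations : int
        Size of the subject-permutation null for the bundle divergence test.
    rng_seed : int
        Seed for every stochastic step (k-means restarts, permutations).
    lag_rule : str
        How consecutive prompts are paired for lagged models; the default
        never pairs across midnight and a missed prompt breaks the pair.
    length_transform : str
        Map from edge weight to graph length; ``inverse_abs`` is 1/|w|.
    k_subgroups : int
        Number of k-means subgroups per clinical dimension.
    pca_standardize : bool
        If True, run clinical PCA on the correlation matrix instead of the
        covariance (default, mean-centered unscaled) matrix.
    embedding_diagonal : str
        Diagonal convention for the adjacency fed to the network embedding.
    """

    fdr_q: float = 0.05
    variance_retention_threshold: float = 0.10
    min_nonzero_fraction: float = 0.10
    n_bundles: Union[int, str] = "auto"
    n_permutations: int = 500
    rng_seed: int = 0
    lag_rule: str = "same_day_consecutive"
    length_transform: str = "inverse_abs"
    k_subgroups: int = 2
    pca_standardize: bool = False
    embedding_diagonal: str = "mean_offdiag"

    def __post_init__(self) -> None:
        for name in ("fdr_q", "variance_retention_threshold", "min_nonzero_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v!r}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.lag_rule not in LAG_RULES:
            raise ValueError(f"lag_rule must be one of {LAG_RULES}")
        if self.length_transform not in LENGTH_TRANSFORMS:
            raise ValueError(f"length_transform must be one of {LENGTH_TRANSFORMS}")
        if self.embedding_diagonal not in DIAGONAL_MODES:
            raise ValueError(f"embedding_diagonal must be one of {DIAGONAL_MODES}")
        if self.n_bundles != "auto" and int(self.n_bundles) < 1:
            raise ValueError("n_bundles must be a positive integer or 'auto'")
        if self.k_subgroups < 2:
            raise ValueError("k_subgroups must be >= 2")


def load_config(path: Union[str, Path]) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return AnalysisConfig(**raw)


def save_config(config: AnalysisConfig, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
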