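"""Core data containers: EMA panel, SIPS table, cohort metadata.

All three are thin, validated wrappers around pandas DataFrames; downstream
modules operate on the underlying frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .items import BINARY_ITEM, EMA_ITEMS, SIPS_ITEMS

#: Non-item columns of an EMA panel frame, in order.
INDEX_COLS = ["subject_id", "day", "prompt"]


class ValidationError(ValueError):
    """Raised when an input table violates a data-model invariant."""


class SchemaError(ValueError):
    """Raised when an input table has unknown or missing columns."""


@dataclass(frozen=True)
class StudyDesign:
    """Prompting schedule: ``prompts_per_day`` prompts on each of ``days`` days."""

    prompts_per_day: int = 8
    days: int = 6

    @property
    def max_prompts(self) -> int:
        return self.prompts_per_day * self.days


@dataclass
class EMAPanel:
    """Long-format per-prompt observations for all subjects.

    ``data`` holds one row per *completed* prompt with columns
    ``subject_id, day, prompt`` followed by the item columns (float; NaN for
    an item skipped within an otherwise completed prompt) and, optionally, a
    ``timestamp`` column.
    """

    data: pd.DataFrame
    item_names: tuple[str, ...] = EMA_ITEMS
    design: StudyDesign = field(default_factory=StudyDesign)

    def __post_init__(self) -> None:
        self.item_names = tuple(self.item_names)
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def subjects(self) -> list:
        return list(dict.fromkeys(self.data["subject_id"]))

    @property
    def n_observations(self) -> int:
        return len(self.data)

    def items_matrix(self) -> pd.DataFrame:
        """Observation x item matrix (float, NaN = missing)."""
        return self.data[list(self.item_names)].astype(float)

    def subject_panel(self, subject_ids: Iterable) -> "EMAPanel":
        keep = set(subject_ids)
        sub = self.data[self.data["subject_id"].isin(keep)].reset_index(drop=True)
        return EMAPanel(sub, self.item_names, self.design)

    def subject_means(self) -> pd.DataFrame:
        """Per-subject mean intensity of each item (NaN-aware)."""
        return self.data.groupby("subject_id", sort=True)[list(self.item_names)].mean()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        missing = [c for c in INDEX_COLS if c not in df.columns]
        if missing:
            raise SchemaError(f"EMA panel lacks required columns {missing}")
        for col in self.item_names:
            if col not in df.columns:
                raise SchemaError(f"EMA panel lacks item column {col!r}")

        day = df["day"].to_numpy()
        prompt = df["prompt"].to_numpy()
        if len(df) and (day < 1).any():
            row = int(np.argmax(day < 1))
            raise ValidationError(f"row {row}: day {day[row]} < 1")
        bad = (prompt < 1) | (prompt > self.design.prompts_per_day)
        if len(df) and bad.any():
            row = int(np.argmax(bad))
            raise ValidationError(
                f"row {row}: prompt_index {prompt[row]} outside "
                f"[1, {self.design.prompts_per_day}]"
            )
        if df.duplicated(INDEX_COLS).any():
            dup = df[df.duplicated(INDEX_COLS)].iloc[0]
            raise ValidationError(
                "duplicate observation for subject "
                f"{dup['subject_id']!r} day {dup['day']} prompt {dup['prompt']}"
            )
        counts = df.groupby("subject_id").size()
        over = counts[counts > self.design.max_prompts]
        if len(over):
            raise ValidationError(
                f"subject {over.index[0]!r} has {int(over.iloc[0])} observations, "
                f"more than the schedule maximum {self.design.max_prompts}"
            )
        for col in self.item_names:
            vals = df[col].to_numpy(dtype=float)
            ok = np.isnan(vals)
            if col == BINARY_ITEM:
                ok |= (vals == 0) | (vals == 1)
                msg = "{0!r} value {1} not in {{0, 1}}"
            else:
                ok |= (vals == np.round(vals)) & (vals >= 1) & (vals <= 7)
                msg = "{0!r} value {1} outside the 1-7 Likert scale"
            if len(df) and not ok.all():
                row = int(np.argmax(~ok))
                raise ValidationError(f"row {row}: item " + msg.format(col, vals[row]))

    def sort(self) -> "EMAPanel":
        df = self.data.sort_values(INDEX_COLS, kind="mergesort").reset_index(drop=True)
        return EMAPanel(df, self.item_names, self.design)


@dataclass
class SIPSTable:
    """One row per subject of clinical interview item scores (integers 0-6)."""

    data: pd.DataFrame  # index = subject_id, columns = item names
    dropped_items: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.validate()

    @property
    def item_names(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def subjects(self) -> list:
        return list(self.data.index)

    def validate(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicated subject_id {dup!r} in SIPS table")
        vals = df.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals == np.round(vals)) & (vals >= 0) & (vals <= 6))
        if vals.size and not ok.all():
            i, j = np.unravel_index(int(np.argmax(~ok)), ok.shape)
            raise ValidationError(
                f"SIPS score {vals[i, j]} for subject {df.index[i]!r} item "
                f"{df.columns[j]!r} outside the 0-6 scale"
            )


@dataclass
class CohortMetadata:
    """Per-subject demographics and lifetime diagnosis flags.

    ``data`` is indexed by subject_id with columns ``age`` (years), ``sex``
    ("M"/"F"), ``fsiq`` (full-scale IQ) and ``n_assessments``; every other
    column is treated as a binary diagnosis flag.
    """

    data: pd.DataFrame

    CORE = ("age", "sex", "fsiq", "n_assessments")

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicated subject_id in metadata")

    @property
    def diagnosis_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.data.columns if c not in self.CORE)

    def covers(self, subject_ids: Iterable) -> bool:
        return set(subject_ids) <= set(self.data.index)
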