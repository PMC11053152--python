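"""Core in-memory containers for the pipeline.

The quantitative proteome is held as a proteins x samples matrix with an
explicit missing-value mask (NaN) and per-sample metadata (biological group,
TMT batch, technical-replicate links).  The clinical table carries the eleven
modelling covariates plus the right-censored recurrence outcome.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: biological groups: pediatric benign, pediatric malignant, adult malignant,
#: plus pooled reference channels
GROUPS = ("PB", "PM", "AM", "POOL")

#: the eleven clinical modelling covariates
CLINICAL_FEATURES = [
    "age",
    "gender",
    "max_nodule_size",
    "multifocality",
    "ETE",
    "TLNR",
    "LLNR",
    "TLNN",
    "LLNN",
    "surgery",
    "HT",
]

#: outcome columns: recurrence indicator and follow-up time in months
OUTCOME_COLUMNS = ["event", "time"]


class PipelineOrderError(RuntimeError):
    """Raised when a preprocessing stage is invoked out of order."""


@dataclass
class AbundanceMatrix:
    """Protein x sample abundance matrix with metadata.

    Parameters
    ----------
    values
        DataFrame indexed by protein id, columns are sample ids.  Missing
        values are NaN.
    meta
        DataFrame indexed by sample id with columns ``group`` (PB/PM/AM/POOL),
        ``batch`` (1..B) and ``replicate_of`` (sample id or NA).
    scale
        ``"log2"`` or ``"linear"``.
    history
        Names of preprocessing stages already applied, in order.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    scale: str = "log2"
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate protein ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        missing_meta = self.values.columns.difference(self.meta.index)
        if len(missing_meta):
            raise ValueError(f"samples without metadata: {list(missing_meta)[:5]}")
        for col in ("group", "batch"):
            if col not in self.meta.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        bad = set(self.meta["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown groups {bad}")
        if "replicate_of" in self.meta.columns:
            links = self.meta["replicate_of"].dropna()
            dangling = set(links) - set(self.meta.index)
            if dangling:
                raise ValueError(f"dangling replicate links: {dangling}")

    # ------------------------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in_group(self, group: str) -> list:
        return list(self.meta.index[self.meta["group"] == group].intersection(self.values.columns))

    def na_rate(self) -> pd.Series:
        """Per-protein fraction of missing entries."""
        return self.values.isna().mean(axis=1)

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.copy(),
            self.meta.copy(),
            self.scale,
            list(self.history),
        )

    # ------------------------------------------------------------------
    def to_linear(self) -> "AbundanceMatrix":
        """Export on the positive linear scale (2**x); identity if already linear."""
        if self.scale == "linear":
            return self.copy()
        out = self.copy()
        out.values = np.power(2.0, out.values)
        out.scale = "linear"
        return out

    def to_log2(self) -> "AbundanceMatrix":
        """Convert to log2; non-positive values must be replaced first."""
        if self.scale == "log2":
            return self.copy()
        vals = self.values.to_numpy(float)
        if np.nanmin(vals) <= 0:
            raise ValueError("non-positive values present; run replace_nonpositive first")
        out = self.copy()
        out.values = np.log2(out.values)
        out.scale = "log2"
        return out

    def require_history(self, *stages: str) -> None:
        """Enforce pipeline ordering: all ``stages`` must already be applied."""
        for stage in stages:
            if stage not in self.history:
                raise PipelineOrderError(
                    f"stage {stage!r} must run before this operation; "
                    f"history so far: {self.history}"
                )


def validate_clinical(table: pd.DataFrame) -> pd.DataFrame:
    """Check a clinical table for schema and invariant violations.

    Returns the table unchanged on success.
    """
    needed = CLINICAL_FEATURES + OUTCOME_COLUMNS
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"clinical table lacks columns: {missing}")
    if (table["time"] <= 0).any():
        raise ValueError("follow-up times must be positive")
    if not table["event"].isin([0, 1]).all():
        raise ValueError("event must be 0/1")
    for col in ("TLNN", "LLNN"):
        if (table[col] < 0).any():
            raise ValueError(f"{col} counts must be non-negative")
    for col in ("TLNR", "LLNR"):
        if ((table[col] < 0) | (table[col] > 1)).any():
            raise ValueError(f"{col} must lie in [0, 1]")
    return table


def deep_copy(obj):
    return _copy.deepcopy(obj)
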