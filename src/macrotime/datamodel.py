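"""Core data types for longitudinal macrophage expression analysis.

The package operates on three kinds of objects:

* :class:`ExpressionMatrix` — a genes × samples matrix of normalized,
  log2-scale expression values (RMA-style microarray output or any
  comparably normalized matrix).
* a *sample annotation* table — one row per sample with the clinical and
  design metadata of the cohort (patient, day of life, treatment,
  disease-severity outcome).  Annotations are plain :class:`pandas.DataFrame`
  objects validated by :func:`validate_annotation`.
* :class:`GeneSetCollection` — named gene sets (GMT-style) for
  over-representation analysis.

Per-gene results (step fits, differential-expression rows, enrichment rows)
are carried as dataclasses or tidy DataFrames produced by the analysis
modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TREATMENTS = ("control", "LPS")
BPD_GROUPS = ("none", "mild", "moderate", "severe")

#: Map from BPD outcome to the coarse two-group comparison used throughout:
#: patients with no or mild disease are "resilient", severe is kept apart,
#: moderate falls in "other" and is excluded from the two-group contrasts.
RESILIENCE_CLASS = {
    "none": "resilient",
    "mild": "resilient",
    "moderate": "other",
    "severe": "severe",
}

ANNOTATION_COLUMNS = (
    "sample_id",
    "patient_id",
    "day_of_life",
    "treatment",
    "bpd_group",
)


class DataModelError(ValueError):
    """Raised when an input violates a structural contract."""


class ExpressionMatrix:
    """A genes × samples matrix of log2-scale normalized expression.

    Parameters
    ----------
    data:
        DataFrame with gene identifiers as the index and sample identifiers
        as columns.  Values must be finite floats.
    scale:
        Recorded scale of the values; downstream fold-change semantics assume
        ``"log2"``.

    Raises
    ------
    DataModelError
        On duplicate gene or sample identifiers, or non-finite values.
    """

    def __init__(self, data: pd.DataFrame, scale: str = "log2"):
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise DataModelError(f"duplicate gene id: {dup!r}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()][0]
            raise DataModelError(f"duplicate sample id: {dup!r}")
        values = data.to_numpy(dtype=float, copy=False)
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise DataModelError(
                f"non-finite expression value for gene {data.index[i]!r}, "
                f"sample {data.columns[j]!r}"
            )
        self.data = data.astype(float)
        self.scale = scale

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise DataModelError(f"samples absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.scale)

    def __repr__(self) -> str:  # pragma: no cover
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples, scale={self.scale})"


def derive_week(day_of_life: int) -> int:
    """Chronological week of life for a day of life (day 1–7 → week 1)."""
    return math.ceil(day_of_life / 7)


def validate_annotation(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-annotation table and fill derived columns.

    Requires columns ``sample_id, patient_id, day_of_life, treatment,
    bpd_group``.  Fills ``chronological_week`` (``ceil(day/7)``) if absent and
    always (re)derives ``resilience_class`` from ``bpd_group``.

    Raises
    ------
    DataModelError
        On missing columns, duplicate sample ids, unknown treatment or
        outcome tokens, non-positive days, or a (patient, day) pair holding
        more than one sample of the same treatment.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise DataModelError(f"annotation missing required columns: {missing}")
    table = table.copy()
    if table["sample_id"].duplicated().any():
        dup = table.loc[table["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DataModelError(f"duplicate sample_id: {dup!r}")
    bad = set(table["treatment"]) - set(TREATMENTS)
    if bad:
        raise DataModelError(
            f"unknown treatment token(s) {sorted(bad)}; allowed: {list(TREATMENTS)}"
        )
    bad = set(table["bpd_group"]) - set(BPD_GROUPS)
    if bad:
        raise DataModelError(
            f"unknown bpd_group token(s) {sorted(bad)}; allowed: {list(BPD_GROUPS)}"
        )
    table["day_of_life"] = table["day_of_life"].astype(int)
    if (table["day_of_life"] < 1).any():
        raise DataModelError("day_of_life must be >= 1")
    dup_pairs = table.duplicated(subset=["patient_id", "day_of_life", "treatment"])
    if dup_pairs.any():
        row = table.loc[dup_pairs].iloc[0]
        raise DataModelError(
            "more than one sample for patient "
            f"{row['patient_id']!r} day {row['day_of_life']} "
            f"treatment {row['treatment']!r}"
        )
    if "chronological_week" not in table.columns or table["chronological_week"].isna().any():
        table["chronological_week"] = table["day_of_life"].map(derive_week)
    table["chronological_week"] = table["chronological_week"].astype(int)
    table["resilience_class"] = table["bpd_group"].map(RESILIENCE_CLASS)
    return table


def check_annotation_covers(matrix: ExpressionMatrix, annotation: pd.DataFrame) -> None:
    """Every matrix sample must appear exactly once in the annotation."""
    ann_ids = set(annotation["sample_id"])
    missing = [s for s in matrix.sample_ids if s not in ann_ids]
    if missing:
        raise DataModelError(
            f"{len(missing)} matrix sample(s) missing from annotation, "
            f"e.g. {missing[:5]}"
        )


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions; members deduplicated, order kept."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, name: str, description: str, members) -> None:
        if name in self.sets:
            raise DataModelError(f"duplicate gene-set name: {name!r}")
        deduped = tuple(dict.fromkeys(members))
        if not deduped:
            raise DataModelError(f"gene set {name!r} has no members")
        self.sets[name] = GeneSet(name, description, deduped)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())


@dataclass(frozen=True)
class StepFit:
    """One gene's fitted step function over a time-ordered series.

    ``step_index`` is the boundary b: the step lies between ordered positions
    b and b+1 (1-based, ``1 <= b <= n-1``).  ``left_mean``/``right_mean`` are
    the fitted segment averages; ``sse`` the residual sum of squares of the
    fitted step; ``m`` the degrees of freedom charged to the adaptive
    regression; ``f_stat`` and ``p_value`` come from the F(m-1, n-m) test of
    the fitted step against the grand mean.  ``direction`` is ``"up"`` or
    ``"down"`` only for significant fits with distinct segment means,
    otherwise ``"none"``.
    """

    gene_id: str | None
    n: int
    step_index: int
    left_mean: float
    right_mean: float
    grand_mean: float
    sse: float
    m: int
    f_stat: float
    p_value: float
    direction: str
    significant: bool


@dataclass(frozen=True)
class VennResult:
    """Two-set overlap accounting for cross-group signature comparison."""

    set_a_only: frozenset
    set_b_only: frozenset
    shared: frozenset

    @property
    def counts(self) -> dict[str, int]:
        return {
            "a_only": len(self.set_a_only),
            "b_only": len(self.set_b_only),
            "shared": len(self.shared),
        }
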