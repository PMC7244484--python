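"""Pseudotime profiles: per-week aggregation, LPS:control ratios, row order.

Samples are grouped by week of life and averaged per gene, separately for
control and LPS-treated aliquots.  The LPS:control "ratio" is computed as
the difference of log2 means — i.e. the log2 fold change of LPS over
control — because the expression values are log2-scale; a linear-ratio
output (2**difference) is available.  Heatmap row order comes from
agglomerative hierarchical clustering with Euclidean distance.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datamodel import DataModelError, ExpressionMatrix

log = logging.getLogger(__name__)

DEFAULT_MAX_WEEK = 10


def aggregate_by_week(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    treatment: str,
    max_week: int = DEFAULT_MAX_WEEK,
    week_column: str = "chronological_week",
    group: str | None = None,
) -> pd.DataFrame:
    """Per-gene mean log2 expression per week for one treatment arm.

    Weeks beyond ``max_week`` are dropped; weeks with no samples are omitted
    with a logged notice (cohort attrition).  ``week_column`` selects the
    grouping column (chronological week by default; any integer annotation
    column such as a gestational-age week works).  ``group`` optionally
    restricts to one resilience class.

    Returns a DataFrame indexed by gene id with sorted integer week columns.
    """
    if week_column not in annotation.columns:
        raise DataModelError(f"week column {week_column!r} not in annotation")
    rows = annotation.loc[annotation["treatment"] == treatment]
    if group is not None:
        rows = rows.loc[rows["resilience_class"] == group]
    rows = rows.loc[rows[week_column] <= max_week]
    if rows.empty:
        raise DataModelError(
            f"no samples for treatment={treatment!r} within max_week={max_week}"
        )
    weeks_present = sorted(rows[week_column].unique())
    absent = sorted(set(range(1, max_week + 1)) - set(weeks_present))
    if absent:
        log.info("weeks without %s samples omitted: %s", treatment, absent)
    columns = {}
    for week in weeks_present:
        ids = list(rows.loc[rows[week_column] == week, "sample_id"])
        columns[int(week)] = matrix.subset_samples(ids).values.mean(axis=1)
    out = pd.DataFrame(columns, index=pd.Index(matrix.gene_ids, name="gene_id"))
    return out[sorted(out.columns)]


def lps_ratio(
    control_profile: pd.DataFrame,
    lps_profile: pd.DataFrame,
    scale: str = "log2diff",
) -> pd.DataFrame:
    """LPS:control fold change per gene per week.

    ``scale="log2diff"`` (default) returns the difference of log2 means,
    i.e. the log2 fold change of LPS over control; ``scale="linear"``
    returns ``2**difference``.  Weeks present in only one profile are
    excluded with a logged notice; gene sets must match.
    """
    if set(control_profile.index) != set(lps_profile.index):
        raise DataModelError("control and LPS profiles cover different genes")
    shared = sorted(set(control_profile.columns) & set(lps_profile.columns))
    dropped = sorted(
        set(control_profile.columns) ^ set(lps_profile.columns)
    )
    if dropped:
        log.info("weeks present in only one treatment arm excluded: %s", dropped)
    if not shared:
        raise DataModelError("no weeks shared between control and LPS profiles")
    diff = lps_profile.loc[control_profile.index, shared] - control_profile[shared]
    if scale == "log2diff":
        return diff
    if scale == "linear":
        return 2.0**diff
    raise DataModelError(f"unknown ratio scale {scale!r}")


def hierarchical_order(
    values, metric: str = "euclidean", method: str = "complete"
) -> tuple[list, np.ndarray]:
    """Agglomerative-clustering row order for heatmap display.

    Returns ``(leaf_order, merges)`` where ``leaf_order`` lists row labels
    (gene ids for a DataFrame, integer indices for an array) in dendrogram
    leaf order, and ``merges`` is the SciPy linkage matrix (each row:
    cluster i, cluster j, merge distance, size).  Clustering is
    deterministic for a given input; equal-distance merges resolve to the
    lower cluster index.  A constant matrix (all pairwise distances zero)
    returns the input order with a warning.
    """
    if isinstance(values, pd.DataFrame):
        labels = list(values.index)
        array = values.to_numpy(dtype=float)
    else:
        array = np.asarray(values, dtype=float)
        labels = list(range(array.shape[0]))
    if array.ndim != 2 or array.shape[0] < 2:
        raise DataModelError("need a 2-D matrix with at least 2 rows")
    if not np.isfinite(array).all():
        raise DataModelError("non-finite values in clustering input")
    distances = pdist(array, metric=metric)
    if np.all(distances == 0.0):
        warnings.warn("all pairwise distances are zero; returning input order")
        n = array.shape[0]
        merges = np.column_stack(
            [np.arange(n - 1) + np.array([0] + list(range(n, 2 * n - 2))),
             np.arange(1, n), np.zeros(n - 1), np.arange(2, n + 1)]
        ).astype(float)
        return labels, merges
    linkage = hierarchy.linkage(distances, method=method)
    order = hierarchy.leaves_list(linkage)
    return [labels[i] for i in order], linkage
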