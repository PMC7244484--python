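"""Two-group differential expression: Welch t-test with BH FDR.

Contrasts are unpaired Welch tests (unequal variance, unequal sample size,
two-tailed) per gene on log2-scale values, with Benjamini–Hochberg FDR
computed across all genes in the matrix.  ``log2_fc`` is ``mean_b - mean_a``
(log2 fold change of group b over group a).

The LPS-versus-control contrasts are unpaired by default even though the
cohort pairs control and LPS aliquots per patient; a paired option exists
for sensitivity analyses (``paired=True`` requires matched patient/day
pairs and applies a paired t-test to the per-pair differences).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import DataModelError, ExpressionMatrix

log = logging.getLogger(__name__)

DEFAULT_FDR_THRESHOLD = 0.05

#: Built-in named contrasts (selector_a, selector_b) over annotation columns.
#: log2_fc is mean(selector_b) - mean(selector_a).
NAMED_CONTRASTS: dict[str, tuple[dict, dict]] = {
    "day1_bpd_vs_none": (
        {"day_of_life": 1, "treatment": "control", "bpd_group": ["none"]},
        {"day_of_life": 1, "treatment": "control",
         "bpd_group": ["mild", "moderate", "severe"]},
    ),
    "day7_severe_vs_nonemild": (
        {"day_of_life": 7, "treatment": "control", "resilience_class": ["resilient"]},
        {"day_of_life": 7, "treatment": "control", "resilience_class": ["severe"]},
    ),
    "lps_vs_control_day1": (
        {"day_of_life": 1, "treatment": "control"},
        {"day_of_life": 1, "treatment": "LPS"},
    ),
    "lps_vs_control_day7": (
        {"day_of_life": 7, "treatment": "control"},
        {"day_of_life": 7, "treatment": "LPS"},
    ),
}


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch's unpaired two-sample t-test (two-tailed).

    Returns ``(t_stat, df, p_value)`` with t = (mean_b - mean_a) /
    sqrt(s_a^2/n_a + s_b^2/n_b), Welch–Satterthwaite df, and a two-tailed
    p from Student's t.

    Degenerate inputs: if both groups have zero variance and equal means the
    test is undefined and ``(0, n_a+n_b-2, 1)`` is returned with a warning;
    zero variance with distinct means returns an infinite t and p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataModelError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise DataModelError("non-finite values in test input")
    t, df, p = _welch_arrays(a[None, :], b[None, :])
    return float(t[0]), float(df[0]), float(p[0])


def _welch_arrays(A: np.ndarray, B: np.ndarray):
    """Row-wise Welch test; A, B are genes × samples blocks."""
    na, nb = A.shape[1], B.shape[1]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    va, vb = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mb - ma) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    degenerate = se2 == 0.0
    tie = degenerate & (ma == mb)
    shift = degenerate & (ma != mb)
    if tie.any():
        warnings.warn(
            f"{int(tie.sum())} gene(s) with zero variance and equal means; "
            "t set to 0, p to 1",
            stacklevel=3,
        )
    with np.errstate(invalid="ignore"):
        t = np.where(tie, 0.0, t)
        t = np.where(shift, np.sign(mb - ma) * np.inf, t)
        df = np.where(degenerate, na + nb - 2, df)
        p = np.where(
            np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(np.where(np.isinf(t), 0, t)), df)
        )
        p = np.where(tie, 1.0, p)
    return t, df, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_i = min over j >= i (rank order) of p_(j) * N / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise DataModelError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _select(annotation: pd.DataFrame, selector) -> pd.DataFrame:
    if callable(selector):
        mask = selector(annotation)
    elif isinstance(selector, dict):
        mask = pd.Series(True, index=annotation.index)
        for column, wanted in selector.items():
            if column not in annotation.columns:
                raise DataModelError(f"selector column {column!r} not in annotation")
            if isinstance(wanted, (list, tuple, set)):
                mask &= annotation[column].isin(list(wanted))
            else:
                mask &= annotation[column] == wanted
    else:
        raise DataModelError(f"selector must be dict or callable, got {type(selector)}")
    return annotation.loc[mask]


def differential_expression(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    contrast,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene Welch differential expression for a two-group contrast.

    ``contrast`` is either a name from :data:`NAMED_CONTRASTS` or a pair
    ``(selector_a, selector_b)`` of dicts/callables over annotation columns.
    FDR is computed across all genes in the matrix (no pre-filtering).

    Returns a table (``gene_id, mean_a, mean_b, log2_fc, t_stat, df,
    p_value, fdr, n_a, n_b, significant``) sorted by ascending p-value.
    """
    if isinstance(contrast, str):
        try:
            selector_a, selector_b = NAMED_CONTRASTS[contrast]
        except KeyError:
            raise DataModelError(
                f"unknown contrast {contrast!r}; known: {sorted(NAMED_CONTRASTS)}"
            ) from None
        name = contrast
    else:
        selector_a, selector_b = contrast
        name = "custom"
    rows_a = _select(annotation, selector_a)
    rows_b = _select(annotation, selector_b)
    for label, rows in (("a", rows_a), ("b", rows_b)):
        if len(rows) < 2:
            raise DataModelError(
                f"contrast {name!r}: selector {label} matches {len(rows)} "
                "sample(s); need >= 2"
            )
    A = matrix.subset_samples(list(rows_a["sample_id"])).values
    B = matrix.subset_samples(list(rows_b["sample_id"])).values
    t, df, p = _welch_arrays(A, B)
    fdr = bh_adjust(p)
    table = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "mean_a": A.mean(axis=1),
            "mean_b": B.mean(axis=1),
            "log2_fc": B.mean(axis=1) - A.mean(axis=1),
            "t_stat": t,
            "df": df,
            "p_value": p,
            "fdr": fdr,
            "n_a": A.shape[1],
            "n_b": B.shape[1],
            "significant": fdr <= fdr_threshold,
        }
    )
    log.info(
        "contrast %s: n_a=%d n_b=%d, %d/%d genes at FDR<=%g",
        name, A.shape[1], B.shape[1], int(table["significant"].sum()),
        len(table), fdr_threshold,
    )
    return table.sort_values(["p_value", "gene_id"], kind="mergesort").reset_index(
        drop=True
    )


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot-ready table: log2 fold change vs -log10 p.

    p = 0 (degenerate zero-variance shifts) maps to one more than the
    largest finite -log10 p in the table and is flagged in ``p_clamped``.
    """
    if results.empty:
        raise DataModelError("empty results table")
    p = results["p_value"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        nlp = -np.log10(p)
    finite = np.isfinite(nlp)
    if not finite.all():
        ceiling = (nlp[finite].max() if finite.any() else 0.0) + 1.0
        nlp = np.where(finite, nlp, ceiling)
    return pd.DataFrame(
        {
            "gene_id": results["gene_id"],
            "log2_fc": results["log2_fc"],
            "neg_log10_p": nlp,
            "significant": results["significant"],
            "p_clamped": ~finite,
        }
    )
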