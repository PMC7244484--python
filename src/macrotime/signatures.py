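"""Cross-group time-dependent gene sets, resilience signature, and ORA.

Genes with "time-dependent expression" in a group are those whose step fit
on that group's control time course is significant at the step-detection
p-value threshold (0.01 by default), optionally restricted to one
direction.  Comparing the sets from the two outcome groups gives a Venn
partition; the resilience signature is the set of genes stepping up in
resilient (none/mild) patients while showing no significant step in severe
patients.  Over-representation of a query set in annotated gene sets is
tested with the hypergeometric upper tail against a measured-gene universe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DataModelError, ExpressionMatrix, GeneSetCollection, VennResult
from .diffexpr import bh_adjust
from .stepminer import order_samples


def _significant_set(step_table: pd.DataFrame, direction_filter: str | None):
    mask = step_table["significant"].astype(bool)
    if direction_filter is not None:
        if direction_filter not in ("up", "down"):
            raise DataModelError(
                f"direction_filter must be 'up', 'down' or None, got {direction_filter!r}"
            )
        mask &= step_table["direction"] == direction_filter
    return frozenset(step_table.loc[mask, "gene_id"])


def time_dependent_sets(
    step_table_a: pd.DataFrame,
    step_table_b: pd.DataFrame,
    direction_filter: str | None = None,
) -> tuple[frozenset, frozenset, VennResult]:
    """Significant step-gene sets of two groups and their Venn partition.

    Both step tables must cover the same gene universe.  The optional
    ``direction_filter`` restricts both sets to up- or down-steps.
    """
    universe_a = set(step_table_a["gene_id"])
    universe_b = set(step_table_b["gene_id"])
    if universe_a != universe_b:
        n_diff = len(universe_a ^ universe_b)
        raise DataModelError(
            f"step tables cover different gene universes ({n_diff} genes differ)"
        )
    set_a = _significant_set(step_table_a, direction_filter)
    set_b = _significant_set(step_table_b, direction_filter)
    venn = VennResult(
        set_a_only=set_a - set_b,
        set_b_only=set_b - set_a,
        shared=frozenset(set_a & set_b),
    )
    return set_a, set_b, venn


def resilience_signature(
    step_resilient: pd.DataFrame,
    step_severe: pd.DataFrame,
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Genes stepping up over time only in resilient (none/mild) patients.

    A gene qualifies if its step fit in the resilient group is significant
    with direction up AND its fit in the severe group is not significant.
    Each gene is annotated with its day-1 mean and day-7-and-later mean over
    the resilient group's control samples (the magnitude of the early rise).

    Returns a table (``gene_id, resilient_step_day, resilient_direction,
    resilient_p, severe_p, day1_mean, day7plus_mean``) sorted by the
    resilient-group p-value; an empty candidate set yields an empty table.
    """
    up_resilient = _significant_set(step_resilient, "up")
    sig_severe = _significant_set(step_severe, None)
    candidates = sorted(up_resilient - sig_severe)
    columns = [
        "gene_id", "resilient_step_day", "resilient_direction",
        "resilient_p", "severe_p", "day1_mean", "day7plus_mean",
    ]
    if not candidates:
        return pd.DataFrame(columns=columns)
    res = step_resilient.set_index("gene_id")
    sev = step_severe.set_index("gene_id")
    ordered = order_samples(annotation, "resilient", "control")
    day1_ids = list(ordered.loc[ordered["day_of_life"] == 1, "sample_id"])
    later_ids = list(ordered.loc[ordered["day_of_life"] >= 7, "sample_id"])
    sub = matrix.subset_samples(day1_ids + later_ids)
    day1 = sub.data[day1_ids].mean(axis=1)
    later = sub.data[later_ids].mean(axis=1)
    table = pd.DataFrame(
        {
            "gene_id": candidates,
            "resilient_step_day": res.loc[candidates, "step_day"].to_numpy(),
            "resilient_direction": res.loc[candidates, "direction"].to_numpy(),
            "resilient_p": res.loc[candidates, "p_value"].to_numpy(),
            "severe_p": sev.loc[candidates, "p_value"].to_numpy(),
            "day1_mean": day1.loc[candidates].to_numpy(),
            "day7plus_mean": later.loc[candidates].to_numpy(),
        }
    )
    return table.sort_values(["resilient_p", "gene_id"], kind="mergesort").reset_index(
        drop=True
    )


def ora_hypergeometric(
    query, collection: GeneSetCollection, universe
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set in gene sets.

    For each set, with N = universe size, K = set members within the
    universe, n = query size, k = overlap, the p-value is the hypergeometric
    upper tail P(X >= k).  Gene matching is exact, case-sensitive.  Returns
    a table (``set_name, k, K, n, N, p_value, neg_log10_p, fdr``) sorted by
    decreasing -log10 p, with BH FDR across the tested sets.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise DataModelError("empty universe")
    if not query:
        raise DataModelError("empty query set")
    stray = query - universe
    if stray:
        raise DataModelError(
            f"{len(stray)} query gene(s) not in universe, e.g. {sorted(stray)[:5]}"
        )
    N, n = len(universe), len(query)
    rows = []
    for gene_set in collection:
        members = set(gene_set.members) & universe
        K = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        rows.append((gene_set.name, k, K, n, N, p))
    table = pd.DataFrame(
        rows, columns=["set_name", "k", "K", "n", "N", "p_value"]
    )
    with np.errstate(divide="ignore"):
        table["neg_log10_p"] = -np.log10(table["p_value"])
    table["fdr"] = bh_adjust(table["p_value"]) if len(table) else []
    return table.sort_values(
        ["neg_log10_p", "set_name"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
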