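"""Venn accounting, resilience signature, hypergeometric ORA."""

import numpy as np
import pandas as pd
import pytest

from macrotime.datamodel import DataModelError, GeneSetCollection
from macrotime.signatures import (
    ora_hypergeometric,
    resilience_signature,
    time_dependent_sets,
)
from macrotime.stepminer import run_stepminer
from macrotime.synthetic import SimConfig, generate_cohort, truth_signature
from oracle_utils import hypergeom_upper_tail


def _step_table(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "p_value", "direction", "significant", "step_day"]
    )


class TestTimeDependentSets:
    def test_identical_tables(self):
        table = _step_table(
            [("G1", 0.001, "up", True, 7), ("G2", 0.5, "none", False, 14)]
        )
        set_a, set_b, venn = time_dependent_sets(table, table.copy())
        assert set_a == set_b == {"G1"}
        assert venn.shared == {"G1"}
        assert not venn.set_a_only and not venn.set_b_only

    def test_disjoint_sets(self):
        a = _step_table([("G1", 0.001, "up", True, 7), ("G2", 0.5, "none", False, 7)])
        b = _step_table([("G1", 0.9, "none", False, 7), ("G2", 0.002, "down", True, 7)])
        _, _, venn = time_dependent_sets(a, b)
        assert venn.shared == frozenset()
        assert venn.set_a_only == {"G1"} and venn.set_b_only == {"G2"}

    def test_direction_filter(self):
        a = _step_table([("G1", 0.001, "up", True, 7), ("G2", 0.001, "down", True, 7)])
        set_a, _, _ = time_dependent_sets(a, a.copy(), direction_filter="up")
        assert set_a == {"G1"}

    def test_partition_property(self, small_cohort):
        matrix, annotation, _ = small_cohort
        res = run_stepminer(matrix, annotation, "resilient")
        sev = run_stepminer(matrix, annotation, "severe")
        set_a, set_b, venn = time_dependent_sets(res, sev)
        assert len(venn.set_a_only) + len(venn.shared) == len(set_a)
        assert len(venn.set_b_only) + len(venn.shared) == len(set_b)
        assert not (venn.set_a_only & venn.set_b_only)

    def test_mismatched_universe_is_error(self):
        a = _step_table([("G1", 0.001, "up", True, 7)])
        b = _step_table([("G2", 0.001, "up", True, 7)])
        with pytest.raises(DataModelError, match="2 genes differ"):
            time_dependent_sets(a, b)


@pytest.fixture(scope="module")
def noiseless():
    config = SimConfig(
        n_genes=60, frac_flat=0.5, frac_step_up=0.3, frac_step_down=0.2,
        noise_sd=0.0, lps_frac=0.0, day1_inflammatory_frac=0.0,
        group_specific_step_fracs=(0.5, 0.25, 0.25), seed=9,
    )
    matrix, annotation, truth = generate_cohort(config)
    res = run_stepminer(matrix, annotation, "resilient")
    sev = run_stepminer(matrix, annotation, "severe")
    return matrix, annotation, truth, res, sev


class TestResilienceSignature:

    def test_planted_resilient_only_up_all_recovered(self, noiseless):
        matrix, annotation, truth, res, sev = noiseless
        table = resilience_signature(res, sev, matrix, annotation)
        expected = set(
            truth.loc[
                (truth["pattern_resilient"] == "step_up")
                & (truth["pattern_severe"] == "flat"),
                "gene_id",
            ]
        )
        assert set(table["gene_id"]) == expected
        # the step-up is visible as a rise from day 1 to later timepoints
        assert (table["day7plus_mean"] > table["day1_mean"]).all()

    def test_shared_and_down_genes_excluded(self, noiseless):
        matrix, annotation, truth, res, sev = noiseless
        table = resilience_signature(res, sev, matrix, annotation)
        shared = truth_signature(truth, "resilient") & truth_signature(truth, "severe")
        down = set(truth.loc[truth["pattern_resilient"] == "step_down", "gene_id"])
        assert not (set(table["gene_id"]) & shared)
        assert not (set(table["gene_id"]) & down)

    def test_empty_candidates_give_empty_table(self):
        a = _step_table([("G1", 0.9, "none", False, 7)])
        config = SimConfig(n_genes=1, seed=0)
        matrix, annotation, _ = generate_cohort(config)
        table = resilience_signature(a, a.copy(), matrix, annotation)
        assert table.empty


class TestORA:
    @pytest.fixture
    def collection(self):
        collection = GeneSetCollection()
        collection.add("SET10", "first ten", [f"G{i}" for i in range(10)])
        collection.add("SET40", "middle", [f"G{i}" for i in range(10, 50)])
        collection.add("OUTSIDE", "not measured", ["X1", "X2"])
        return collection

    def test_query_equals_universe_boundary(self):
        collection = GeneSetCollection()
        collection.add("ALL", "everything", ["G1", "G2", "G3"])
        table = ora_hypergeometric({"G1", "G2", "G3"}, collection, {"G1", "G2", "G3"})
        assert table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_zero_overlap_gives_p_one(self, collection):
        universe = {f"G{i}" for i in range(100)}
        table = ora_hypergeometric({"G99"}, collection, universe).set_index("set_name")
        assert table.loc["SET10", "k"] == 0
        assert table.loc["SET10", "p_value"] == pytest.approx(1.0)

    def test_matches_tail_summation(self, collection):
        universe = {f"G{i}" for i in range(100)}
        query = {f"G{i}" for i in range(5)} | {f"G{i}" for i in range(50, 65)}
        table = ora_hypergeometric(query, collection, universe).set_index("set_name")
        # SET10: N=100, K=10, n=20, k=5
        assert table.loc["SET10", ["k", "K", "n", "N"]].tolist() == [5, 10, 20, 100]
        assert table.loc["SET10", "p_value"] == pytest.approx(
            hypergeom_upper_tail(5, 100, 10, 20), rel=1e-12
        )

    def test_sorted_by_decreasing_neg_log10_p(self, collection):
        universe = {f"G{i}" for i in range(100)}
        query = {f"G{i}" for i in range(8)}
        table = ora_hypergeometric(query, collection, universe)
        assert (np.diff(table["neg_log10_p"]) <= 1e-12).all()
        assert (table["fdr"] >= table["p_value"] - 1e-12).all()

    def test_contract_errors(self, collection):
        with pytest.raises(DataModelError, match="empty universe"):
            ora_hypergeometric({"G1"}, collection, set())
        with pytest.raises(DataModelError, match="empty query"):
            ora_hypergeometric(set(), collection, {"G1"})
        with pytest.raises(DataModelError, match="not in universe"):
            ora_hypergeometric({"Z9"}, collection, {"G1"})
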