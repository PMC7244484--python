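"""Welch t-test, BH adjustment, contrasts, volcano tables."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from macrotime.datamodel import DataModelError
from macrotime.diffexpr import (
    bh_adjust,
    differential_expression,
    volcano_table,
    welch_t_test,
)
from macrotime.synthetic import SimConfig, generate_cohort
from oracle_utils import brute_force_bh


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_zero_variance_shift_gives_p_zero(self):
        t, df, p = welch_t_test([0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0])
        assert np.isinf(t) and p == 0.0

    def test_zero_variance_tie_warns(self):
        with pytest.warns(UserWarning, match="zero variance"):
            t, df, p = welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert t == 0.0 and p == 1.0

    def test_group_too_small(self):
        with pytest.raises(DataModelError, match="at least 2"):
            welch_t_test([1.0], [1.0, 2.0])

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            a = rng.normal(0, rng.uniform(0.5, 3), size=rng.integers(2, 30))
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3),
                           size=rng.integers(2, 30))
            t, df, p = welch_t_test(a, b)
            ref = stats.ttest_ind(b, a, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert df == pytest.approx(ref.df, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_symmetry_under_side_swap(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=10), rng.normal(1, 2, size=7)
        t1, df1, p1 = welch_t_test(a, b)
        t2, df2, p2 = welch_t_test(b, a)
        assert t2 == pytest.approx(-t1)
        assert df2 == pytest.approx(df1)
        assert p2 == pytest.approx(p1)


class TestBH:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])

    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(DataModelError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_brute_force_definition(self, p_values):
        np.testing.assert_allclose(
            bh_adjust(p_values), brute_force_bh(p_values), atol=1e-12
        )

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_capped(self, p_values):
        adjusted = bh_adjust(p_values)
        assert (adjusted >= np.asarray(p_values) - 1e-12).all()
        assert (adjusted <= 1.0).all()


@pytest.fixture(scope="module")
def cohort():
    config = SimConfig(n_genes=400, seed=23)
    return generate_cohort(config)


class TestDifferentialExpression:

    def test_day1_inflammatory_genes_rank_top(self, cohort):
        matrix, annotation, truth = cohort
        table = differential_expression(matrix, annotation, "day1_bpd_vs_none")
        planted = set(truth.loc[truth["day1_inflammatory"], "gene_id"])
        top = set(table.head(len(planted))["gene_id"])
        # planted offset 2.0 vs noise 0.5 at day-1 group sizes: nearly all on top
        assert len(planted & top) >= 0.9 * len(planted)
        planted_rows = table[table["gene_id"].isin(planted)]
        assert (planted_rows["fdr"] < 0.05).mean() >= 0.95
        assert (planted_rows["log2_fc"] > 0).all()

    def test_lps_contrast_recovers_planted_effect(self, cohort):
        matrix, annotation, truth = cohort
        table = differential_expression(matrix, annotation, "lps_vs_control_day1")
        planted = truth.loc[truth["lps_responsive"], "gene_id"]
        mean_fc = table.set_index("gene_id").loc[planted, "log2_fc"].mean()
        assert mean_fc == pytest.approx(3.0, abs=0.1)

    def test_side_swap_negates_fc(self, cohort):
        matrix, annotation, _ = cohort
        sel_a = {"day_of_life": 1, "treatment": "control"}
        sel_b = {"day_of_life": 1, "treatment": "LPS"}
        fwd = differential_expression(matrix, annotation, (sel_a, sel_b))
        rev = differential_expression(matrix, annotation, (sel_b, sel_a))
        fwd, rev = fwd.set_index("gene_id"), rev.set_index("gene_id")
        np.testing.assert_allclose(fwd["log2_fc"], -rev.loc[fwd.index, "log2_fc"])
        np.testing.assert_allclose(
            fwd["p_value"], rev.loc[fwd.index, "p_value"], atol=1e-12
        )

    def test_small_selector_is_error(self, cohort):
        matrix, annotation, _ = cohort
        with pytest.raises(DataModelError, match="selector"):
            differential_expression(
                matrix, annotation,
                ({"patient_id": "SEV001", "day_of_life": 1, "treatment": "control"},
                 {"day_of_life": 1, "treatment": "LPS"}),
            )

    def test_unknown_contrast_name(self, cohort):
        matrix, annotation, _ = cohort
        with pytest.raises(DataModelError, match="unknown contrast"):
            differential_expression(matrix, annotation, "day3_things")

    def test_null_split_controls_false_positives(self):
        """Contrasting a random split of one group: ~uniform p, few low FDRs."""
        config = SimConfig(
            n_genes=2000, frac_flat=1.0, frac_step_up=0.0, frac_step_down=0.0,
            lps_frac=0.0, day1_inflammatory_frac=0.0, seed=31,
        )
        matrix, annotation, _ = generate_cohort(config)
        day1 = annotation[
            (annotation["treatment"] == "control")
            & (annotation["resilience_class"] == "severe")
            & (annotation["day_of_life"] == 1)
        ]
        ids = sorted(day1["sample_id"])
        rng = np.random.default_rng(31)
        rng.shuffle(ids)
        half = len(ids) // 2
        sel_a = {"sample_id": ids[:half]}
        sel_b = {"sample_id": ids[half:]}
        table = differential_expression(matrix, annotation, (sel_a, sel_b))
        assert (table["p_value"] < 0.05).mean() <= 0.07
        assert (table["fdr"] < 0.05).mean() <= 0.01


class TestVolcano:
    def test_transform_and_clamping(self, small_cohort):
        matrix, annotation, _ = small_cohort
        table = differential_expression(matrix, annotation, "lps_vs_control_day1")
        volcano = volcano_table(table)
        row = volcano.set_index("gene_id")
        probe = table.iloc[len(table) // 2]
        if probe["p_value"] > 0:
            assert row.loc[probe["gene_id"], "neg_log10_p"] == pytest.approx(
                -np.log10(probe["p_value"])
            )
        # smaller p => larger -log10 p over the whole table
        merged = table.merge(volcano, on="gene_id")
        order = merged.sort_values("p_value")
        assert (np.diff(order["neg_log10_p"]) <= 1e-12).all()

    def test_p_zero_maps_above_max(self):
        import pandas as pd

        frame = pd.DataFrame(
            {"gene_id": ["A", "B"], "log2_fc": [1.0, 2.0],
             "p_value": [0.01, 0.0], "significant": [True, True]}
        )
        volcano = volcano_table(frame).set_index("gene_id")
        assert volcano.loc["A", "neg_log10_p"] == pytest.approx(2.0)
        assert volcano.loc["B", "neg_log10_p"] == pytest.approx(3.0)
        assert bool(volcano.loc["B", "p_clamped"])
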