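import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from projdense import (
    assign_ap_bin,
    colabel_proportions,
    distribution_table,
    overlap_from_counts,
    overlap_statistics,
    validate_cell_table,
)
from projdense.cell_stats import AP_BINS
from projdense.refdata import (
    ANIMALS,
    colabel_cell_table,
    distribution_cell_table,
    overlap_cell_table,
)


def _cells(rows):
    df = pd.DataFrame(
        rows,
        columns=[
            "animal", "bregma_mm", "subregion", "layer",
            "tracer_nac", "tracer_vta", "calb1", "ctip2", "foxp2",
        ],
    )
    return validate_cell_table(df)


class TestApBins:
    @pytest.mark.parametrize(
        "bregma,label",
        [
            (3.05, ">2.80 mm"),
            (2.80, "2.80–2.35 mm"),
            (2.35, "2.80–2.35 mm"),
            (2.00, "2.34–1.99 mm"),
            (1.98, "1.98–1.71 mm"),
            (1.50, "1.70–1.42 mm"),
            (1.30, "<1.42 mm"),
        ],
    )
    def test_printed_bin_edges(self, bregma, label):
        assert assign_ap_bin(bregma) == label

    @given(st.floats(-1.0, 4.0, allow_nan=False))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_every_value_gets_exactly_one_bin_and_order_is_monotone(self, x):
        label = assign_ap_bin(x)
        order = [b[0] for b in AP_BINS]
        assert label in order
        # moving rostrally can only move to an earlier (more rostral) bin
        assert order.index(assign_ap_bin(x + 0.5)) <= order.index(label)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            assign_ap_bin(float("nan"))


class TestDistribution:
    def test_reference_subregion_summary(self):
        table = distribution_cell_table("nac")
        dist = distribution_table(table, "nac", "subregion")
        mo = dist[dist.stratum == "MO"].iloc[0]
        assert (mo.n_A1, mo.n_A2, mo.n_A3) == (135, 404, 82)
        assert mo.mean_pct == pytest.approx(59.99, abs=5e-3)
        assert mo.sd_pct == pytest.approx(7.57, abs=5e-3)

    def test_reference_layer_summary(self):
        dist = distribution_table(distribution_cell_table("vta"), "vta", "layer")
        l5b = dist[dist.stratum == "L5b"].iloc[0]
        assert l5b.pooled_count == 1094
        assert l5b.mean_pct == pytest.approx(56.82, abs=5e-3)
        assert l5b.sd_pct == pytest.approx(6.91, abs=5e-3)

    @pytest.mark.parametrize("population,axis", [
        ("nac", "ap_bin"), ("nac", "subregion"), ("nac", "layer"),
        ("vta", "ap_bin"), ("vta", "subregion"), ("vta", "layer"),
    ])
    def test_counts_conserved_and_per_animal_percentages_sum_to_100(self, population, axis):
        table = distribution_cell_table(population)
        dist = distribution_table(table, population, axis)
        assert dist.pooled_count.sum() == len(table)
        for a in ANIMALS:
            col = 100.0 * dist[f"n_{a}"] / dist[f"n_{a}"].sum()
            assert col.sum() == pytest.approx(100.0, abs=1e-9)
        assert dist.pooled_pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_reference_ap_pooled_counts(self):
        dist = distribution_table(distribution_cell_table("vta"), "vta", "ap_bin")
        assert list(dist.pooled_count) == [23, 221, 530, 864, 115, 125]

    def test_single_stratum_degenerates_to_100_pct(self):
        rows = [
            ("A1", 2.0, "PrL", "L5a", 1, 0, pd.NA, pd.NA, pd.NA),
            ("A2", 2.0, "PrL", "L5a", 1, 0, pd.NA, pd.NA, pd.NA),
        ]
        dist = distribution_table(_cells(rows), "nac", "layer")
        row = dist[dist.stratum == "L5a"].iloc[0]
        assert row.mean_pct == pytest.approx(100.0)
        assert row.sd_pct == pytest.approx(0.0)

    def test_empty_population_rejected(self):
        rows = [("A1", 2.0, "PrL", "L5a", 1, 0, pd.NA, pd.NA, pd.NA)]
        with pytest.raises(ValueError, match="population"):
            distribution_table(_cells(rows), "vta", "layer")


class TestColabel:
    def test_reference_calb1_superficial_proportion(self):
        table = colabel_cell_table("nac", "calb1")
        (l23,) = [s for s in colabel_proportions(table, "nac", "calb1") if s.stratum == "L2/3"]
        assert l23.numerators == (84, 71, 42)
        assert l23.denominators == (128, 101, 60)
        assert l23.mean_pct == pytest.approx(68.64, abs=5e-3)
        assert l23.sd_pct == pytest.approx(2.62, abs=5e-3)

    def test_small_counts_are_suppressed_not_reported(self):
        # VTA-projecting cells barely found in the calbindin-rich layer:
        # per-animal denominators 4, 2, 5
        table = colabel_cell_table("vta", "calb1")
        summaries = {s.stratum: s for s in colabel_proportions(table, "vta", "calb1")}
        assert summaries["L2/3"].suppressed
        assert summaries["L2/3"].mean_pct is None
        # large denominators but only 7 marker-positive cells in total
        assert summaries["L5a-5b-6"].suppressed
        assert not summaries["Total"].suppressed

    def test_all_positive_gives_100_pct(self):
        rows = [
            ("A%d" % a, 2.0, "PrL", "L2/3", 1, 0, 1, pd.NA, pd.NA)
            for a in (1, 2, 3)
            for _ in range(12)
        ]
        for s in colabel_proportions(_cells(rows), "nac", "calb1"):
            if s.pooled_denominator:
                assert not s.suppressed
                assert s.mean_pct == pytest.approx(100.0)
                assert s.sd_pct == pytest.approx(0.0)

    def test_untested_cells_enter_neither_numerator_nor_denominator(self):
        rows = [
            ("A1", 2.0, "PrL", "L2/3", 1, 0, 1, pd.NA, pd.NA)
            for _ in range(10)
        ] + [
            ("A1", 2.0, "PrL", "L2/3", 1, 0, pd.NA, pd.NA, pd.NA)
            for _ in range(50)
        ]
        (total,) = [s for s in colabel_proportions(_cells(rows), "nac", "calb1")
                    if s.stratum == "Total"]
        assert total.pooled_denominator == 10
        assert total.pooled_numerator == 10

    def test_fully_untested_marker_rejected(self):
        rows = [("A1", 2.0, "PrL", "L2/3", 1, 0, 1, pd.NA, pd.NA)] * 5
        with pytest.raises(ValueError, match="untested"):
            colabel_proportions(_cells(rows), "nac", "ctip2")


class TestOverlap:
    def test_reference_counts_reproduce_ratio_summaries(self):
        ov = overlap_statistics(overlap_cell_table())
        assert ov.vta_single == (111, 489, 770)
        assert ov.double == (0, 55, 70)
        assert ov.ratios["double_over_vta"]["mean_pct"] == pytest.approx(6.78, abs=5e-3)
        assert ov.ratios["double_over_vta"]["sd_pct"] == pytest.approx(5.97, abs=5e-3)
        assert ov.ratios["double_over_nac"]["mean_pct"] == pytest.approx(1.54, abs=5e-3)
        assert ov.ratios["double_over_nac"]["sd_pct"] == pytest.approx(1.40, abs=5e-3)

    def test_explicit_totals_override_component_sum(self):
        ov = overlap_from_counts(
            ANIMALS, (269, 2940, 2551), (111, 489, 770), (0, 55, 70),
            totals=(380, 3374, 3251),
        )
        assert ov.ratios["double_over_total"]["mean_pct"] == pytest.approx(1.26, abs=5e-3)
        assert ov.ratios["double_over_total"]["sd_pct"] == pytest.approx(1.12, abs=5e-3)

    def test_zero_doubles_give_zero_ratios(self):
        ov = overlap_from_counts(("A1", "A2"), (10, 20), (5, 8), (0, 0))
        for ratio in ov.ratios.values():
            assert ratio["mean_pct"] == 0.0
            assert ratio["sd_pct"] == 0.0

    def test_zero_denominator_animal_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            ov = overlap_from_counts(("A1", "A2"), (10, 20), (0, 8), (3, 2))
        assert len(ov.ratios["double_over_vta"]["per_animal_pct"]) == 1

    def test_single_population_table_rejected(self):
        rows = [("A1", 2.0, "PrL", "L5a", 1, 0, pd.NA, pd.NA, pd.NA)] * 3
        with pytest.raises(ValueError, match="both tracer"):
            overlap_statistics(_cells(rows))
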