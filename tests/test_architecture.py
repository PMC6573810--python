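"""Genetic-architecture grids, liability variance and heritability sizing."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lodsim.architecture import (
    LOGISTIC_VARIANCE,
    SCENARIOS,
    ArchitectureScenario,
    VariantSpec,
    architecture_variance,
    build_architecture,
    build_scenario_grid,
    heritability_from_variance,
    mean_prs_offset,
    read_variant_table,
    sets_for_heritability,
    variance_for_heritability,
    write_variant_table,
)


class TestGrid:
    def test_scenario_a_prints_the_reference_grid(self):
        grid = build_scenario_grid(SCENARIOS["A"])
        mafs = sorted({v.eaf for v in grid})
        ors = sorted({v.odds_ratio for v in grid})
        assert mafs == [0.073, 0.180, 0.286, 0.393, 0.500]
        assert ors == [1.05, 1.075, 1.100, 1.125, 1.15]
        assert len(grid) == 25
        # full cross-product
        assert {(v.eaf, v.odds_ratio) for v in grid} == set(
            itertools.product(mafs, ors)
        )

    def test_scenario_e_bounds(self):
        grid = build_scenario_grid(SCENARIOS["E"])
        assert min(v.eaf for v in grid) == 0.0073
        assert max(v.eaf for v in grid) == 0.0499
        assert min(v.odds_ratio for v in grid) == 1.63
        assert max(v.odds_ratio for v in grid) == 4.05

    def test_two_point_grid_is_the_cross_product(self):
        scen = ArchitectureScenario("X", 0.1, 0.2, 1.1, 1.2, grid_points=2)
        grid = build_scenario_grid(scen)
        assert {(v.eaf, v.odds_ratio) for v in grid} == {
            (0.1, 1.1), (0.1, 1.2), (0.2, 1.1), (0.2, 1.2)
        }

    def test_or_axis_descends_as_maf_ascends(self):
        # label orientation: o1 is the largest OR
        grid = {v.variant_id: v for v in build_scenario_grid(SCENARIOS["A"])}
        assert grid["s1_m1_o1"].odds_ratio == 1.15
        assert grid["s1_m1_o5"].odds_ratio == 1.05
        assert grid["s1_m5_o1"].eaf == 0.500

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureScenario("bad", 0.3, 0.1, 1.05, 1.15)
        with pytest.raises(ValueError):
            ArchitectureScenario("bad", 0.1, 0.3, 1.2, 1.1)
        with pytest.raises(ValueError):
            ArchitectureScenario("bad", 0.1, 0.3, 1.05, 1.15, grid_points=1)

    def test_grid_is_deterministic(self):
        assert build_scenario_grid(SCENARIOS["B"]) == build_scenario_grid(
            SCENARIOS["B"]
        )


class TestVariance:
    def test_scenario_a_single_set_value(self):
        var = architecture_variance(build_scenario_grid(SCENARIOS["A"]))
        # truncates to the published 0.09098 at 5 decimals
        assert var == pytest.approx(0.0909860805, abs=1e-9)
        assert math.floor(var * 1e5) / 1e5 == 0.09098

    @pytest.mark.parametrize(
        "eaf,orv,expected",
        [(0.5, 1.0, 0.0), (0.5, 1.15, 2 * 0.25 * math.log(1.15) ** 2)],
    )
    def test_single_variant_hand_values(self, eaf, orv, expected):
        var = architecture_variance([VariantSpec("v", eaf, orv)])
        assert var == pytest.approx(expected, abs=1e-12)
        if orv == 1.15:
            assert var == pytest.approx(0.0097672, abs=5e-7)

    def test_additive_over_sets(self):
        one = build_scenario_grid(SCENARIOS["A"])
        five = [v for s in range(5) for v in build_scenario_grid(SCENARIOS["A"], s)]
        assert architecture_variance(five) == pytest.approx(
            5 * architecture_variance(one), rel=1e-9
        )

    def test_matches_exhaustive_hardy_weinberg_enumeration(self):
        # brute-force oracle: enumerate all genotypes of a 3-variant
        # architecture, weight by HW probabilities, take the PRS variance
        variants = [
            VariantSpec("a", 0.073, 1.15),
            VariantSpec("b", 0.286, 1.10),
            VariantSpec("c", 0.500, 1.05),
        ]
        probs = {v.variant_id: v.eaf for v in variants}
        total_var = 0.0
        mean = sum(2 * v.eaf * v.log_or for v in variants)
        var = 0.0
        for counts in itertools.product(range(3), repeat=3):
            w = 1.0
            prs = 0.0
            for v, a in zip(variants, counts):
                p = probs[v.variant_id]
                w *= [(1 - p) ** 2, 2 * p * (1 - p), p**2][a]
                prs += a * v.log_or
            var += w * (prs - mean) ** 2
        assert architecture_variance(variants) == pytest.approx(var, rel=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            architecture_variance([])


class TestHeritability:
    def test_fixed_points(self):
        assert heritability_from_variance(0.0) == 0.0
        assert heritability_from_variance(LOGISTIC_VARIANCE) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            heritability_from_variance(-1.0)

    def test_stroke_sizing_value(self):
        var = 25 * architecture_variance(build_scenario_grid(SCENARIOS["A"]))
        assert heritability_from_variance(var) == pytest.approx(0.40875, abs=5e-4)

    @pytest.mark.parametrize(
        "h2,total_variants",
        [(0.41, 625), (0.31, 400), (0.40, 600), (0.095, 100), (0.0, 0)],
    )
    def test_published_scenario_a_sizing(self, h2, total_variants):
        n_sets = sets_for_heritability(h2, "A")
        assert n_sets * 25 == total_variants

    def test_sizing_round_trips_within_one_set(self):
        one_set = architecture_variance(build_scenario_grid(SCENARIOS["A"]))
        for h2 in (0.05, 0.2, 0.41, 0.6, 0.795):
            n = sets_for_heritability(h2, "A")
            achieved = heritability_from_variance(n * one_set)
            above = heritability_from_variance((n + 1) * one_set)
            below = heritability_from_variance(max(0, n - 1) * one_set)
            assert abs(achieved - h2) <= max(above - achieved, achieved - below)

    @given(st.floats(min_value=0.0, max_value=0.95))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_variance(self, h2):
        v = variance_for_heritability(h2)
        assert heritability_from_variance(v) == pytest.approx(h2, abs=1e-12)
        assert heritability_from_variance(v + 0.1) > h2


class TestOffsetAndIO:
    def test_mean_offset_values(self):
        assert mean_prs_offset([VariantSpec("v", 0.5, 1.15)]) == pytest.approx(
            math.log(1.15), abs=1e-9
        )
        assert mean_prs_offset([VariantSpec("v", 0.3, 1.0)]) == 0.0
        one = build_scenario_grid(SCENARIOS["A"])
        two = one + build_scenario_grid(SCENARIOS["A"], 2)
        assert mean_prs_offset(two) == pytest.approx(2 * mean_prs_offset(one))

    def test_explicit_set_override(self):
        arch = build_architecture("A", target_h2=0.795, n_sets=143)
        assert arch.n_variants == 143 * 25

    def test_default_tracked_is_the_3x3_subgrid(self):
        arch = build_architecture("A", target_h2=0.31)
        assert len(arch.tracked_ids) == 9
        eafs = {v.eaf for v in arch.tracked_variants()}
        ors = {v.odds_ratio for v in arch.tracked_variants()}
        assert eafs == {0.073, 0.286, 0.500}
        assert ors == {1.05, 1.10, 1.15}

    def test_variant_table_round_trip(self, tmp_path):
        grid = build_scenario_grid(SCENARIOS["D"])
        path = tmp_path / "arch.txt"
        write_variant_table(grid, path)
        back = read_variant_table(path)
        assert [v.variant_id for v in back] == [v.variant_id for v in grid]
        np.testing.assert_allclose(
            [v.eaf for v in back], [v.eaf for v in grid], rtol=1e-6
        )
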