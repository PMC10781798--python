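"""Grid layout formulas, the published 24-chamber arrangement table, and
material savings."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from blistercalc import (
    AlveolusShape,
    AlveolusSpec,
    Material,
    SealPolicy,
    arrangement_sweep,
    grid_area,
    interspace_area,
    min_seal_margin,
    n_row_area,
    optimize_card,
    savings_percent,
    two_row_area,
)
from blistercalc.layout import MEAN_ROUND_ALVEOLUS_D_MM

ROUND11 = AlveolusSpec(shape=AlveolusShape.round, d_mm=11.0)

# Published 24-chamber reference table: rows -> margin k -> (area cm², % of
# the 4×6 arrangement).  Frozen from the source publication's printing.
REFERENCE_TABLE = {
    1: {2: (47.1, 109), 3: (57.6, 112), 4: (69.2, 115), 5: (81.7, 117)},
    2: {2: (44.2, 102), 3: (53.0, 103), 4: (62.6, 104), 5: (72.9, 105)},
    3: {2: (43.5, 101), 3: (51.8, 101), 4: (60.8, 101), 5: (70.5, 101)},
    4: {2: (43.2, 100), 3: (51.3, 100), 4: (60.2, 100), 5: (69.7, 100)},
}


class TestCalibration:
    def test_grid_search_recovers_the_calibrated_diameter(self):
        """An independent grid search over d ∈ [10, 12] (0.01 steps)
        minimizing the max deviation over all 16 reference cells must land
        on the calibrated 11.0 mm mean round-alveolus diameter."""

        def max_dev(d):
            return max(
                abs(
                    (r * d + (r + 1) * k) * (24 // r * d + (24 // r + 1) * k) / 100.0
                    - REFERENCE_TABLE[r][k][0]
                )
                for r in REFERENCE_TABLE
                for k in REFERENCE_TABLE[r]
            )

        grid = np.round(np.arange(10.0, 12.001, 0.01), 2)
        best = min(grid, key=max_dev)
        assert best == pytest.approx(MEAN_ROUND_ALVEOLUS_D_MM)
        # deviations at the optimum are printing-rounding noise only
        assert max_dev(best) <= 0.05 + 1e-9

    def test_all_sixteen_reference_cells_reproduce(self):
        for r, by_k in REFERENCE_TABLE.items():
            for k, (area, _) in by_k.items():
                assert grid_area(r, 24 // r, ROUND11, k) == pytest.approx(
                    area, abs=0.05
                )

    def test_all_sixteen_percentages_reproduce(self):
        for k in (2, 3, 4, 5):
            sweep = arrangement_sweep(24, ROUND11, [k], [1, 2, 3, 4])
            for _, row in sweep.iterrows():
                expected = REFERENCE_TABLE[row["n_rows"]][k][1]
                assert row["percent_of_squarest"] == expected


class TestClosedForms:
    @pytest.mark.parametrize(
        "alv, n, k, expected",
        [
            (ROUND11, 24, 2.0, 44.24),
            (AlveolusSpec(shape=AlveolusShape.elongated, e_mm=5, f_mm=20), 10, 2.0, 17.02),
            (AlveolusSpec(shape=AlveolusShape.round, d_mm=10.0), 2, 0.0, 2.0),
        ],
    )
    def test_two_row_area(self, alv, n, k, expected):
        assert two_row_area(alv, n, k) == pytest.approx(expected, abs=0.005)

    def test_two_row_odd_n_uses_fractional_columns(self):
        # literal evaluation of the closed form at n = 5
        d, k = 10.0, 2.0
        expected = (2 * d + 3 * k) * (k + 0.5 * 5 * (k + d)) / 100.0
        alv = AlveolusSpec(shape=AlveolusShape.round, d_mm=d)
        assert two_row_area(alv, 5, k) == pytest.approx(expected, rel=1e-12)

    def test_single_bare_alveolus(self):
        alv = AlveolusSpec(shape=AlveolusShape.round, d_mm=10.0)
        assert grid_area(1, 1, alv, 0.0) == pytest.approx(1.0)

    @given(
        d=st.floats(4.0, 16.0),
        k=st.floats(0.0, 8.0),
        half_n=st.integers(1, 30),
    )
    def test_grid_equals_two_row_for_even_n(self, d, k, half_n):
        alv = AlveolusSpec(shape=AlveolusShape.round, d_mm=d)
        n = 2 * half_n
        assert grid_area(2, half_n, alv, k) == pytest.approx(
            two_row_area(alv, n, k), rel=1e-12
        )

    @given(
        e=st.floats(3.0, 10.0),
        f=st.floats(8.0, 25.0),
        k=st.floats(0.0, 8.0),
        half_n=st.integers(1, 30),
    )
    def test_grid_two_row_identity_elongated(self, e, f, k, half_n):
        alv = AlveolusSpec(shape=AlveolusShape.elongated, e_mm=e, f_mm=f)
        assert grid_area(2, half_n, alv, k) == pytest.approx(
            two_row_area(alv, 2 * half_n, k), rel=1e-12
        )

    @given(
        d=st.floats(4.0, 16.0),
        k=st.floats(0.1, 8.0),
        r=st.integers(1, 6),
        cols=st.integers(1, 12),
        bump=st.floats(0.05, 3.0),
    )
    def test_area_strictly_monotone(self, d, k, r, cols, bump):
        alv = AlveolusSpec(shape=AlveolusShape.round, d_mm=d)
        base = grid_area(r, cols, alv, k)
        assert grid_area(r, cols, alv, k + bump) > base
        bigger = AlveolusSpec(shape=AlveolusShape.round, d_mm=d + bump)
        assert grid_area(r, cols, bigger, k) > base
        assert grid_area(r + 1, cols, alv, k) > base
        assert grid_area(r, cols + 1, alv, k) > base


class TestSquarestIsSmallest:
    @pytest.mark.parametrize("k", [2.0, 5.0])
    def test_brute_force_oracle_up_to_60(self, k):
        """Enumerating every factor pair confirms the minimum area sits at
        the pair minimizing |rows − cols|."""
        for n in range(1, 61):
            pairs = [(r, n // r) for r in range(1, n + 1) if n % r == 0]
            areas = {p: grid_area(p[0], p[1], ROUND11, k) for p in pairs}
            best_by_area = min(areas, key=areas.get)
            best_by_shape = min(pairs, key=lambda p: abs(p[0] - p[1]))
            assert areas[best_by_area] == pytest.approx(
                areas[best_by_shape], rel=1e-12
            )


class TestInterspaceCrossover:
    def test_interspace_exceeds_chamber_area_from_3mm(self):
        """On the 24-chamber 4×6 reference configuration the seal/gap
        material overtakes the chamber material from k = 3 mm upward."""
        from blistercalc import alveolus_base_area

        chamber_cm2 = 24 * alveolus_base_area(ROUND11) / 100.0
        assert interspace_area(4, 6, ROUND11, 2.0) < chamber_cm2
        for k in (3.0, 4.0, 5.0):
            assert interspace_area(4, 6, ROUND11, k) > chamber_cm2


class TestSavings:
    @pytest.mark.parametrize(
        "measured, optimized, printed_pct",
        [(52.1, 30.3, 42), (57.1, 33.3, 42)],
    )
    def test_savings_round_to_printed_percent(self, measured, optimized, printed_pct):
        assert round(savings_percent(measured, optimized)) == printed_pct

    def test_equal_areas_save_nothing(self):
        assert savings_percent(50.0, 50.0) == 0.0

    def test_enlargement_goes_negative(self):
        assert savings_percent(30.0, 40.0) < 0.0

    def test_zero_measured_area_rejected(self):
        with pytest.raises(ValueError):
            savings_percent(0.0, 10.0)


class TestSealPolicy:
    @pytest.mark.parametrize(
        "material, margin",
        [(Material.al_al, 4.0), (Material.al_plastic, 2.0), (Material.plastic, 2.0)],
    )
    def test_default_margins(self, material, margin):
        assert min_seal_margin(material) == margin

    def test_unknown_material_falls_back_conservatively(self, caplog):
        with caplog.at_level("WARNING", logger="blistercalc.layout"):
            assert min_seal_margin("paper") == 4.0
        assert any("unknown blister material" in r.message for r in caplog.records)

    def test_policy_override(self):
        policy = SealPolicy(margin_by_material={Material.al_al: 3.0})
        assert min_seal_margin(Material.al_al, policy) == 3.0


class TestOptimizeCard:
    def test_worked_round_card(self, worked_example):
        cards, _ = worked_example
        res = optimize_card(cards[0])  # al_plastic, d=11, n=24, 60 cm²
        assert res.margin_mm == 2.0
        assert res.optimized_cm2 == pytest.approx(44.24, abs=0.005)
        assert res.savings_pct == pytest.approx(26.3, abs=0.05)

    def test_card_already_optimal_saves_zero(self):
        from blistercalc import BlisterCardRecord, Shape, SodfSpec

        # marketed dimensions equal the 2 mm two-row optimum: 26 × 122 mm
        card = BlisterCardRecord(
            brand_id="OPT",
            material=Material.al_plastic,
            n_sodf=20,
            n_rows=2,
            card_length_i_mm=122.0,
            half_width_b_mm=13.0,
            gross_weight_g=8.0,
            gap_min_h_mm=2.0,
            gap_max_g_mm=2.0,
            alveolus=AlveolusSpec(shape=AlveolusShape.round, d_mm=10.0),
            sodf=SodfSpec(
                shape=Shape.round,
                strength_mg=50.0,
                diameter_mm=8.0,
                mass_g=0.2,
            ),
            package_size=100,
            cards_per_pack=5,
        )
        res = optimize_card(card)
        assert res.savings_pct == pytest.approx(0.0, abs=1e-9)

    def test_al_al_uses_wider_margin(self, worked_example):
        cards, _ = worked_example
        res = optimize_card(cards[1])  # al_al elongated
        assert res.margin_mm == 4.0
        assert res.optimized_cm2 > two_row_area(cards[1].alveolus, 10, 2.0)


class TestArrangementSweep:
    def test_rows_not_dividing_n_flagged_infeasible(self):
        sweep = arrangement_sweep(24, ROUND11, [2.0], [1, 2, 5])
        infeasible = sweep[~sweep["feasible"]]
        assert list(infeasible["n_rows"]) == [5]
        assert infeasible["percent_of_squarest"].isna().all()

    def test_square_count_self_normalizes(self):
        alv = AlveolusSpec(shape=AlveolusShape.round, d_mm=10.0)
        sweep = arrangement_sweep(4, alv, [2.0], [2])
        assert list(sweep["percent_of_squarest"]) == [100]
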