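"""Dose coefficients, KAP scaling model, dose synthesis and weighting."""

import numpy as np
import pytest

from ugidose.dosimetry import (DoseCoefficientSet, KAPSchedule,
                               REMAINDER_TISSUES, TISSUE_REGION_MAP,
                               TISSUE_WEIGHTS, compute_dc,
                               contrast_ratio_table, detriment_weighted_dose,
                               interpolate_dc, interpolate_dc_set,
                               kap_schedule, solve_pulse_kap, total_dose)
from ugidose.protocols import load_protocol


class TestComputeDC:
    def test_unit_conversion(self):
        dcs = compute_dc({"organ": 1e-12}, 1e-9)
        assert dcs["organ"] == pytest.approx(1.0)

    def test_scale_invariance(self):
        a = compute_dc({"o": 3e-13}, 2e-9)
        b = compute_dc({"o": 3e-13 * 7}, 2e-9 * 7)
        assert a["o"] == pytest.approx(b["o"])

    def test_zero_tally_zero_dc(self):
        assert compute_dc({"o": 0.0}, 1e-9)["o"] == 0.0

    def test_zero_kap_rejected(self):
        with pytest.raises(ValueError):
            compute_dc({"o": 1.0}, 0.0)


GRID = {(60.0, 2.5000): 10.0, (60.0, 5.7448): 20.0,
        (80.0, 2.9000): 30.0, (80.0, 7.7020): 50.0,
        (110.0, 3.9000): 40.0, (110.0, 9.9905): 80.0}


class TestInterpolateDC:
    def test_exact_at_grid_nodes(self):
        for (kvp, hvl), v in GRID.items():
            assert interpolate_dc(GRID, kvp, hvl) == pytest.approx(v)

    def test_hvl_midpoint_is_arithmetic_mean(self):
        mid = 0.5 * (2.5 + 5.7448)
        assert interpolate_dc(GRID, 60.0, mid) == pytest.approx(15.0)

    def test_log_linear_kvp_weights(self):
        # at 65 kVp the 60-kVp weight is ln(80/65)/ln(80/60) = 0.72177
        hvl = 3.2
        v60 = interpolate_dc(GRID, 60.0, hvl)
        v80 = interpolate_dc(GRID, 80.0, hvl)
        w60 = (np.log(80) - np.log(65)) / (np.log(80) - np.log(60))
        assert w60 == pytest.approx(0.72177, abs=1e-4)
        assert interpolate_dc(GRID, 65.0, hvl) == pytest.approx(
            w60 * v60 + (1 - w60) * v80)

    def test_monotone_between_nodes(self):
        vals = [interpolate_dc(GRID, 60.0, h)
                for h in np.linspace(2.5, 5.7448, 20)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpolate_dc(GRID, 50.0, 3.0)
        with pytest.raises(ValueError):
            interpolate_dc(GRID, 60.0, 9.0)

    def test_per_organ_interpolation(self):
        grid = {node: {"a": v, "b": 2 * v} for node, v in GRID.items()}
        out = interpolate_dc_set(grid, 60.0, 2.5)
        assert out == {"a": pytest.approx(10.0), "b": pytest.approx(20.0)}


class TestKAPModel:
    def test_pooled_solve_reproduces_published_constants(self):
        m = solve_pulse_kap()
        assert m.p_pulse_mgy_cm2 == pytest.approx(0.0252, abs=5e-5)
        assert m.p_frame_mgy_cm2 == pytest.approx(0.655, abs=5e-4)

    def test_single_protocol_variant(self):
        m = solve_pulse_kap(fluoro_seconds=(75.0,))
        assert m.p_pulse_mgy_cm2 == pytest.approx(
            0.02 / (562.5 + 156.0) * 1e3, rel=1e-9)
        assert m.p_pulse_mgy_cm2 == pytest.approx(0.0278, abs=5e-4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            solve_pulse_kap(median_total_gy_cm2=-1.0)


PAPER_TOTALS = {("newborn", "normal"): 1.811e-2,
                ("one_year", "normal"): 2.189e-2,
                ("newborn", "abnormal"): 1.905e-2,
                ("one_year", "abnormal"): 2.189e-2}


class TestKAPSchedule:
    @pytest.mark.parametrize("age,diag", list(PAPER_TOTALS))
    def test_totals_reproduce_published_tables(self, age, diag):
        sched = kap_schedule(load_protocol(age, diag), solve_pulse_kap())
        assert sched.total == pytest.approx(PAPER_TOTALS[(age, diag)],
                                            rel=5e-4)

    def test_field_and_spot_film_cells(self):
        sched = kap_schedule(load_protocol("newborn", "normal"),
                             solve_pulse_kap())
        assert sched.fluoro_gy_cm2[0] == pytest.approx(9.452e-4, rel=5e-4)
        assert sched.fluoro_gy_cm2[2] == pytest.approx(1.890e-3, rel=5e-4)
        assert max(sched.rad_gy_cm2) == pytest.approx(6.553e-4, rel=5e-4)
        assert sched.rad_gy_cm2[:3] == (0.0, 0.0, 0.0)

    def test_20_second_field_cell(self):
        sched = kap_schedule(load_protocol("one_year", "abnormal"),
                             solve_pulse_kap())
        assert max(sched.fluoro_gy_cm2) == pytest.approx(3.781e-3, rel=5e-4)


class TestTotalDose:
    def test_single_field_identity(self):
        dcs = DoseCoefficientSet({("f1", "fluoro"): {"o": 1.0}})
        sched = KAPSchedule(("f1",), (0.005,), (0.0,))
        assert total_dose(dcs, sched)["o"] == pytest.approx(0.005)

    def test_linearity_in_kap(self):
        dcs = DoseCoefficientSet({("f1", "fluoro"): {"o": 2.0},
                                  ("f2", "fluoro"): {"o": 3.0}})
        s1 = KAPSchedule(("f1", "f2"), (0.001, 0.002), (0.0, 0.0))
        s2 = KAPSchedule(("f1", "f2"), (0.002, 0.004), (0.0, 0.0))
        d1 = total_dose(dcs, s1)["o"]
        assert d1 == pytest.approx(0.008)  # 2*0.001 + 3*0.002
        assert total_dose(dcs, s2)["o"] == pytest.approx(2 * d1)

    def test_missing_dc_names_field_and_component(self):
        dcs = DoseCoefficientSet({("f1", "fluoro"): {"o": 1.0}})
        sched = KAPSchedule(("f1",), (0.001,), (0.0005,))
        with pytest.raises(KeyError, match="rad"):
            total_dose(dcs, sched)


class TestDetrimentWeightedDose:
    def test_weights_are_normalised(self):
        assert sum(TISSUE_WEIGHTS.values()) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_dose_identity(self):
        regions = set(TISSUE_REGION_MAP.values())
        doses = {r: 1.0 for r in regions}
        assert detriment_weighted_dose(doses) == pytest.approx(1.0, abs=1e-9)

    def test_stomach_only_dose(self):
        regions = set(TISSUE_REGION_MAP.values())
        doses = {r: 0.0 for r in regions}
        doses["stomach_wall"] = 2.0
        assert detriment_weighted_dose(doses) == pytest.approx(0.24)

    def test_all_zero(self):
        regions = set(TISSUE_REGION_MAP.values())
        assert detriment_weighted_dose({r: 0.0 for r in regions}) == 0.0

    def test_missing_region_rejected(self):
        with pytest.raises(KeyError):
            detriment_weighted_dose({"stomach_wall": 1.0})

    def test_remainder_uses_mean(self):
        regions = set(TISSUE_REGION_MAP.values())
        doses = {r: 0.0 for r in regions}
        doses["spleen"] = 13.0  # one of 13 remainder tissues
        expected = 0.12 * 13.0 / len(REMAINDER_TISSUES)
        assert detriment_weighted_dose(doses) == pytest.approx(expected)


class TestRatioTable:
    def test_identical_inputs_all_ones(self):
        d = {"F1": {"a": 1.0, "b": 2.0}, "Total": {"a": 3.0, "b": 4.0}}
        t = contrast_ratio_table(d, d)
        assert all(v == 1.0 for row in t.values() for v in row.values())

    def test_total_is_ratio_of_sums_not_mean_of_ratios(self):
        w = {"F1": {"a": 1.0}, "F2": {"a": 2.0},
             "Total": {"a": 3.0}}
        wo = {"F1": {"a": 2.0}, "F2": {"a": 2.0},
              "Total": {"a": 4.0}}
        t = contrast_ratio_table(w, wo)
        assert t["Total"]["a"] == pytest.approx(0.75)

    def test_zero_denominator_flagged(self):
        w = {"F1": {"a": 1.0}}
        wo = {"F1": {"a": 0.0}}
        assert contrast_ratio_table(w, wo)["F1"]["a"] is None

    def test_mismatched_fields_rejected(self):
        with pytest.raises(ValueError):
            contrast_ratio_table({"F1": {"a": 1.0}}, {"F2": {"a": 1.0}})
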