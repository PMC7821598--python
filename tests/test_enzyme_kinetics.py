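"""Kinetic-slope engine, calibration modes, and the activity panel."""

import numpy as np
import pytest

from mitoclamp.enzyme_kinetics import (
    KineticTrace,
    calibrate_activity,
    dehydrogenase_panel,
    kinetic_slope,
)
from mitoclamp.errors import (
    CalibrationError,
    DuplicateRowError,
    InvalidInputError,
    NonlinearTraceError,
)
from mitoclamp.ros_leak import StandardCurve
from mitoclamp.synthetic import gen_kinetic_trace_arrays


def _trace(t, y, assay="PDH", protein=0.005, blank=None):
    return KineticTrace(time_s=t, signal=y, assay_label=assay, protein_mg=protein,
                        blank_trace=blank)


class TestKineticSlope:
    def test_exact_linear_trace(self):
        t, y = gen_kinetic_trace_arrays(2.0, seed=0)
        slope, window, r2 = kinetic_slope(_trace(t, y))
        assert slope == pytest.approx(2.0, rel=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert window[0] == t[0]  # initial-rate convention: earliest window

    def test_blank_subtraction(self):
        t, y = gen_kinetic_trace_arrays(2.0, seed=0)
        tb, yb = gen_kinetic_trace_arrays(0.5, seed=0)
        slope, _, _ = kinetic_slope(_trace(t, y, blank=_trace(tb, yb)))
        assert slope == pytest.approx(1.5, rel=1e-9)

    def test_saturating_trace_early_slope_near_initial_rate(self):
        t, y = gen_kinetic_trace_arrays(3.0, seed=0, duration_s=30.0,
                                        saturating_tau_s=600.0)
        slope, _, _ = kinetic_slope(_trace(t, y))
        assert slope == pytest.approx(3.0, rel=0.05)

    def test_signal_scaling_scales_rate(self):
        t, y0 = gen_kinetic_trace_arrays(2.0, seed=1, noise_sd=0.01)
        y = y0 - y0[0]
        s1, _, _ = kinetic_slope(_trace(t, 100.0 + y))
        s2, _, _ = kinetic_slope(_trace(t, 100.0 + 3.0 * y))
        assert s2 == pytest.approx(3.0 * s1, rel=1e-6)

    def test_window_selection_is_deterministic(self):
        t, y = gen_kinetic_trace_arrays(2.0, seed=5, noise_sd=0.05)
        first = kinetic_slope(_trace(t, y))
        second = kinetic_slope(_trace(t, y))
        assert first == second

    def test_nonlinear_trace_rejected(self):
        t = np.arange(0.0, 60.0, 2.0)
        y = 100.0 + np.where(np.arange(len(t)) % 2 == 0, 5.0, -5.0)
        with pytest.raises(NonlinearTraceError):
            kinetic_slope(_trace(t, y))

    def test_unknown_assay_label_rejected(self):
        t, y = gen_kinetic_trace_arrays(1.0, seed=0)
        with pytest.raises(InvalidInputError):
            KineticTrace(time_s=t, signal=y, assay_label="hexokinase", protein_mg=0.01)


class TestCalibration:
    def test_beer_lambert_arithmetic(self):
        """1.36 AU/min over eps 13.6 mM^-1 cm^-1, 1 cm, 1 mL, 0.1 mg is 1000."""
        res = calibrate_activity(1.36, 0.1, calibration=13.6, path_cm=1.0, volume_mL=1.0)
        assert res.rate == pytest.approx(1000.0)
        assert res.units == "nmol/min/mg"
        assert res.calibration_mode == "extinction_coefficient"

    def test_zero_slope_gives_zero(self):
        assert calibrate_activity(0.0, 0.1, calibration=13.6).rate == 0.0

    def test_standard_curve_and_extinction_agree(self):
        # AU = eps * path * conc(mM); amount nmol in 1 mL -> conc uM, so the
        # consistent amount-based curve slope is eps/1000 AU per nmol
        curve = StandardCurve(np.empty(0), np.empty(0), slope=13.6 / 1000.0,
                              intercept=0.0, r_squared=1.0)
        via_curve = calibrate_activity(1.36, 0.1, calibration=curve)
        via_eps = calibrate_activity(1.36, 0.1, calibration=13.6, volume_mL=1.0)
        assert via_curve.rate == pytest.approx(via_eps.rate, rel=0.02)

    def test_uncalibrated_mode_keeps_au_units(self):
        res = calibrate_activity(2.0, 0.5)
        assert res.rate == pytest.approx(4.0)
        assert res.units == "AU/min/mg"

    def test_missing_calibration_parameters_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_activity(1.0, 0.1, calibration=-13.6)
        bad = StandardCurve(np.empty(0), np.empty(0), slope=1.0, intercept=0.0, r_squared=0.5)
        with pytest.raises(CalibrationError):
            calibrate_activity(1.0, 0.1, calibration=bad)

    def test_blank_subtraction_commutes_with_calibration(self):
        net = calibrate_activity(1.36 - 0.36, 0.1, calibration=13.6).rate
        separate = (
            calibrate_activity(1.36, 0.1, calibration=13.6).rate
            - calibrate_activity(0.36, 0.1, calibration=13.6).rate
        )
        assert net == pytest.approx(separate, rel=1e-12)


class TestPanel:
    def _records(self, animals=("a1", "a2"), assays=("PDH", "MDH", "CI")):
        records = []
        for animal in animals:
            for k, assay in enumerate(assays):
                t, y = gen_kinetic_trace_arrays(1.0 + k, seed=hash((animal, k)) % 1000)
                records.append(
                    {
                        "animal": animal, "sex": "M", "group": "control",
                        "assay": assay,
                        "trace": _trace(t, y, assay=assay),
                    }
                )
        return records

    def test_two_animals_three_assays_give_six_rows(self):
        panel = dehydrogenase_panel(self._records())
        assert len(panel) == 6
        assert panel["present"].all()

    def test_duplicate_rows_rejected(self):
        records = self._records()
        records.append(records[0].copy())
        with pytest.raises(DuplicateRowError):
            dehydrogenase_panel(records)

    def test_missing_assay_flagged_absent_not_imputed(self):
        records = self._records(animals=("a1",), assays=("PDH", "MDH"))
        panel = dehydrogenase_panel(records, expected_assays=["PDH", "MDH", "CI"])
        row = panel[(panel["animal"] == "a1") & (panel["assay"] == "CI")].iloc[0]
        assert not row["present"]
        assert np.isnan(row["rate"])
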