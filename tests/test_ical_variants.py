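"""Voltage clamp, I-V curves and conductance calibration."""
import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from lqt8sim import ical_variants as iv
from lqt8sim.constants import PEAK_DENSITY_FOLD
from lqt8sim.ionic_model import (CellState, CellTypeParams, default_state,
                                 get_variant, ionic_rhs)

WT = get_variant("WT")
R858H = get_variant("R858H")


class TestSteadyStateCurves:
    def test_half_activation_at_midpoint(self):
        assert iv.steady_state_activation(WT.va_half, WT) == pytest.approx(0.5)
        assert iv.steady_state_inactivation(WT.vina_half, WT) == pytest.approx(0.5)

    def test_saturation_limits(self):
        assert iv.steady_state_activation(200.0, WT) == pytest.approx(1.0, abs=1e-9)
        assert iv.steady_state_activation(-200.0, WT) == pytest.approx(0.0, abs=1e-9)
        assert iv.steady_state_inactivation(-200.0, WT) == pytest.approx(1.0, abs=1e-9)

    @given(st.floats(-80.0, 60.0), st.floats(-80.0, 60.0))
    def test_activation_increasing_inactivation_decreasing(self, v1, v2):
        lo, hi = min(v1, v2), max(v1, v2)
        assert iv.steady_state_activation(lo, WT) <= iv.steady_state_activation(hi, WT)
        assert iv.steady_state_inactivation(lo, WT) >= iv.steady_state_inactivation(hi, WT)

    def test_r858h_inactivation_halfpoint_shifted_positive(self):
        """The reported ~+2 mV shift of voltage inactivation vs WT."""
        v = np.linspace(-60, 20, 3201)
        half_wt = v[np.argmin(np.abs(iv.steady_state_inactivation(v, WT) - 0.5))]
        half_mut = v[np.argmin(np.abs(iv.steady_state_inactivation(v, R858H) - 0.5))]
        assert half_mut - half_wt == pytest.approx(2.0, abs=0.1)

    def test_r858h_window_current_exceeds_wt(self):
        assert iv.window_current_integral(R858H) > iv.window_current_integral(WT)


class TestVoltageClamp:
    def test_step_to_holding_potential_gives_no_current(self):
        proto = iv.VoltageClampProtocol(test_potentials=(-90.0 + 1e-6,))
        _, traces = iv.simulate_voltage_clamp(WT, proto)
        assert np.abs(traces).max() < 0.05  # pA/pF

    def test_depolarizing_step_peak_is_inward(self):
        proto = iv.VoltageClampProtocol(test_potentials=(0.0,))
        _, traces = iv.simulate_voltage_clamp(WT, proto)
        assert traces.min() < -5.0

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            iv.VoltageClampProtocol(step_duration=0.0)
        with pytest.raises(ValueError):
            iv.VoltageClampProtocol(test_potentials=(0.0, -10.0))

    def test_clamp_agrees_with_independent_ode_integration(self):
        """Cross-check one clamp step against scipy's LSODA on the reference
        right-hand side with vm pinned."""
        proto = iv.VoltageClampProtocol(test_potentials=(0.0,))
        times, traces = iv.simulate_voltage_clamp(WT, proto)
        ct = CellTypeParams.for_class("ENDO")

        # reproduce the pre-step holding phase, then the step, via solve_ivp
        def rhs_clamped(t, y):
            s = CellState.from_vector(y)
            dy, _ = ionic_rhs(s, ct, WT)
            dy[0] = 0.0
            return dy

        y0 = default_state().as_vector()
        y0[0] = -90.0
        hold = solve_ivp(rhs_clamped, (0, 2000.0), y0, method="LSODA",
                         rtol=1e-8, atol=1e-10)
        y1 = hold.y[:, -1]
        y1[0] = 0.0
        stepsol = solve_ivp(rhs_clamped, (0, 300.0), y1, method="LSODA",
                            rtol=1e-8, atol=1e-10, dense_output=True)
        from lqt8sim.ionic_model import ical_current
        ical_ref = []
        for t in times:
            s = CellState.from_vector(stepsol.sol(t))
            s.vm = 0.0
            ical_ref.append(ical_current(s, WT))
        ical_ref = np.array(ical_ref)
        assert traces[0].min() == pytest.approx(ical_ref.min(), rel=0.01)


class TestIVCurve:
    def test_all_zero_traces_give_zero_curve(self):
        proto = iv.VoltageClampProtocol()
        curve = iv.compute_iv_curve(
            np.zeros((len(proto.test_potentials), 100)), proto)
        assert np.all(curve.peak_density == 0.0)

    def test_empty_traces_rejected(self):
        with pytest.raises(ValueError):
            iv.compute_iv_curve(np.empty((0, 0)))

    def test_peak_equals_bruteforce_minimum_over_samples(self):
        proto = iv.VoltageClampProtocol(test_potentials=(-20.0, 0.0, 20.0))
        _, traces = iv.simulate_voltage_clamp(WT, proto)
        curve = iv.compute_iv_curve(traces, proto)
        for row, peak in zip(traces, curve.peak_density):
            assert peak == min(row)

    def test_wt_curve_has_unique_interior_minimum(self):
        _, traces = iv.simulate_voltage_clamp(WT)
        curve = iv.compute_iv_curve(traces)
        k = int(np.argmin(curve.peak_density))
        assert 0 < k < len(curve.peak_density) - 1
        diffs = np.sign(np.diff(curve.peak_density))
        # strictly decreasing then strictly increasing around the minimum
        assert np.all(diffs[:k] == -1) and np.all(diffs[k:] == 1)


class TestCalibration:
    def test_identity_for_wt_at_unit_target(self):
        csf = iv.calibrate_csf(WT, 1.0, rel_tol=1e-3)
        assert csf == pytest.approx(1.0, abs=2e-3)

    def test_monotone_in_target_fold(self):
        lo = iv.calibrate_csf(WT, 0.9, rel_tol=1e-3)
        hi = iv.calibrate_csf(WT, 1.2, rel_tol=1e-3)
        assert lo < 1.0 < hi

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            iv.calibrate_csf(WT, -1.0)

    def test_unbracketed_root_reports_interval(self):
        with pytest.raises(ValueError, match=r"\[0.9, 1.1\]"):
            iv.calibrate_csf(WT, 5.0, lo=0.9, hi=1.1)

    def test_shipped_table_reproduces_experimental_folds(self, fold_ratios):
        """The frozen csf values hit every fold ratio within 0.5%."""
        folds = fold_ratios
        for label, target in PEAK_DENSITY_FOLD.items():
            assert folds[label] == pytest.approx(target, rel=5e-3), label
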