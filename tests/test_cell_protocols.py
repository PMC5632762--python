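"""APD measurement, restitution protocols and afterdepolarization detection."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lqt8sim import cell_protocols as cp
from lqt8sim.runner_fixtures import SyntheticTraceSpec, generate_synthetic_trace


class TestApd90:
    def test_trapezoid_fixture_matches_closed_form(self):
        spec = SyntheticTraceSpec(plateau_ms=200.0, ramp_ms=100.0)
        tr = generate_synthetic_trace(spec)
        assert cp.apd90(tr) == pytest.approx(290.0, abs=2 * spec.dt)

    @given(plateau=st.floats(100.0, 300.0), ramp=st.floats(40.0, 200.0))
    def test_closed_form_holds_for_arbitrary_geometry(self, plateau, ramp):
        spec = SyntheticTraceSpec(plateau_ms=plateau, ramp_ms=ramp,
                                  cycle_ms=1000.0)
        tr = generate_synthetic_trace(spec)
        assert cp.apd90(tr) == pytest.approx(spec.apd90, abs=2 * spec.dt)

    def test_sustained_depolarization_flagged(self):
        t = np.arange(0, 500, 0.1)
        vm = np.where(t < 1.0, -85.0, 30.0)  # never repolarizes
        tr = cp.Trace(t, vm, stim_times=np.array([0.0]))
        with pytest.raises(cp.MeasurementError):
            cp.apd90(tr)

    def test_beat_indexing_selects_the_right_beat(self):
        spec = SyntheticTraceSpec(plateau_ms=150.0, ramp_ms=80.0, beats=3)
        tr = generate_synthetic_trace(spec)
        for b in range(3):
            assert cp.apd90(tr, b) == pytest.approx(spec.apd90, abs=0.3)


class TestPacing:
    def test_steady_state_beat_to_beat_convergence(self, paced_trace):
        tr = paced_trace("ENDO", "WT")
        assert abs(cp.apd90(tr, -1) - cp.apd90(tr, -2)) < 1.0

    def test_rate_adaptation_apd_shortens_with_pcl(self, paced_trace):
        """APD decreases as the cycle length drops from 2,000 to 500 ms."""
        for var in ("G1783C", "WT", "P381S", "M456I", "A582D", "R858H"):
            for cls in ("ENDO", "MCELL", "EPI"):
                apds = [cp.apd90(paced_trace(cls, var, pcl))
                        for pcl in (2000.0, 1000.0, 500.0)]
                assert apds[0] > apds[1] > apds[2], (var, cls)

    def test_invalid_protocol_rejected(self):
        with pytest.raises(ValueError):
            cp.pace("ENDO", "WT", pcl=0.5)
        with pytest.raises(ValueError):
            cp.pace("ENDO", "WT", 1000.0, n_beats=0)


class TestRestitution:
    def test_dynamic_curve_consistent_with_steady_pacing(self, paced_trace):
        curve = cp.restitution_dynamic("ENDO", "WT",
                                       pcl_schedule=[1000.0, 950.0, 900.0])
        steady = cp.apd90(paced_trace("ENDO", "WT"))
        # the 30-beat point at PCL 1,000 equals the 100-beat steady APD
        assert curve.apd[-1] == pytest.approx(steady, abs=2.0)

    def test_dynamic_apd_nonincreasing_with_rate(self):
        curve = cp.restitution_dynamic("ENDO", "WT")
        assert np.all(np.diff(curve.apd) >= -1.0)  # sorted by DI ascending

    def test_s1s2_long_di_recovers_steady_apd(self):
        curve = cp.restitution_s1s2("ENDO", "WT", di_list=[150.0, 800.0])
        s1_apd = cp.apd90(cp.pace("ENDO", "WT", 1000.0, 30, record_last=1))
        assert curve.apd[curve.di == 800.0][0] == pytest.approx(s1_apd, abs=2.0)
        assert curve.apd[0] < curve.apd[-1]  # short DI gives shorter APD

    def test_s1s2_and_dynamic_agree_at_long_di(self):
        """Protocol equivalence in the fully recovered limit."""
        s12 = cp.restitution_s1s2("ENDO", "WT", di_list=[700.0])
        dyn = cp.restitution_dynamic("ENDO", "WT", pcl_schedule=[1000.0, 990.0])
        i = int(np.argmin(np.abs(dyn.di - 700.0)))
        assert abs(s12.apd[0] - dyn.apd[i]) < 5.0

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            cp.restitution_dynamic("ENDO", "WT", pcl_schedule=[500.0, 600.0])


class TestMaxSlope:
    def test_straight_line_slope_recovered(self):
        di = np.linspace(50, 500, 20)
        curve = cp.APDRCurve(di, 0.5 * di + 120.0, "dynamic")
        assert cp.max_apdr_slope(curve) == pytest.approx(0.5, rel=1e-9)

    def test_matches_bruteforce_secant_maximum_on_convex_curve(self):
        di = np.linspace(20, 600, 40)
        apd = 280.0 - 150.0 * np.exp(-di / 80.0)
        curve = cp.APDRCurve(di, apd, "dynamic")
        secants = np.diff(apd) / np.diff(di)
        assert cp.max_apdr_slope(curve) == pytest.approx(secants.max(), abs=0.05)

    def test_duplicate_di_rejected(self):
        with pytest.raises(ValueError):
            cp.max_apdr_slope(cp.APDRCurve([10, 10, 20], [100, 110, 120], "s1s2"))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cp.max_apdr_slope(cp.APDRCurve([10, 20], [100, 110], "s1s2"))


class TestAfterdepolarizations:
    def test_monotonic_repolarization_yields_no_events(self):
        tr = generate_synthetic_trace(SyntheticTraceSpec())
        assert cp.detect_afterdepolarizations(tr) == []

    def test_bump_after_repolarization_is_a_dad(self):
        spec = SyntheticTraceSpec(plateau_ms=200.0, ramp_ms=100.0,
                                  bump_time=380.0, bump_amplitude=5.0)
        events = cp.detect_afterdepolarizations(generate_synthetic_trace(spec))
        assert [e.kind for e in events] == ["DAD"]
        assert events[0].onset_time == pytest.approx(380.0, abs=1.0)

    def test_bump_during_late_repolarization_is_an_ead(self):
        # the bump must rise faster than the 1.2 mV/ms repolarization ramp
        spec = SyntheticTraceSpec(plateau_ms=200.0, ramp_ms=100.0,
                                  bump_time=275.0, bump_amplitude=15.0,
                                  bump_width=16.0)
        events = cp.detect_afterdepolarizations(generate_synthetic_trace(spec))
        assert [e.kind for e in events] == ["EAD"]

    def test_subthreshold_bump_below_prominence_ignored(self):
        spec = SyntheticTraceSpec(bump_time=380.0, bump_amplitude=0.5)
        assert cp.detect_afterdepolarizations(
            generate_synthetic_trace(spec)) == []

    def test_notch_dome_morphology_not_misclassified(self, paced_trace):
        """The Ito spike-notch-dome of a WT MCELL AP is normal morphology."""
        assert cp.detect_afterdepolarizations(paced_trace("MCELL", "WT")) == []


class TestCalciumBiomarkers:
    def test_constant_channels_give_zero_amplitude(self):
        t = np.arange(0, 1000, 0.1)
        tr = cp.Trace(t, np.full_like(t, -85.0),
                      channels={"cai": np.full_like(t, 1e-4),
                                "casr": np.full_like(t, 3.0),
                                "irel": np.zeros_like(t)},
                      stim_times=np.array([0.0]))
        bio = cp.calcium_biomarkers(tr)
        assert bio["cai_amp"] == 0.0
        assert bio["casr_max"] == 3.0

    def test_missing_channel_named_in_error(self):
        tr = generate_synthetic_trace(SyntheticTraceSpec())
        with pytest.raises(cp.MeasurementError, match="cai"):
            cp.calcium_biomarkers(tr)

    def test_identical_classes_give_zero_differences(self):
        bio = {"cai_amp": 1e-4, "casr_max": 3.0}
        diffs = cp.transmural_differences(
            {"ENDO": bio, "MCELL": bio, "EPI": bio})
        assert all(v == 0.0 for d in diffs.values() for v in d.values())

    def test_sr_load_rises_along_allele_ordering(self, paced_trace):
        loads = [cp.calcium_biomarkers(paced_trace("ENDO", v))["casr_max"]
                 for v in ("G1783C", "WT", "P381S", "M456I", "A582D", "R858H")]
        assert np.all(np.diff(loads) > 0)
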