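"""Monodomain solver: stability, boundaries, conduction and classification."""
import numpy as np
import pytest

from lqt8sim import monodomain_tissue as mt


class TestStability:
    def test_transmural_configuration_number(self):
        num, ok = mt.check_stability(mt.TissueParams(0.0385, 0.15, 0.02))
        assert num == pytest.approx(0.0385 * 0.02 / 0.15 ** 2, rel=1e-12)
        assert num == pytest.approx(0.0342, abs=5e-4)
        assert ok

    def test_2d_mcell_configuration_number(self):
        num, ok = mt.check_stability(mt.TissueParams(0.154, 0.25, 0.02))
        assert num == pytest.approx(0.0493, abs=5e-4)
        assert ok

    def test_vanishing_dx_fails_and_simulation_refuses(self):
        params = mt.TissueParams(0.0385, 0.001, 0.02)
        num, ok = mt.check_stability(params)
        assert num >= 0.5 and not ok
        geo = mt.build_homogeneous_cable(n=8, dx=0.001)
        with pytest.raises(mt.StabilityError):
            mt.simulate(geo, params, [], 1.0, init="resting")


class TestGeometry:
    def test_transmural_cable_composition(self):
        geo = mt.build_transmural_cable()
        assert geo.n == 165
        assert geo.length_mm == pytest.approx(24.75)
        cm = geo.class_map
        assert np.all(cm[:60] == mt.CLASS_CODES["ENDO"])
        assert np.all(cm[60:105] == mt.CLASS_CODES["MCELL"])
        assert np.all(cm[105:] == mt.CLASS_CODES["EPI"])
        # segment boundaries at 9.0 and 15.75 mm
        changes = np.nonzero(np.diff(cm))[0] + 1
        assert list(changes * geo.dx) == pytest.approx([9.0, 15.75])

    def test_homogeneous_builder_is_uniform(self):
        geo = mt.build_homogeneous_cable("MCELL")
        assert np.all(geo.class_map == mt.CLASS_CODES["MCELL"])

    def test_sheet_tiles_the_cable(self):
        geo = mt.build_transmural_sheet(lateral_mm=3.0)
        assert geo.ny == 20 and geo.nx == 165

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError):
            mt.Geometry(np.array([0, 7]), 0.15)


class TestDiffusionOperator:
    def test_uniform_field_stays_spatially_uniform(self):
        """With no-flux boundaries a uniform field has zero diffusion
        current everywhere, so spatial spread stays at machine precision."""
        geo = mt.build_homogeneous_cable(n=40)
        st = mt.simulate(geo, mt.TissueParams(), [], 50.0, init="resting",
                         rec_dt=10.0)
        spread = st.vm.max(axis=1) - st.vm.min(axis=1)
        assert np.all(spread < 1e-9)

    def test_pure_diffusion_conserves_total_vm(self):
        """No-flux boundaries conserve the discrete content.  With mirror
        ghost nodes the conserved quantity carries half weights at the two
        boundary cells (the finite-volume reading of the stencil)."""
        geo = mt.build_homogeneous_cable(n=80)
        y0 = np.tile(np.zeros(19), (80, 1))
        x = np.arange(80)
        y0[:, 0] = 100.0 * np.exp(-((x - 40.0) ** 2) / 30.0) - 85.0
        st = mt.simulate(geo, mt.TissueParams(), [], 100.0, reaction=False,
                         initial_states=y0, rec_dt=10.0)
        w = np.ones(80)
        w[0] = w[-1] = 0.5
        final = st.meta["final_states"][:, 0]
        assert (w * final).sum() == pytest.approx((w * y0[:, 0]).sum(),
                                                  rel=1e-10)
        assert not np.allclose(final, y0[:, 0])  # it did diffuse

    def test_pure_diffusion_matches_heat_kernel(self):
        """A Gaussian profile spreads per the closed-form heat solution."""
        D, dx = 0.0385, 0.15
        n = 400
        geo = mt.build_homogeneous_cable(n=n)
        x = geo.positions_mm()
        x0, s0, amp = x[n // 2], 1.2, 50.0
        y0 = np.tile(np.zeros(19), (n, 1))
        y0[:, 0] = amp * np.exp(-((x - x0) ** 2) / (2 * s0 ** 2))
        t_end = 100.0
        st = mt.simulate(geo, mt.TissueParams(D, dx), [], t_end,
                         reaction=False, initial_states=y0, rec_dt=10.0)
        s_t = np.sqrt(s0 ** 2 + 2 * D * t_end)
        expected = amp * (s0 / s_t) * np.exp(-((x - x0) ** 2) / (2 * s_t ** 2))
        final = st.meta["final_states"][:, 0]
        assert np.max(np.abs(final - expected)) < 0.01 * amp


class TestConduction:
    def test_cv_mesh_consistency_on_refinement(self, homogeneous_cv):
        """Halving dx changes CV by the first-order scheme's known numerical
        dispersion (~8% at the study grid, where the upstroke spans only a
        few nodes); the refined value must stay within 10% and above the
        coarse one (dispersion slows the discrete front)."""
        cv1 = homogeneous_cv("WT")
        cv2 = homogeneous_cv("WT", dx=0.075)
        assert cv2 > cv1
        assert abs(cv2 - cv1) / cv1 < 0.10

    def test_cv_scales_with_sqrt_of_diffusivity(self, homogeneous_cv):
        """Cable theory: speed proportional to sqrt(D).  The monodomain PDE
        is invariant under x -> 2x, D -> 4D, so scaling dx with sqrt(D)
        keeps the discrete problem self-similar and the ratio lands on 2
        almost exactly."""
        cv1 = homogeneous_cv("WT")
        cv4 = homogeneous_cv("WT", d_coeff=4 * 0.0385, dx=0.30)
        assert cv4 / cv1 == pytest.approx(2.0, rel=0.02)

    def test_unstimulated_probe_flagged(self):
        geo = mt.build_homogeneous_cable(n=40)
        st = mt.simulate(geo, mt.TissueParams(), [], 20.0, init="resting")
        with pytest.raises(ValueError, match="CV probe"):
            mt.measure_cv(st)

    def test_zero_amplitude_stimulus_is_no_capture(self):
        geo = mt.build_homogeneous_cable()
        onsets = np.arange(4) * 300.0
        stim = mt.end_stimulus(geo, onsets, amplitude=0.0)
        st = mt.simulate(geo, mt.TissueParams(), [stim], 1300.0)
        assert mt.classify_conduction(st, onsets, n_eval=4) == "no_capture"

    def test_wt_cable_conducts_one_to_one_at_slow_pacing(self, transmural_run):
        st = transmural_run("WT")
        onsets = np.arange(10) * 1000.0
        assert mt.classify_conduction(st, onsets) == "1:1"

    def test_transmural_apd_longest_in_m_segment(self, transmural_run):
        from lqt8sim import pseudo_ecg as pe
        prof = pe.repolarization_metrics(transmural_run("WT"), 9000.0)
        m_slice = slice(60, 105)
        assert prof.apd[m_slice].max() == prof.apd.max()


class TestFocalActivity:
    def test_injected_ectopic_source_classified_as_pvc(self):
        """A suprathreshold stimulus away from the pacing site must be
        reported as a premature ventricular complex."""
        geo = mt.build_homogeneous_cable()
        onsets = np.arange(3) * 500.0
        s1 = mt.end_stimulus(geo, onsets)
        ectopic = mt.StimulusRegion(np.array([80, 81, 82]),
                                    np.array([1400.0]))
        st = mt.simulate(geo, mt.TissueParams(), [s1, ectopic], 1800.0)
        events = mt.detect_focal_activity(st, s1)
        pvc = [e for e in events if e.kind == "pvc"]
        assert pvc and any(abs(e.node - 81) < 8 for e in pvc)

    def test_clean_wt_run_has_no_focal_events(self):
        geo = mt.build_homogeneous_cable()
        onsets = np.arange(4) * 500.0
        s1 = mt.end_stimulus(geo, onsets)
        st = mt.simulate(geo, mt.TissueParams(), [s1], 2000.0)
        assert mt.detect_focal_activity(st, s1) == []


class TestSpectral:
    def test_pure_sinusoid_frequency_recovered(self):
        t = np.arange(0, 8000.0, 1.0)  # ms
        sig = np.sin(2 * np.pi * 3.0 * t / 1000.0)
        assert mt.dominant_frequency(sig, 1.0) == pytest.approx(3.0, abs=0.15)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            mt.dominant_frequency(np.zeros(10), 1.0)
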