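"""Unipolar pseudo-ECG and repolarization biomarkers for 1D cable runs.

The extracellular potential at a virtual electrode on the cable axis is the
discretized line integral of (-dVm/dx) * d(1/r)/dx (Gima-Rudy formulation).
The amplitude scale constant affects mV values only; every time-based
biomarker (QT, T-wave width, RT, DOR, MSG) is invariant to it.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell_protocols import Trace, _repol_crossing
from .monodomain_tissue import SpaceTimeVm

#: Amplitude scale (mm^2): sets the WT T-wave peak to the ~1 mV order.
ECG_SCALE_MM2 = 9.0

#: Default electrode offset beyond the ENDO end of the cable (mm).
#: (An ENDO-side electrode yields the upright T wave this transmural
#: composition produces; the sign convention keeps QRS polarity consistent.)
ELECTRODE_OFFSET_MM = 20.0

#: T-end tail cutoff: fraction of the T-peak height above the diastolic
#: plateau at which the baseline intersection is read (the discrete cable
#: leaves a small standing diastolic offset that never crosses y = 0 exactly).
T_END_FRACTION = 0.005

#: Q-onset detection threshold as a fraction of the R-wave peak.
Q_ONSET_FRACTION = 0.02


class ECGMeasurementError(ValueError):
    """An ECG landmark could not be located."""


@dataclass
class ECGTrace:
    """Unipolar potential phi_e (mV) on the run's recording time grid."""
    time: np.ndarray
    phi_e: np.ndarray

    def __post_init__(self):
        if len(self.time) != len(self.phi_e):
            raise ValueError("time and phi_e must have equal length")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class RepolarizationProfile:
    """Per-node APD and the derived repolarization biomarkers.

    ``rt`` is the repolarization-time metric: the latest 90%-repolarization
    instant in the cable measured from the beat's stimulus (activation time
    plus local APD).  ``apd_max`` is the largest bare APD for reference.
    ``dor`` is the dispersion of repolarization, max - min APD.
    """
    positions_mm: np.ndarray
    apd: np.ndarray            # ms, per node
    repol_time: np.ndarray     # ms from the beat stimulus, per node
    gradient: np.ndarray       # ms/mm, centered differences of APD
    rt: float                  # ms, latest repolarization instant
    apd_max: float             # ms, largest APD in the cable
    dor: float                 # ms, max - min APD
    msg: float                 # ms/mm, max |gradient|
    msg_epi_m: float           # ms/mm, max |gradient| near the EPI-M junction


def compute_pseudo_ecg(spacetime: SpaceTimeVm,
                       electrode_mm: float | None = None,
                       scale: float = ECG_SCALE_MM2) -> ECGTrace:
    """Discretized Gima-Rudy integral along a 1D cable.

    The electrode sits on the cable axis at ``electrode_mm`` (default:
    20 mm beyond the far end); positions inside the cable are rejected.
    """
    geo = spacetime.geometry
    if geo.ny != 1:
        raise ValueError("pseudo-ECG requires a 1D cable run")
    pos = geo.positions_mm()
    if electrode_mm is None:
        electrode_mm = -ELECTRODE_OFFSET_MM
    if 0.0 <= electrode_mm <= geo.length_mm:
        raise ValueError("electrode must lie outside the cable")
    r = electrode_mm - pos
    vm = spacetime.vm
    dvdx = np.gradient(vm, geo.dx, axis=1)     # mV/mm
    kernel = np.sign(r) / r ** 2               # d(1/r)/dx for an axial electrode
    phi = scale * np.sum(-dvdx * kernel[None, :], axis=1) * geo.dx
    return ECGTrace(spacetime.times.copy(), phi)


def _landmarks(ecg: ECGTrace, beat_start: float, beat_end: float | None = None):
    """(q_onset, r_peak_t, t_peak_t, t_end) of one beat."""
    t = ecg.time
    phi = ecg.phi_e
    if beat_end is None:
        beat_end = t[-1]
    sel = (t >= beat_start) & (t <= beat_end)
    tt, pp = t[sel], phi[sel]
    if len(tt) < 10:
        raise ECGMeasurementError("beat window too short")
    qrs_sel = tt <= beat_start + 60.0
    r_abs = np.abs(pp[qrs_sel]).max()
    i_q = np.nonzero(np.abs(pp) > Q_ONSET_FRACTION * r_abs)[0]
    if len(i_q) == 0:
        raise ECGMeasurementError("no QRS deflection above the noise floor")
    q_onset = tt[i_q[0]]
    r_peak_t = tt[qrs_sel][np.argmax(np.abs(pp[qrs_sel]))]

    t_sel = tt >= beat_start + 120.0
    if not t_sel.any():
        raise ECGMeasurementError("no T-wave window in the beat")
    i_tpk = np.argmax(pp[t_sel])
    t_peak_t = tt[t_sel][i_tpk]
    t_peak_v = pp[t_sel][i_tpk]
    # T end: interpolated intersection of the T downslope with the baseline
    # y = 0.  The discrete cable's diastolic class heterogeneity leaves a
    # small standing offset, so the crossing is read where the wave has
    # fallen to within T_END_FRACTION of its height above the end-of-beat
    # plateau.
    plateau = float(np.median(pp[tt >= tt[-1] - 50.0]))
    level = plateau + T_END_FRACTION * (t_peak_v - plateau)
    t_end = _repol_crossing(tt, pp, int(np.nonzero(t_sel)[0][0] + i_tpk), level)
    if t_end is None:
        raise ECGMeasurementError("T wave does not return to baseline")
    return float(q_onset), float(r_peak_t), float(t_peak_t), float(t_end)


def qt_interval(ecg: ECGTrace, beat_start: float = 0.0,
                beat_end: float | None = None) -> float:
    """Q-wave onset to T-wave end (baseline y = 0 intersection), ms."""
    q_onset, _, _, t_end = _landmarks(ecg, beat_start, beat_end)
    return t_end - q_onset


def t_wave_metrics(ecg: ECGTrace, beat_start: float = 0.0,
                   beat_end: float | None = None) -> dict[str, float]:
    """T-wave width (peak to end, ms) and amplitude (peak phi_e, mV)."""
    _, _, t_peak_t, t_end = _landmarks(ecg, beat_start, beat_end)
    sel = (ecg.time >= beat_start + 120.0)
    if beat_end is not None:
        sel &= ecg.time <= beat_end
    amp = float(ecg.phi_e[sel].max())
    return {"width": t_end - t_peak_t, "amplitude": amp,
            "t_peak_time": t_peak_t, "t_end_time": t_end}


def repolarization_metrics(spacetime: SpaceTimeVm, beat_start: float,
                           epi_m_junction_mm: float | None = None,
                           junction_halfwidth_mm: float = 1.5
                           ) -> RepolarizationProfile:
    """Per-node APD90 and RT / DOR / spatial-gradient biomarkers.

    Tissue APD is measured from the node's maximum-dVm/dt time (tracked at
    full resolution in the activation window) to 90% repolarization of the
    recorded vm.  RT is the largest APD in the cable; DOR is max - min APD;
    the spatial gradient uses centered differences over x.
    """
    geo = spacetime.geometry
    if geo.ny != 1:
        raise ValueError("repolarization metrics require a 1D cable run")
    pos = geo.positions_mm()
    t = spacetime.times
    sel = t >= beat_start
    tt = t[sel]
    apd = np.empty(geo.n)
    for node in range(geo.n):
        vm = spacetime.vm[sel, node]
        t_act = spacetime.dvdt_argt[node]
        if not np.isfinite(t_act):
            raise ECGMeasurementError(f"node {node} never activated")
        rest = vm[0]
        peak = vm.max()
        level = rest + 0.1 * (peak - rest)
        i_peak = int(np.argmax(vm))
        crossing = _repol_crossing(tt, vm, i_peak, level)
        if crossing is None:
            raise ECGMeasurementError(f"node {node} failed to repolarize")
        apd[node] = crossing - t_act
    repol_time = spacetime.dvdt_argt - beat_start + apd
    grad = np.gradient(apd, pos)
    if epi_m_junction_mm is None:
        # transmural composition boundary between MCELL and EPI segments
        cm = geo.class_map
        j = np.nonzero(np.diff(cm) != 0)[0]
        epi_m_junction_mm = pos[j[-1]] if len(j) else pos[len(pos) // 2]
    near = np.abs(pos - epi_m_junction_mm) <= junction_halfwidth_mm
    return RepolarizationProfile(
        positions_mm=pos, apd=apd, repol_time=repol_time, gradient=grad,
        rt=float(repol_time.max()), apd_max=float(apd.max()),
        dor=float(apd.max() - apd.min()),
        msg=float(np.abs(grad).max()),
        msg_epi_m=float(np.abs(grad[near]).max()))


def membrane_potential_heterogeneity(trace_a: Trace, trace_b: Trace):
    """delta(t) = |vm_a - vm_b| on a shared time grid, and its maximum (mV).

    Traces must share the grid (single-cell APs aligned on the stimulus).
    """
    if len(trace_a.time) != len(trace_b.time) or \
            abs(trace_a.dt - trace_b.dt) > 1e-12:
        raise ValueError("traces must share one time grid")
    delta = np.abs(trace_a.vm - trace_b.vm)
    return delta, float(delta.max())
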