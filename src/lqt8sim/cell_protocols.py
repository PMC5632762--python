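"""Single-cell experiments: pacing, APD, restitution, afterdepolarizations
and calcium-handling biomarkers.

All measurements operate on :class:`Trace` objects (uniform time grid), so
every operation is equally applicable to simulated APs and to synthetic
fixtures with analytically known geometry.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .constants import DT_MS, STIM_CELL_AMP, STIM_CELL_MS
from .ionic_model import _pace_vector, _prepaced_vector, default_state, get_variant

#: Default recording resolution for single-cell traces (ms).
REC_DT_MS = 0.1

#: Afterdepolarization prominence threshold (mV above the local trend).
AD_PROMINENCE_MV = 1.0


class MeasurementError(ValueError):
    """A biomarker could not be measured (e.g. no repolarization)."""


@dataclass
class Trace:
    """Single-site time series of vm with optional channels.

    ``time`` is a uniform grid in ms; ``channels`` may hold ical, incx, irel
    (pA/pF resp. mM/ms), cai, casr (mM).  ``stim_times`` mark stimulus onsets
    (ms, on the same clock as ``time``).
    """
    time: np.ndarray
    vm: np.ndarray
    channels: dict = field(default_factory=dict)
    stim_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.vm = np.asarray(self.vm, float)
        if len(self.time) != len(self.vm):
            raise ValueError("time and vm must have equal length")
        dt = np.diff(self.time)
        if len(dt) and (dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-9)):
            raise ValueError("time grid must be uniform and increasing")
        for name, ch in self.channels.items():
            if len(ch) != len(self.time):
                raise ValueError(f"channel {name!r} length mismatch")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class APDRCurve:
    """APD vs diastolic interval, tagged by protocol."""
    di: np.ndarray
    apd: np.ndarray
    protocol: str  # "dynamic" or "s1s2"

    def __post_init__(self):
        self.di = np.asarray(self.di, float)
        self.apd = np.asarray(self.apd, float)
        order = np.argsort(self.di)
        self.di = self.di[order]
        self.apd = self.apd[order]
        if np.any(self.di <= 0):
            raise ValueError("diastolic intervals must be positive")


@dataclass(frozen=True)
class AfterdepolarizationEvent:
    kind: str        # "EAD" or "DAD"
    onset_time: float  # ms
    prominence: float  # mV


# ---------------------------------------------------------------------------
# Pacing
# ---------------------------------------------------------------------------

def pace(cell_class: str, variant, pcl: float, n_beats: int = 100,
         record_last: int | None = None, dt: float = DT_MS,
         stim_amp: float = STIM_CELL_AMP, stim_ms: float = STIM_CELL_MS,
         rec_dt: float = REC_DT_MS) -> Trace:
    """Pace a cell from the published initial conditions.

    Integration runs at ``dt`` (default 0.02 ms); the returned trace is
    sampled every ``rec_dt``.  ``record_last`` restricts recording to the
    final beats to bound memory.  Loss of excitability (a stimulated beat
    with no upstroke) in the recorded window raises :class:`MeasurementError`.
    """
    if pcl <= stim_ms:
        raise ValueError("pcl must exceed the stimulus duration")
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    variant = get_variant(variant)
    n_rec_beats = n_beats if record_last is None else min(record_last, n_beats)
    rec_start_ms = (n_beats - n_rec_beats) * pcl
    y = default_state().as_vector()
    stride = max(1, int(round(rec_dt / dt)))
    rec = _pace_vector(y, cell_class, variant, pcl, n_beats, dt,
                       stim_amp, stim_ms, rec_stride=stride,
                       rec_start_ms=rec_start_ms)
    time = rec_start_ms + np.arange(rec.shape[0]) * dt * stride
    stim_times = np.arange(n_beats) * pcl
    stim_times = stim_times[stim_times >= rec_start_ms - 1e-9]
    trace = Trace(time, rec[:, 0],
                  channels={"ical": rec[:, 1], "incx": rec[:, 2],
                            "irel": rec[:, 3], "cai": rec[:, 4],
                            "casr": rec[:, 5]},
                  stim_times=stim_times,
                  meta={"cell_class": cell_class.upper(),
                        "variant": variant.label, "pcl": pcl,
                        "n_beats": n_beats, "dt": dt})
    last = _beat_slice(trace, -1)
    if trace.vm[last].max() < -40.0:
        raise MeasurementError(
            f"loss of excitability: no upstroke in the final beat "
            f"({cell_class}/{variant.label} at PCL {pcl} ms)")
    return trace


def _beat_slice(trace: Trace, beat_index: int) -> slice:
    """Index slice of one beat window [stim_k, stim_{k+1})."""
    if len(trace.stim_times) == 0:
        return slice(0, len(trace.time))
    stims = trace.stim_times
    k = range(len(stims))[beat_index]
    t0 = stims[k]
    t1 = stims[k + 1] if k + 1 < len(stims) else trace.time[-1] + trace.dt
    i0 = int(np.searchsorted(trace.time, t0 - 1e-9))
    i1 = int(np.searchsorted(trace.time, t1 - 1e-9))
    if i1 <= i0 + 2:
        raise MeasurementError(f"beat {beat_index} not contained in trace")
    return slice(i0, i1)


def _beat_features(trace: Trace, beat_index: int = -1):
    """(upstroke time, resting vm, peak vm, beat slice) of one beat."""
    sl = _beat_slice(trace, beat_index)
    t = trace.time[sl]
    vm = trace.vm[sl]
    rest = vm[0]
    dvdt = np.diff(vm) / trace.dt
    i_up = int(np.argmax(dvdt))
    return t[i_up], rest, float(vm.max()), sl


def _repol_crossing(t, vm, i_start, level):
    """First downward interpolated crossing of ``level`` at/after i_start."""
    below = np.nonzero((vm[i_start:-1] >= level) & (vm[i_start + 1:] < level))[0]
    if len(below) == 0:
        return None
    i = i_start + below[0]
    frac = (vm[i] - level) / (vm[i] - vm[i + 1])
    return t[i] + frac * (t[i + 1] - t[i])


def apd_at(trace: Trace, beat_index: int = -1, fraction: float = 0.9) -> float:
    """AP duration at a repolarization fraction (APD90 for fraction=0.9).

    Measured from the maximum-upstroke-velocity time to the interpolated
    crossing of resting + (1-fraction) x amplitude on the downstroke.
    """
    t_up, rest, peak, sl = _beat_features(trace, beat_index)
    t = trace.time[sl]
    vm = trace.vm[sl]
    level = rest + (1.0 - fraction) * (peak - rest)
    i_peak = int(np.argmax(vm))
    crossing = _repol_crossing(t, vm, i_peak, level)
    if crossing is None:
        raise MeasurementError(
            f"no {fraction:.0%} repolarization within the cycle "
            f"(sustained depolarization or window too short)")
    return float(crossing - t_up)


def apd90(trace: Trace, beat_index: int = -1) -> float:
    """APD at 90% repolarization of the given beat (default: final beat)."""
    return apd_at(trace, beat_index, 0.9)


# ---------------------------------------------------------------------------
# Restitution
# ---------------------------------------------------------------------------

def default_dynamic_schedule() -> list[float]:
    """PCL schedule: 1000 -> 400 ms in 50-ms steps, then 10-ms steps."""
    return [float(p) for p in range(1000, 399, -50)] + \
           [float(p) for p in range(390, 199, -10)]


def restitution_dynamic(cell_class: str, variant, pcl_schedule=None,
                        beats_per_pcl: int = 30, dt: float = DT_MS) -> APDRCurve:
    """Dynamic restitution: 30 stimuli per PCL down a decreasing schedule.

    For each PCL the last APD is plotted against the last diastolic interval
    (PCL minus the penultimate beat's APD).  The scan stops at loss of 1:1
    capture.  The cell state carries over between PCL stages, as in the
    experimental protocol.
    """
    if pcl_schedule is None:
        pcl_schedule = default_dynamic_schedule()
    pcl_schedule = list(map(float, pcl_schedule))
    if np.any(np.diff(pcl_schedule) >= 0):
        raise ValueError("pcl_schedule must be strictly decreasing")
    variant = get_variant(variant)
    y = default_state().as_vector()
    stride = max(1, int(round(REC_DT_MS / dt)))
    dis, apds = [], []
    for pcl in pcl_schedule:
        rec = _pace_vector(y, cell_class, variant, pcl, beats_per_pcl, dt,
                           STIM_CELL_AMP, STIM_CELL_MS, rec_stride=stride,
                           rec_start_ms=(beats_per_pcl - 2) * pcl)
        time = np.arange(rec.shape[0]) * dt * stride
        tr = Trace(time, rec[:, 0], stim_times=np.array([0.0, pcl]))
        if tr.vm[_beat_slice(tr, -1)].max() < -40.0 \
                or tr.vm[_beat_slice(tr, 0)].max() < -40.0:
            break  # loss of 1:1 capture ends the protocol
        try:
            apd_prev = apd90(tr, 0)
            apd_last = apd90(tr, 1)
        except MeasurementError:
            break
        di = pcl - apd_prev
        if di <= 0:
            break
        dis.append(di)
        apds.append(apd_last)
    if not dis:
        raise MeasurementError("no captured beats in the dynamic protocol")
    return APDRCurve(np.array(dis), np.array(apds), "dynamic")


def restitution_s1s2(cell_class: str, variant, di_list=None,
                     s1_pcl: float = 1000.0, n_s1: int = 30,
                     dt: float = DT_MS) -> APDRCurve:
    """S1-S2 restitution: a premature S2 after 30 conditioning S1 beats.

    The S2 is delivered at the programmed diastolic interval after the last
    S1 action potential's APD90; its APD is plotted against the DI.  An S2
    that fails to capture is recorded as a missing point.
    """
    if di_list is None:
        di_list = [1000, 900, 800, 700, 600, 500, 400, 300, 250, 200, 150,
                   100, 80, 60, 40, 20, 10]
    di_list = np.asarray(di_list, float)
    if np.any(di_list <= 0):
        raise ValueError("diastolic intervals must be positive")
    variant = get_variant(variant)

    y = default_state().as_vector()
    stride = max(1, int(round(REC_DT_MS / dt)))
    # 29 conditioning beats, then measure beat 30 to time the S2
    _pace_vector(y, cell_class, variant, s1_pcl, n_s1 - 1, dt,
                 STIM_CELL_AMP, STIM_CELL_MS)
    y30 = y.copy()
    rec = _pace_vector(y.copy(), cell_class, variant, s1_pcl, 1, dt,
                       STIM_CELL_AMP, STIM_CELL_MS, rec_stride=stride)
    tr30 = Trace(np.arange(rec.shape[0]) * dt * stride, rec[:, 0],
                 stim_times=np.array([0.0]))
    t_up, _, _, _ = _beat_features(tr30, 0)
    apd_s1 = apd90(tr30, 0)
    t_end_s1 = t_up + apd_s1

    dis, apds = [], []
    for di in di_list:
        s2_time = t_end_s1 + di
        horizon = s2_time + 1000.0
        from . import _kernels
        from .ionic_model import CellTypeParams, build_variant_lut
        ct = CellTypeParams.for_class(cell_class)
        lut = build_variant_lut(variant, dt)
        n_steps = int(round(horizon / dt))
        stim_steps = np.array([0, int(round(s2_time / dt))], dtype=np.int64)
        rec_start = int(round(s2_time / dt)) - stride
        n_rec = (n_steps - rec_start - 1) // stride + 1
        rec = np.empty((n_rec, 6))
        yy = y30.copy().reshape(19, 1)
        bad = _kernels.run_cell(yy, lut, ct.endo_s_gate, ct.g_to, ct.g_ks,
                                variant.csf, dt, n_steps, stim_steps,
                                int(round(STIM_CELL_MS / dt)), STIM_CELL_AMP,
                                stride, rec_start, rec)
        if bad >= 0:
            raise FloatingPointError(f"non-finite vm during S2 run (DI {di})")
        time = rec_start * dt + np.arange(rec.shape[0]) * dt * stride
        tr = Trace(time, rec[:, 0], stim_times=np.array([s2_time]))
        if tr.vm.max() < -40.0:
            continue  # S2 failed to capture: missing point
        try:
            apds.append(apd90(tr, 0))
            dis.append(di)
        except MeasurementError:
            continue
    if not dis:
        raise MeasurementError("no S2 beat captured at any programmed DI")
    return APDRCurve(np.array(dis), np.array(apds), "s1s2")


def max_apdr_slope(curve: APDRCurve) -> float:
    """Maximum centered-finite-difference slope d(APD)/d(DI) of the curve."""
    di, apd = curve.di, curve.apd
    if len(di) < 3:
        raise ValueError("need at least 3 restitution points")
    if np.any(np.diff(di) == 0):
        raise ValueError("duplicate diastolic intervals")
    slopes = np.gradient(apd, di)
    return float(slopes.max())


# ---------------------------------------------------------------------------
# Afterdepolarizations
# ---------------------------------------------------------------------------

def detect_afterdepolarizations(trace: Trace,
                                prominence: float = AD_PROMINENCE_MV):
    """Positive-going vm deflections during or after repolarization.

    Per beat: deflections (peak prominence above ``prominence``) between the
    50% and 90% repolarization times are EADs; between 90% repolarization and
    the next stimulus, DADs.  The upstroke, the Ito notch-dome complex and
    the plateau (before 50% repolarization) are excluded.
    """
    events: list[AfterdepolarizationEvent] = []
    n_beats = max(len(trace.stim_times), 1)
    for b in range(n_beats):
        t_up, rest, peak, sl = _beat_features(trace, b)
        t = trace.time[sl]
        vm = trace.vm[sl]
        i_peak = int(np.argmax(vm))
        lvl50 = rest + 0.5 * (peak - rest)
        lvl90 = rest + 0.1 * (peak - rest)
        t50 = _repol_crossing(t, vm, i_peak, lvl50)
        t90 = _repol_crossing(t, vm, i_peak, lvl90)
        if t50 is None:
            continue  # no repolarization phase to search
        pk, props = find_peaks(vm, prominence=prominence)
        for i, p in enumerate(pk):
            tp = t[p]
            if t90 is not None and tp > t90:
                events.append(AfterdepolarizationEvent(
                    "DAD", float(tp), float(props["prominences"][i])))
            elif tp > t50:
                events.append(AfterdepolarizationEvent(
                    "EAD", float(tp), float(props["prominences"][i])))
    return events


# ---------------------------------------------------------------------------
# Calcium handling and transmural summaries
# ---------------------------------------------------------------------------

def calcium_biomarkers(trace: Trace) -> dict[str, float]:
    """Final-beat calcium biomarkers.

    Returns ``cai_amp`` (peak minus diastolic cytosolic calcium, mM),
    ``casr_max`` (peak SR calcium, mM) and ``irel_max`` (peak SR release
    flux, mM/ms).
    """
    for ch in ("cai", "casr", "irel"):
        if ch not in trace.channels:
            raise MeasurementError(f"trace lacks required channel {ch!r}")
    sl = _beat_slice(trace, -1)
    cai = trace.channels["cai"][sl]
    return {
        "cai_amp": float(cai.max() - cai[0]),
        "casr_max": float(trace.channels["casr"][sl].max()),
        "irel_max": float(trace.channels["irel"][sl].max()),
    }


def transmural_differences(per_class: dict[str, dict[str, float]]
                           ) -> dict[str, dict[str, float]]:
    """Signed pairwise biomarker differences between cell classes.

    ``per_class`` maps class name (ENDO/MCELL/EPI) to a biomarker dict; the
    result maps "ENDO-EPI", "ENDO-M", "EPI-M" to per-biomarker differences.
    """
    pairs = {"ENDO-EPI": ("ENDO", "EPI"), "ENDO-M": ("ENDO", "MCELL"),
             "EPI-M": ("EPI", "MCELL")}
    out = {}
    for tag, (a, b) in pairs.items():
        keys = per_class[a].keys() & per_class[b].keys()
        out[tag] = {k: per_class[a][k] - per_class[b][k] for k in keys}
    return out
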