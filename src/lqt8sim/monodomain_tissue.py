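"""Monodomain reaction-diffusion tissue: 1D cables and 2D sheets.

Solves Cm dVm/dt = D lap(Vm) - Iion with forward-Euler time marching,
3-point (1D) / 5-point (2D) Laplacians and no-flux (mirror) boundaries.
Nodes carry the full TP06 state with a uniform I_CaL variant; the cell-class
map sets the transmural composition (60 ENDO / 45 MCELL / 60 EPI for the
standard 24.75-mm transmural cable).

Provides conduction-velocity measurement, distal-capture (2:1 block)
classification, the maximum-2:1-block-PCL (MPCL) scan, focal-activity
detection on homogeneous cables, S1-S1 vulnerability classification on
transmural sheets, and cross-field spiral induction with dominant-frequency
read-out.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, periodogram

from . import _kernels
from .constants import (DT_MS, DX_MCELL_2D_MM, DX_TRANSMURAL_MM, D_MCELL_2D,
                        D_TRANSMURAL, STIM_TISSUE_AMP, STIM_TISSUE_MS)
from .ionic_model import (CellTypeParams, _prepaced_vector, build_variant_lut,
                          default_state, get_variant)

CLASS_CODES = {"ENDO": 0, "MCELL": 1, "EPI": 2}
_CODE_CLASSES = {v: k for k, v in CLASS_CODES.items()}

#: Upstroke detection threshold for activation bookkeeping (mV).
ACT_THRESHOLD_MV = -20.0


class StabilityError(ValueError):
    """The explicit scheme's CFL-type criterion D dt/dx^2 < 1/2 is violated."""


@dataclass(frozen=True)
class TissueParams:
    """Solver constants for a monodomain run."""
    d_coeff: float = D_TRANSMURAL   # mm^2/ms
    dx: float = DX_TRANSMURAL_MM    # mm
    dt: float = DT_MS               # ms
    cm: float = 1.0                 # uF/cm^2

    @property
    def stability_number(self) -> float:
        return self.d_coeff * self.dt / self.dx ** 2


def check_stability(params: TissueParams) -> tuple[float, bool]:
    """Return (D dt/dx^2, passes) for the explicit diffusion update."""
    num = params.stability_number
    return num, bool(num < 0.5)


@dataclass
class Geometry:
    """Node layout: 1D when ny == 1; row-major (ny, nx) otherwise.

    For transmural geometries axis x runs ENDO -> MCELL -> EPI; a 2D sheet
    stores the transmural direction along x and the lateral extent along y.
    """
    class_map: np.ndarray      # int codes per node (flattened, row-major)
    dx: float
    ny: int = 1
    label: str = ""

    def __post_init__(self):
        self.class_map = np.asarray(self.class_map, dtype=np.int64)
        if self.class_map.ndim != 1:
            raise ValueError("class_map must be flat (row-major)")
        if self.n % self.ny != 0:
            raise ValueError("node count not divisible by ny")
        if not np.all(np.isin(self.class_map, list(_CODE_CLASSES))):
            raise ValueError("every node needs a valid cell class")

    @property
    def n(self) -> int:
        return len(self.class_map)

    @property
    def nx(self) -> int:
        return self.n // self.ny

    @property
    def length_mm(self) -> float:
        return self.nx * self.dx

    def positions_mm(self) -> np.ndarray:
        """Node-centre x positions along the (transmural) axis."""
        return (np.arange(self.nx) + 0.5) * self.dx


def build_transmural_cable(n_endo: int = 60, n_m: int = 45, n_epi: int = 60,
                           dx: float = DX_TRANSMURAL_MM) -> Geometry:
    """The standard transmural cable: contiguous ENDO, MCELL, EPI segments."""
    cm = np.concatenate([np.zeros(n_endo), np.ones(n_m), np.full(n_epi, 2)])
    return Geometry(cm.astype(np.int64), dx, label="transmural-cable")


def build_homogeneous_cable(cell_class: str = "MCELL", n: int = 165,
                            dx: float = DX_TRANSMURAL_MM) -> Geometry:
    code = CLASS_CODES[cell_class.upper()]
    return Geometry(np.full(n, code, dtype=np.int64), dx,
                    label=f"homogeneous-cable-{cell_class.upper()}")


def build_transmural_sheet(lateral_mm: float = 150.0,
                           dx: float = DX_TRANSMURAL_MM) -> Geometry:
    """Transmural sheet: the transmural cable extended laterally (axis y)."""
    cable = build_transmural_cable(dx=dx)
    ny = int(round(lateral_mm / dx))
    cm = np.tile(cable.class_map, ny)
    return Geometry(cm, dx, ny=ny, label="transmural-sheet")


def build_homogeneous_sheet(cell_class: str = "MCELL", size_mm: float = 375.0,
                            dx: float = DX_MCELL_2D_MM,
                            size_y_mm: float | None = None) -> Geometry:
    nx = int(round(size_mm / dx))
    ny = int(round((size_y_mm if size_y_mm else size_mm) / dx))
    code = CLASS_CODES[cell_class.upper()]
    return Geometry(np.full(nx * ny, code, dtype=np.int64), dx, ny=ny,
                    label=f"homogeneous-sheet-{cell_class.upper()}")


@dataclass
class StimulusRegion:
    """A stimulated node set with a train of onset times."""
    nodes: np.ndarray
    onsets: np.ndarray                     # ms
    amplitude: float = STIM_TISSUE_AMP     # uA/cm^2 (== pA/pF)
    duration: float = STIM_TISSUE_MS       # ms

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=np.int64)
        self.onsets = np.sort(np.asarray(self.onsets, dtype=float))
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")


@dataclass
class SpaceTimeVm:
    """Membrane potential over (time, node) plus activation bookkeeping."""
    vm: np.ndarray              # (n_rec, n) at the recording stride
    times: np.ndarray           # ms
    geometry: Geometry
    act_times: np.ndarray       # (n, K) upstroke times (-20 mV crossings)
    act_counts: np.ndarray      # (n,)
    dvdt_argt: np.ndarray       # per-node time of max dVm/dt in the window
    dvdt_max: np.ndarray
    meta: dict = field(default_factory=dict)

    def upstrokes(self, node: int) -> np.ndarray:
        return self.act_times[node, :self.act_counts[node]]


def _initial_states(geometry: Geometry, variant, init: str,
                    prepace_pcl: float, dt: float) -> np.ndarray:
    y = np.empty((geometry.n, 19), dtype=np.float64)
    if init == "resting":
        y[:] = default_state().as_vector()[None, :]
        return y
    if init != "prepaced":
        raise ValueError(f"unknown init mode {init!r}")
    for code, cls in _CODE_CLASSES.items():
        mask = geometry.class_map == code
        if mask.any():
            vec = np.array(_prepaced_vector(cls, get_variant(variant).label,
                                            float(prepace_pcl), 100, float(dt)))
            y[mask, :] = vec[None, :]
    return y


def simulate(geometry: Geometry, params: TissueParams, stimuli, duration: float,
             variant="WT", rec_dt: float = 1.0, init: str = "prepaced",
             prepace_pcl: float = 1000.0, reaction: bool = True,
             act_window: tuple | None = None, max_upstrokes: int = 64,
             initial_states: np.ndarray | None = None,
             probe_node: int | None = None, snapshot_dt: float | None = None):
    """Run the monodomain model; 1D and 2D dispatch on the geometry.

    ``stimuli`` is a list of at most two :class:`StimulusRegion` (e.g. an S1
    train and an S2).  ``act_window`` (ms) bounds the per-node max-dVm/dt
    search (defaults to the whole run).  For 2D runs, ``probe_node`` records
    a 1-ms point trace and ``snapshot_dt`` coarse full-field snapshots; the
    full field history is not stored.
    """
    num, ok = check_stability(params)
    if not ok:
        raise StabilityError(
            f"D*dt/dx^2 = {num:.4f} >= 1/2; refusing to run")
    variant = get_variant(variant)
    if abs(params.dx - geometry.dx) > 1e-12:
        raise ValueError("params.dx disagrees with geometry.dx")
    dt = params.dt
    n_steps = int(round(duration / dt))
    lut = build_variant_lut(variant, dt)
    ct = [CellTypeParams.for_class(_CODE_CLASSES[c])
          for c in range(3)]
    gto = np.array([ct[c].g_to for c in geometry.class_map])
    gks = np.array([ct[c].g_ks for c in geometry.class_map])
    endo_flags = (geometry.class_map == CLASS_CODES["ENDO"])

    stimuli = list(stimuli)
    if len(stimuli) > 2:
        raise ValueError("at most two stimulus regions are supported")
    while len(stimuli) < 2:
        stimuli.append(StimulusRegion(np.empty(0, dtype=np.int64),
                                      np.empty(0)))
    for s in stimuli:
        if len(s.nodes) and (s.nodes.min() < 0 or s.nodes.max() >= geometry.n):
            raise ValueError("stimulus nodes outside the geometry")
    amp = stimuli[0].amplitude if len(stimuli[0].nodes) else STIM_TISSUE_AMP
    dur_steps = int(round((stimuli[0].duration if len(stimuli[0].nodes)
                           else STIM_TISSUE_MS) / dt))
    s1_steps = np.round(stimuli[0].onsets / dt).astype(np.int64)
    s2_steps = np.round(stimuli[1].onsets / dt).astype(np.int64)

    if initial_states is not None:
        y = np.array(initial_states, dtype=np.float64, copy=True)
    else:
        y = _initial_states(geometry, variant, init, prepace_pcl, dt)

    if act_window is None:
        win = (0, n_steps)
    else:
        win = (int(round(act_window[0] / dt)), int(round(act_window[1] / dt)))
    act_times = np.zeros((geometry.n, max_upstrokes), dtype=np.float64)
    act_counts = np.zeros(geometry.n, dtype=np.int64)
    dvdt_max = np.full(geometry.n, -np.inf)
    dvdt_argt = np.full(geometry.n, np.nan)

    rec_stride = max(1, int(round(rec_dt / dt)))
    if geometry.ny == 1:
        n_rec = (n_steps - 1) // rec_stride + 1
        rec = np.empty((n_rec, geometry.n))
        bad = _kernels.run_cable(
            y, lut, endo_flags, gto, gks, variant.csf, params.d_coeff,
            params.dx, dt, n_steps, stimuli[0].nodes, s1_steps,
            stimuli[1].nodes, s2_steps, dur_steps, amp, rec_stride, rec,
            ACT_THRESHOLD_MV, act_times, act_counts, win[0], win[1],
            dvdt_max, dvdt_argt, reaction)
        times = np.arange(rec.shape[0]) * dt * rec_stride
        probe_rec = None
        snaps = snap_times = None
    else:
        probe_idx = probe_node if probe_node is not None else geometry.n // 2
        probe_stride = max(1, int(round(1.0 / dt)))
        probe_rec = np.empty((n_steps - 1) // probe_stride + 1)
        if snapshot_dt:
            snap_stride = max(1, int(round(snapshot_dt / dt)))
            snaps = np.empty(((n_steps - 1) // snap_stride + 1, geometry.n))
        else:
            snap_stride = n_steps + 1
            snaps = np.empty((0, geometry.n))
        bad = _kernels.run_sheet(
            y, lut, endo_flags, gto, gks, variant.csf, params.d_coeff,
            params.dx, dt, n_steps, geometry.ny, geometry.nx,
            stimuli[0].nodes, s1_steps, stimuli[1].nodes, s2_steps,
            dur_steps, amp, probe_idx, probe_stride, probe_rec,
            snap_stride, snaps, ACT_THRESHOLD_MV, act_times, act_counts)
        rec = snaps
        times = (np.arange(snaps.shape[0]) * dt * snap_stride
                 if snaps.shape[0] else np.empty(0))
        snap_times = times
    if bad >= 0:
        node = int(np.argmin(np.isfinite(y[:, 0])))
        raise FloatingPointError(
            f"non-finite vm at t = {bad * dt:.2f} ms (node {node})")

    st = SpaceTimeVm(rec, times, geometry, act_times, act_counts,
                     dvdt_argt, dvdt_max,
                     meta={"variant": variant.label, "params": params,
                           "duration": duration, "final_states": y,
                           "stim_onsets": stimuli[0].onsets,
                           "s2_onsets": stimuli[1].onsets})
    if probe_rec is not None:
        st.meta["probe_trace"] = probe_rec
        st.meta["probe_dt"] = 1.0
        st.meta["probe_node"] = probe_idx
    return st


# ---------------------------------------------------------------------------
# 1D measurements
# ---------------------------------------------------------------------------

def end_stimulus(geometry: Geometry, onsets, width_mm: float = 0.45,
                 amplitude: float = STIM_TISSUE_AMP,
                 duration: float = STIM_TISSUE_MS) -> StimulusRegion:
    """Stimulus applied to a strip at the x=0 (ENDO) end of a 1D cable."""
    n_nodes = max(1, int(round(width_mm / geometry.dx)))
    return StimulusRegion(np.arange(n_nodes), np.asarray(onsets, float),
                          amplitude, duration)


def measure_cv(spacetime: SpaceTimeVm, x_center: float | None = None,
               delta_x: float | None = None) -> float:
    """Conduction velocity CV = 2 dx_probe / dt_probe around mid-cable.

    Activation time per probe is the time of maximum dVm/dt (tracked at full
    resolution during the run).  Default probes sit at 1/4 and 3/4 of the
    cable, away from the boundaries.
    """
    geo = spacetime.geometry
    if geo.ny != 1:
        raise ValueError("measure_cv expects a 1D run")
    length = geo.length_mm
    if x_center is None:
        x_center = length / 2.0
    if delta_x is None:
        delta_x = length / 4.0
    pos = geo.positions_mm()
    i1 = int(np.argmin(np.abs(pos - (x_center - delta_x))))
    i2 = int(np.argmin(np.abs(pos - (x_center + delta_x))))
    t1, t2 = spacetime.dvdt_argt[i1], spacetime.dvdt_argt[i2]
    if not (np.isfinite(t1) and np.isfinite(t2)) or t2 == t1:
        raise ValueError("no activation detected at one or both CV probes")
    return float((pos[i2] - pos[i1]) / (t2 - t1))


def classify_conduction(spacetime: SpaceTimeVm, stim_times,
                        distal_node: int | None = None,
                        n_eval: int = 5) -> str:
    """1:1 / 2:1_block / no_capture from distal propagated APs.

    Counts, over the last ``n_eval`` stimuli, how many are followed by a
    distal upstroke within one cycle.
    """
    stim_times = np.asarray(stim_times, float)
    if len(stim_times) < 4:
        raise ValueError("need at least 4 stimuli to classify conduction")
    geo = spacetime.geometry
    if distal_node is None:
        distal_node = geo.n - 5
    pcl = np.median(np.diff(stim_times)) if len(stim_times) > 1 else np.inf
    ups = spacetime.upstrokes(distal_node)
    hits = 0
    for t0 in stim_times[-n_eval:]:
        if np.any((ups > t0) & (ups <= t0 + pcl)):
            hits += 1
    ratio = hits / n_eval
    if ratio >= 0.9:
        return "1:1"
    if ratio == 0.0:
        return "no_capture"
    if 0.3 <= ratio <= 0.7:
        return "2:1_block"
    return "partial_block"


def run_s1_train(variant, pcl: float, n_beats: int = 10,
                 geometry: Geometry | None = None,
                 params: TissueParams | None = None,
                 tail_ms: float = 500.0, rec_dt: float = 1.0,
                 act_window: tuple | None = None) -> SpaceTimeVm:
    """Apply an S1 train to the ENDO end of a (transmural) cable."""
    if geometry is None:
        geometry = build_transmural_cable()
    if params is None:
        params = TissueParams(dx=geometry.dx)
    onsets = np.arange(n_beats) * pcl
    stim = end_stimulus(geometry, onsets)
    duration = (n_beats - 1) * pcl + tail_ms
    if act_window is None:
        act_window = (onsets[-1], duration)
    return simulate(geometry, params, [stim], duration, variant=variant,
                    rec_dt=rec_dt, act_window=act_window)


def find_mpcl(variant, start: float = 400.0, stop: float = 300.0,
              step: float = 1.0, n_beats: int = 10,
              geometry: Geometry | None = None,
              params: TissueParams | None = None) -> float | None:
    """Largest PCL showing 2:1 distal block on the transmural cable.

    Descending scan from ``start`` in 1-ms steps; each trial applies a
    10-beat S1 train and classifies distal capture over the last 5 beats.
    Returns None if no 2:1 block is found above ``stop`` (below-range).
    """
    if geometry is None:
        geometry = build_transmural_cable()
    if params is None:
        params = TissueParams(dx=geometry.dx)
    pcl = start
    while pcl >= stop:
        onsets = np.arange(n_beats) * pcl
        st = run_s1_train(variant, pcl, n_beats, geometry, params,
                          tail_ms=200.0)
        label = classify_conduction(st, onsets)
        if label == "2:1_block":
            return pcl
        pcl -= step
    return None


@dataclass(frozen=True)
class FocalEvent:
    kind: str       # "subthreshold_dad" or "pvc"
    node: int
    time: float     # ms
    amplitude: float  # mV (deflection prominence or upstroke peak)


def detect_focal_activity(spacetime: SpaceTimeVm, stim: StimulusRegion,
                          window: tuple | None = None,
                          cv_tol_ms: float = 30.0,
                          prominence: float = 1.0) -> list[FocalEvent]:
    """Ectopic activity in a homogeneous cable run.

    Suprathreshold upstrokes not attributable to a wave propagating from the
    stimulus (arrival-time mismatch beyond ``cv_tol_ms``) are classified as
    PVCs.  Sub-threshold depolarizations (diastolic vm deflections with the
    given prominence, below the activation threshold) are reported as
    subthreshold DADs.  ``window`` restricts the search (ms).
    """
    geo = spacetime.geometry
    pos = geo.positions_mm()
    stim_x = pos[stim.nodes].mean()
    # empirical propagation speed from the first beat's activation bookkeeping
    far = int(np.argmax(np.abs(pos - stim_x)))
    ups_far = spacetime.upstrokes(far)
    if len(ups_far) == 0:
        raise ValueError("stimulated wave never reached the cable end")
    cv = abs(pos[far] - stim_x) / (ups_far[0] - stim.onsets[0])
    t_lo, t_hi = window if window else (0.0, np.inf)

    events: list[FocalEvent] = []
    for node in range(geo.n):
        expected = stim.onsets + abs(pos[node] - stim_x) / cv
        for t in spacetime.upstrokes(node):
            if not (t_lo <= t <= t_hi):
                continue
            if np.min(np.abs(expected - t)) > cv_tol_ms:
                events.append(FocalEvent("pvc", node, float(t), 0.0))
    # subthreshold deflections on the recorded traces
    dt_rec = spacetime.times[1] - spacetime.times[0]
    sel = (spacetime.times >= t_lo) & (spacetime.times <= t_hi)
    tsel = spacetime.times[sel]
    for node in range(geo.n):
        vm = spacetime.vm[sel, node]
        pk, props = find_peaks(vm, prominence=prominence)
        for i, p in enumerate(pk):
            if vm[p] >= ACT_THRESHOLD_MV - 20.0:   # AP peaks, not DADs
                continue
            t = float(tsel[p])
            # skip deflections explained by wave arrival (upstroke foot)
            expected = stim.onsets + abs(pos[node] - stim_x) / cv
            if np.min(np.abs(expected - t)) < cv_tol_ms:
                continue
            events.append(FocalEvent("subthreshold_dad", node, t,
                                     float(props["prominences"][i])))
    events.sort(key=lambda e: e.time)
    return events


# ---------------------------------------------------------------------------
# 2D protocols
# ---------------------------------------------------------------------------

def _edge_strip_nodes(geometry: Geometry, n_cols: int,
                      lateral_fraction: float = 0.5,
                      align: str = "edge") -> np.ndarray:
    """Node indices of an ENDO-edge strip over a fraction of the lateral
    extent (transmural sheet: columns 0..n_cols-1).

    ``align='edge'`` starts the strip at one lateral border, which preserves
    the full reentry path length on the other side in scaled-down sheets;
    ``align='center'`` centres it as in the full-size protocol.
    """
    ny, nx = geometry.ny, geometry.nx
    span = int(round(ny * lateral_fraction))
    if align == "edge":
        rows = np.arange(span)
    elif align == "center":
        rows = np.arange((ny - span) // 2, (ny + span) // 2)
    else:
        raise ValueError(f"unknown strip alignment {align!r}")
    cols = np.arange(n_cols)
    return (rows[:, None] * nx + cols[None, :]).ravel()


def vulnerability_s1s1_2d(variant, s1s1: float,
                          lateral_mm: float = 50.0,
                          params: TissueParams | None = None,
                          observe_ms: float = 800.0,
                          geometry: Geometry | None = None) -> dict:
    """Two-stimulus (S1-S1) vulnerability test on a transmural sheet.

    Classifies the second wave as ``bidirectional`` (full transmural
    conduction), ``unidirectional_block_reentry`` (partial/total transmural
    block with activity persisting after the direct wave would have exited)
    or ``bilateral_block``.
    """
    if geometry is None:
        geometry = build_transmural_sheet(lateral_mm=lateral_mm)
    if params is None:
        params = TissueParams(dx=geometry.dx)
    strip = _edge_strip_nodes(geometry, n_cols=3)
    stim = StimulusRegion(strip, np.array([0.0, s1s1]))
    duration = s1s1 + observe_ms
    st = simulate(geometry, params, [stim], duration, variant=variant,
                  rec_dt=duration, max_upstrokes=16)

    nx, ny = geometry.nx, geometry.ny
    epi_edge = np.arange(ny) * nx + (nx - 1)
    # did the second wave cross to the EPI edge?
    crossed = 0
    for node in epi_edge:
        ups = st.upstrokes(node)
        if np.any((ups > s1s1) & (ups <= s1s1 + 350.0)):
            crossed += 1
    frac_crossed = crossed / ny
    # exit time of the second direct wave: transmural depth / plane CV
    t_exit = s1s1 + 350.0
    late = 0
    for node in range(geometry.n):
        ups = st.upstrokes(node)
        late += int(np.any(ups > t_exit))
    late_frac = late / geometry.n
    if frac_crossed > 0.9 and late_frac < 0.01:
        outcome = "bidirectional"
    elif late_frac >= 0.01:
        outcome = "unidirectional_block_reentry"
    elif frac_crossed < 0.1:
        outcome = "bilateral_block"
    else:
        outcome = "partial_block"
    return {"outcome": outcome, "frac_epi_crossed": frac_crossed,
            "late_activity_fraction": late_frac, "spacetime": st}


def induce_spiral_s1s2_2d(variant="WT", size_mm: float = 100.0,
                          params: TissueParams | None = None,
                          duration: float = 3000.0,
                          cell_class: str = "MCELL",
                          prepace_pcl: float = 1000.0,
                          s2_offset_ms: float = 0.0) -> SpaceTimeVm:
    """Cross-field S1-S2 spiral induction on a homogeneous sheet.

    S1: plane wave from the left edge.  S2: once the wave has passed over
    the first half of the domain - its repolarization tail clearing the
    midline - the upper-left quarter is stimulated.  ``s2_offset_ms`` can
    advance or delay the S2 within the vulnerable window where tissue just
    beyond the quarter is still refractory, so the break can curl.  The
    centre-point trace (1-ms sampling) is stored in the result's metadata
    for spectral analysis.
    """
    geometry = build_homogeneous_sheet(cell_class, size_mm,
                                       dx=DX_MCELL_2D_MM)
    if params is None:
        params = TissueParams(d_coeff=D_MCELL_2D, dx=geometry.dx)
    ny, nx = geometry.ny, geometry.nx
    # S1 strip: 3 leftmost columns, full height
    s1_nodes = (np.arange(ny)[:, None] * nx + np.arange(3)[None, :]).ravel()

    # phase 1: find when the S1 wave has passed over the first half of the
    # domain, i.e. when its repolarization tail clears the midline (the S2
    # region must be excitable while the tissue ahead is still refractory)
    probe_mid = (ny // 2) * nx + nx // 2
    st1 = simulate(geometry, params, [StimulusRegion(s1_nodes, [0.0])],
                   duration=800.0, variant=variant, init="prepaced",
                   prepace_pcl=prepace_pcl, probe_node=probe_mid,
                   max_upstrokes=4)
    mid_ups = st1.upstrokes(probe_mid)
    if len(mid_ups) == 0:
        raise ValueError("S1 wave failed to reach the domain midline")
    trace = st1.meta["probe_trace"]
    # search for the tail a safe margin past the upstroke sample
    i_up = int(mid_ups[0] / st1.meta["probe_dt"]) + 10
    repol = np.nonzero(trace[i_up:] < -70.0)[0]
    if len(repol) == 0:
        raise ValueError("midline failed to repolarize during phase 1")
    t_s2 = float((i_up + repol[0]) * st1.meta["probe_dt"]) + s2_offset_ms

    # phase 2: full run with the S2 applied to the upper-left quarter
    q_rows = np.arange(ny // 2)
    q_cols = np.arange(nx // 2)
    s2_nodes = (q_rows[:, None] * nx + q_cols[None, :]).ravel()
    st = simulate(geometry, params,
                  [StimulusRegion(s1_nodes, [0.0]),
                   StimulusRegion(s2_nodes, [t_s2])],
                  duration=duration, variant=variant, init="prepaced",
                  prepace_pcl=prepace_pcl, probe_node=probe_mid,
                  max_upstrokes=64)
    st.meta["t_s2"] = t_s2
    return st


def dominant_frequency(signal: np.ndarray, dt_ms: float,
                       transient_ms: float = 1000.0) -> float:
    """Fundamental frequency (Hz) of a vm recording after a transient.

    Argmax of the periodogram above 0.5 Hz; the leading ``transient_ms`` is
    discarded.
    """
    signal = np.asarray(signal, float)
    i0 = int(round(transient_ms / dt_ms))
    seg = signal[i0:]
    if len(seg) < 16:
        raise ValueError("signal too short for spectral analysis")
    fs = 1000.0 / dt_ms
    freqs, power = periodogram(seg - seg.mean(), fs=fs)
    mask = freqs > 0.5
    return float(freqs[mask][np.argmax(power[mask])])
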