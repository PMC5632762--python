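"""TP06 human ventricular myocyte model with a pluggable variant I_CaL.

The model covers the endocardial (ENDO), midmyocardial (MCELL) and epicardial
(EPI) phenotypes, which differ in the transient-outward (Ito) and slow
delayed-rectifier (IKs) conductances and in the kinetics of the Ito
inactivation gate ``s``.  The sarcoplasmic-reticulum calcium efflux combines a
calcium-induced release flux (gated by the subspace calcium and regulated by
SR load) with a passive leak.  The L-type calcium current is parameterised by
an :class:`ICaLVariantParams` record so CACNA1C variant kinetics can be
swapped in without touching the rest of the model.

This module provides the readable reference implementation: a plain-Python
right-hand side (:func:`ionic_rhs`), single-step integrators and the
pre-pacing entry point.  The production integrators live in
``lqt8sim._kernels`` and are cross-checked against this path in the tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from . import _kernels
from .constants import (CELL_CLASSES, DT_MS, GATE_NAMES, N_STATE, STATE_NAMES,
                        STIM_CELL_AMP, STIM_CELL_MS, TP06_INITIAL_STATE,
                        tp06_constants, variant_table)

_C = tp06_constants()
_FRT = _C["F"] / (_C["R"] * _C["T"])
_RTF = 1.0 / _FRT

CURRENT_NAMES = ("ina", "ical", "ito", "ikr", "iks", "ik1", "incx", "inak",
                 "ipca", "ipk", "ibna", "ibca", "irel", "iup", "ileak",
                 "ixfer")


@dataclass(frozen=True)
class ICaLVariantParams:
    """Six-parameter description of a variant L-type calcium channel.

    ``csf`` scales the maximal conductance, ``va_half``/``sa`` set the
    steady-state activation sigmoid, ``vina_half``/``sina`` the steady-state
    voltage-inactivation sigmoid, and ``tcsf`` scales the voltage-inactivation
    time constant.  All other I_CaL kinetics are the TP06 originals.
    """
    label: str
    csf: float = 1.0
    va_half: float = -8.0
    sa: float = 7.5
    vina_half: float = -20.0
    sina: float = 7.0
    tcsf: float = 1.0

    def __post_init__(self):
        for name in ("csf", "sa", "sina", "tcsf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.label}: {name} must be strictly positive")

    @classmethod
    def from_table(cls, label: str) -> "ICaLVariantParams":
        rec = variant_table()[label]
        return cls(label=label, csf=rec["csf"], va_half=rec["va_half"],
                   sa=rec["sa"], vina_half=rec["vina_half"],
                   sina=rec["sina"], tcsf=rec["tcsf"])


def get_variant(variant: "str | ICaLVariantParams") -> ICaLVariantParams:
    if isinstance(variant, ICaLVariantParams):
        return variant
    return ICaLVariantParams.from_table(variant)


@dataclass(frozen=True)
class CellTypeParams:
    """Cell-class parameters: only g_to, g_Ks and the ``s``-gate kinetics
    differ between ENDO, MCELL and EPI."""
    cell_class: str
    g_to: float
    g_ks: float
    endo_s_gate: bool

    def __post_init__(self):
        if self.g_to < 0 or self.g_ks < 0:
            raise ValueError("conductances must be non-negative")

    @classmethod
    def for_class(cls, cell_class: str) -> "CellTypeParams":
        cc = cell_class.upper()
        if cc not in CELL_CLASSES:
            raise ValueError(f"unknown cell class {cell_class!r}")
        key = {"ENDO": "endo", "MCELL": "m", "EPI": "epi"}[cc]
        return cls(cell_class=cc, g_to=_C[f"g_to_{key}"],
                   g_ks=_C[f"g_Ks_{key}"], endo_s_gate=(cc == "ENDO"))


@dataclass
class CellState:
    """Full TP06 state: vm, 12 voltage/calcium gates, the SR release recovery
    gate and 5 concentrations."""
    vm: float
    m: float; h: float; j: float
    xr1: float; xr2: float; xs: float
    r: float; s: float
    d: float; f: float; f2: float; fcass: float
    rbar: float
    nai: float; ki: float
    cai: float; cass: float; casr: float

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "CellState":
        return cls(**{name: float(y[k]) for k, name in enumerate(STATE_NAMES)})

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=np.float64)

    def validate(self) -> None:
        for name in STATE_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"non-finite state field {name!r}: {value}")
        for name in GATE_NAMES:
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"gate {name!r} out of [0,1]: {value}")
        for name in ("nai", "ki", "cai", "cass", "casr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"concentration {name!r} must be positive")


@dataclass(frozen=True)
class CurrentsSnapshot:
    """Membrane currents (pA/pF) and SR fluxes (mM/ms) at one instant."""
    ina: float; ical: float; ito: float; ikr: float; iks: float; ik1: float
    incx: float; inak: float; ipca: float; ipk: float; ibna: float; ibca: float
    irel: float; iup: float; ileak: float; ixfer: float

    def total_membrane(self) -> float:
        return (self.ina + self.ical + self.ito + self.ikr + self.iks
                + self.ik1 + self.incx + self.inak + self.ipca + self.ipk
                + self.ibna + self.ibca)


def default_state() -> CellState:
    """The published TP06 initial conditions (before re-equilibration)."""
    return CellState(**TP06_INITIAL_STATE)


# ---------------------------------------------------------------------------
# Direct right-hand side (reference path)
# ---------------------------------------------------------------------------

def ical_current(state: CellState, variant: "str | ICaLVariantParams") -> float:
    """Instantaneous I_CaL (pA/pF) at the state's gate values.

    Non-linear GHK-type driving force on the subspace calcium; conductance
    scaled by the variant ``csf``.  Gates are read, not advanced.
    """
    variant = get_variant(variant)
    state.validate()
    v = state.vm
    vm15 = v - 15.0
    if abs(vm15) < 1e-9:
        a = _C["g_CaL"] * 2.0 * _C["F"]
    else:
        e2v = np.exp(2.0 * vm15 * _FRT)
        a = _C["g_CaL"] * 4.0 * vm15 * _C["F"] * _FRT * 1.0 / (e2v - 1.0)
    e2v = np.exp(2.0 * vm15 * _FRT)
    return (variant.csf * a * state.d * state.f * state.f2 * state.fcass
            * (0.25 * state.cass * e2v - _C["Ca_o"]))


def ionic_rhs(state: CellState, ct: CellTypeParams,
              variant: "str | ICaLVariantParams", i_stim: float = 0.0,
              current_scales: dict | None = None):
    """Time derivatives of the full state plus a consistent currents snapshot.

    ``i_stim`` is in pA/pF (numerically equal to uA/cm^2 at Cm = 1 uF/cm^2);
    a depolarising stimulus is negative.  ``current_scales`` optionally scales
    named currents (e.g. ``{"incx": 0.0}``) for knockout experiments.
    """
    variant = get_variant(variant)
    state.validate()
    v = state.vm
    nai, ki, cai, cass, casr = state.nai, state.ki, state.cai, state.cass, state.casr

    ena = _RTF * np.log(_C["Na_o"] / nai)
    ek = _RTF * np.log(_C["K_o"] / ki)
    eks = _RTF * np.log((_C["K_o"] + _C["P_kna"] * _C["Na_o"])
                        / (ki + _C["P_kna"] * nai))
    eca = 0.5 * _RTF * np.log(_C["Ca_o"] / cai)

    ina = _C["g_Na"] * state.m ** 3 * state.h * state.j * (v - ena)
    ical = ical_current(state, variant)
    ito = ct.g_to * state.r * state.s * (v - ek)
    ikr = _C["g_Kr"] * np.sqrt(_C["K_o"] / 5.4) * state.xr1 * state.xr2 * (v - ek)
    iks = ct.g_ks * state.xs ** 2 * (v - eks)
    vek = v - ek
    ak1 = 0.1 / (1.0 + np.exp(0.06 * (vek - 200.0)))
    bk1 = (3.0 * np.exp(0.0002 * (vek + 100.0)) + np.exp(0.1 * (vek - 10.0))) \
        / (1.0 + np.exp(-0.5 * vek))
    ik1 = _C["g_K1"] * np.sqrt(_C["K_o"] / 5.4) * ak1 / (ak1 + bk1) * vek
    e1 = np.exp(_C["gamma_ncx"] * v * _FRT)
    e2 = np.exp((_C["gamma_ncx"] - 1.0) * v * _FRT)
    incx = _C["K_NaCa"] * (e1 * nai ** 3 * _C["Ca_o"]
                           - e2 * _C["Na_o"] ** 3 * cai * _C["alpha_ncx"]) \
        / ((_C["Km_Nai"] ** 3 + _C["Na_o"] ** 3) * (_C["Km_Ca"] + _C["Ca_o"])
           * (1.0 + _C["K_sat"] * e2))
    inak = _C["P_NaK"] * _C["K_o"] * nai \
        / ((_C["K_o"] + _C["K_mk"]) * (nai + _C["K_mNa"])) \
        / (1.0 + 0.1245 * np.exp(-0.1 * v * _FRT) + 0.0353 * np.exp(-v * _FRT))
    ipca = _C["g_pCa"] * cai / (cai + _C["K_pCa"])
    ipk = _C["g_pK"] * vek / (1.0 + np.exp((25.0 - v) / 5.98))
    ibna = _C["g_bna"] * (v - ena)
    ibca = _C["g_bca"] * (v - eca)

    # SR efflux: calcium-induced release plus an RyR-pathway leak into the
    # subspace, with a threshold overload-release term (spontaneous release
    # once the SR load exceeds K_over).
    kcasr = _C["max_sr"] - (_C["max_sr"] - _C["min_sr"]) \
        / (1.0 + (_C["EC_sr"] / casr) ** 2)
    sens = 1.0 + _C["S_over"] * 0.5 * (1.0 + np.tanh(
        (casr - _C["K_over"]) / (2.0 * _C["w_over"])))
    k1 = _C["k1_prime"] / kcasr * sens
    k2 = _C["k2_prime"] * kcasr
    o_gate = k1 * cass ** 2 * state.rbar / (_C["k3"] + k1 * cass ** 2)
    irel = _C["V_rel"] * o_gate * (casr - cass)
    ileak = _C["V_leak"] * (casr - cass)
    iup = _C["Vmax_up"] / (1.0 + (_C["K_up"] / cai) ** 2)
    ixfer = _C["V_xfer"] * (cass - cai)

    currents = dict(ina=ina, ical=ical, ito=ito, ikr=ikr, iks=iks, ik1=ik1,
                    incx=incx, inak=inak, ipca=ipca, ipk=ipk, ibna=ibna,
                    ibca=ibca, irel=irel, iup=iup, ileak=ileak, ixfer=ixfer)
    if current_scales:
        unknown = set(current_scales) - set(CURRENT_NAMES)
        if unknown:
            raise ValueError(f"unknown current names {sorted(unknown)}")
        for name, scale in current_scales.items():
            currents[name] = currents[name] * scale
    for name, value in currents.items():
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite current {name!r}: {value}")
    snap = CurrentsSnapshot(**currents)

    rates = _kernels.gate_curves(v, variant.va_half, variant.sa,
                                 variant.vina_half, variant.sina, variant.tcsf)
    s_key = "s_endo" if ct.endo_s_gate else "s_epi"
    dy = np.zeros(N_STATE)
    dy[0] = -(snap.total_membrane() + i_stim)
    for k, name in enumerate(STATE_NAMES[1:12], start=1):
        key = s_key if name == "s" else name
        inf, tau = rates[key]
        dy[k] = (float(inf) - getattr(state, name)) / float(tau)
    cssq = (cass / 0.05) ** 2
    fcass_inf = 0.6 / (1.0 + cssq) + 0.4
    tau_fcass = 80.0 / (1.0 + cssq) + 2.0
    dy[12] = (fcass_inf - state.fcass) / tau_fcass
    dy[13] = -k2 * cass * state.rbar + _C["k4"] * (1.0 - state.rbar)

    cm, vc, f = _C["Cm"], _C["V_c"], _C["F"]
    bufc = 1.0 / (1.0 + _C["Buf_c"] * _C["K_buf_c"] / (cai + _C["K_buf_c"]) ** 2)
    bufsr = 1.0 / (1.0 + _C["Buf_sr"] * _C["K_buf_sr"] / (casr + _C["K_buf_sr"]) ** 2)
    bufss = 1.0 / (1.0 + _C["Buf_ss"] * _C["K_buf_ss"] / (cass + _C["K_buf_ss"]) ** 2)
    dy[14] = -(snap.ina + snap.ibna + 3.0 * snap.inak + 3.0 * snap.incx) * cm / (vc * f)
    dy[15] = -(snap.ik1 + snap.ito + snap.ikr + snap.iks + snap.ipk + i_stim
               - 2.0 * snap.inak) * cm / (vc * f)
    dy[16] = bufc * (-(snap.ibca + snap.ipca - 2.0 * snap.incx) * cm / (2.0 * vc * f)
                     - snap.iup * _C["V_sr"] / vc + snap.ixfer)
    dy[17] = bufss * (-snap.ical * cm / (2.0 * _C["V_ss"] * f)
                      + (snap.irel + snap.ileak) * _C["V_sr"] / _C["V_ss"]
                      - snap.ixfer * vc / _C["V_ss"])
    dy[18] = bufsr * (snap.iup - snap.irel - snap.ileak)
    return dy, snap


def step(state: CellState, ct: CellTypeParams, variant: "str | ICaLVariantParams",
         i_stim: float = 0.0, dt: float = DT_MS,
         method: str = "rush_larsen") -> CellState:
    """Advance one step: forward Euler for vm and concentrations; gates by the
    exponential (Rush-Larsen) update or, optionally, plain forward Euler."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if method not in ("rush_larsen", "euler"):
        raise ValueError(f"unknown integration method {method!r}")
    variant = get_variant(variant)
    dy, _ = ionic_rhs(state, ct, variant, i_stim)
    y = state.as_vector()
    y_new = y + dt * dy
    if method == "rush_larsen":
        rates = _kernels.gate_curves(y[0], variant.va_half, variant.sa,
                                     variant.vina_half, variant.sina,
                                     variant.tcsf)
        s_key = "s_endo" if ct.endo_s_gate else "s_epi"
        for k, name in enumerate(STATE_NAMES[1:12], start=1):
            key = s_key if name == "s" else name
            inf, tau = rates[key]
            y_new[k] = float(inf) + (y[k] - float(inf)) * np.exp(-dt / float(tau))
        cssq = (y[17] / 0.05) ** 2
        fc_inf = 0.6 / (1.0 + cssq) + 0.4
        tau_fc = 80.0 / (1.0 + cssq) + 2.0
        y_new[12] = fc_inf + (y[12] - fc_inf) * np.exp(-dt / tau_fc)
        kcasr = _C["max_sr"] - (_C["max_sr"] - _C["min_sr"]) \
            / (1.0 + (_C["EC_sr"] / y[18]) ** 2)
        a = _C["k2_prime"] * kcasr * y[17] + _C["k4"]
        rbar_inf = _C["k4"] / a
        y_new[13] = rbar_inf + (y[13] - rbar_inf) * np.exp(-a * dt)
    else:
        # plain Euler can overshoot [0,1] for stiff gates; clip to the
        # physical range (only relevant far from the stability limit)
        y_new[1:14] = np.clip(y_new[1:14], 0.0, 1.0)
    return CellState.from_vector(y_new)


# ---------------------------------------------------------------------------
# Fast pacing + pre-paced initial states (kernel-backed)
# ---------------------------------------------------------------------------

def build_variant_lut(variant: "str | ICaLVariantParams",
                      dt: float = DT_MS) -> np.ndarray:
    variant = get_variant(variant)
    return _cached_lut(variant.va_half, variant.sa, variant.vina_half,
                       variant.sina, variant.tcsf, dt)


@lru_cache(maxsize=64)
def _cached_lut(va_half, sa, vina_half, sina, tcsf, dt):
    return _kernels.build_lut(dt, va_half, sa, vina_half, sina, tcsf)


def _pace_vector(y: np.ndarray, cell_class: str,
                 variant: ICaLVariantParams, pcl: float, n_beats: int,
                 dt: float, stim_amp: float, stim_ms: float,
                 rec_stride: int = 0, rec_start_ms: float = 0.0):
    """Run a pacing train on a state vector in place; optionally record."""
    ct = CellTypeParams.for_class(cell_class)
    lut = build_variant_lut(variant, dt)
    steps_per_beat = int(round(pcl / dt))
    n_steps = steps_per_beat * n_beats
    stim_steps = (np.arange(n_beats) * steps_per_beat).astype(np.int64)
    stim_dur = int(round(stim_ms / dt))
    if rec_stride > 0:
        rec_start = int(round(rec_start_ms / dt))
        n_rec = (n_steps - rec_start + rec_stride - 1) // rec_stride
        rec = np.empty((n_rec, 6), dtype=np.float64)
    else:
        rec_start = 0
        rec = np.empty((0, 6), dtype=np.float64)
    y2 = y.reshape(1, 19)
    bad = _kernels.run_cell(y2, lut, ct.endo_s_gate, ct.g_to, ct.g_ks,
                            variant.csf, dt, n_steps, stim_steps, stim_dur,
                            stim_amp, max(rec_stride, 1), rec_start, rec)
    if bad >= 0:
        raise FloatingPointError(
            f"non-finite vm at t = {bad * dt:.2f} ms "
            f"({cell_class}/{variant.label}, PCL {pcl} ms)")
    return rec


@lru_cache(maxsize=256)
def _prepaced_vector(cell_class: str, label: str, pcl: float,
                     n_beats: int, dt: float) -> tuple:
    variant = get_variant(label)
    y = default_state().as_vector()
    _pace_vector(y, cell_class, variant, pcl, n_beats, dt,
                 STIM_CELL_AMP, STIM_CELL_MS)
    return tuple(y)


def initial_state(cell_class: str, variant: "str | ICaLVariantParams" = "WT",
                  pcl: float = 1000.0, n_beats: int = 100,
                  dt: float = DT_MS) -> CellState:
    """Pre-paced steady state: ``n_beats`` conditioning beats at ``pcl``.

    This is the working initial condition for all single-cell measurements;
    100 beats at PCL 1,000 ms by default.
    """
    variant = get_variant(variant)
    y = np.array(_prepaced_vector(cell_class.upper(), variant.label,
                                  float(pcl), int(n_beats), float(dt)))
    state = CellState.from_vector(y)
    state.validate()
    return state


def resting_potential(cell_class: str,
                      variant: "str | ICaLVariantParams" = "WT",
                      pcl: float = 1000.0, n_beats: int = 100,
                      dt: float = DT_MS) -> float:
    """Minimum diastolic vm over the final pre-pacing cycle (mV)."""
    variant = get_variant(variant)
    y = np.array(_prepaced_vector(cell_class.upper(), variant.label,
                                  float(pcl), int(n_beats - 1), float(dt)))
    rec = _pace_vector(y, cell_class, variant, pcl, 1, dt,
                       STIM_CELL_AMP, STIM_CELL_MS, rec_stride=5)
    return float(rec[:, 0].min())
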