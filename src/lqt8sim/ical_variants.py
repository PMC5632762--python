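"""Variant I_CaL construction, voltage clamp, I-V curves and calibration.

The six CACNA1C alleles are modelled by scaling the I_CaL conductance (csf)
and shifting the steady-state activation/inactivation curves.  Conductance
scale factors are calibrated so the simulated voltage-clamp I-V minimum
reproduces the experimentally observed peak-density fold ratio vs WT.

During clamp simulations the intracellular calcium subsystem runs with the
full model (so calcium-dependent inactivation is driven by the model's own
subspace calcium rather than a frozen value); this dialect is recorded in the
methods note.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .constants import DT_MS, PEAK_DENSITY_FOLD
from .ionic_model import (CellTypeParams, ICaLVariantParams, default_state,
                          get_variant)


@dataclass(frozen=True)
class VoltageClampProtocol:
    """Step-depolarisation protocol: hold, step to each test potential, and
    return to holding between steps."""
    holding_potential: float = -90.0   # mV
    test_potentials: tuple = tuple(np.arange(-40.0, 60.0 + 1e-9, 10.0))
    step_duration: float = 300.0       # ms
    inter_step_interval: float = 3000.0  # ms

    def __post_init__(self):
        if self.step_duration <= 0:
            raise ValueError("step_duration must be positive")
        tp = np.asarray(self.test_potentials, dtype=float)
        if len(tp) == 0 or np.any(np.diff(tp) <= 0):
            raise ValueError("test potentials must be strictly increasing")


@dataclass
class IVCurve:
    """Peak inward current density per test potential."""
    test_potentials: np.ndarray
    peak_density: np.ndarray  # pA/pF, most negative current during each step

    @property
    def minimum(self) -> float:
        """The most negative peak density over the whole curve."""
        return float(self.peak_density.min())

    @property
    def minimum_potential(self) -> float:
        return float(self.test_potentials[int(np.argmin(self.peak_density))])


def steady_state_activation(v, variant) -> np.ndarray:
    """d-gate steady state 1/(1+exp((va_half - v)/sa))."""
    variant = get_variant(variant)
    return 1.0 / (1.0 + np.exp((variant.va_half - np.asarray(v, float))
                               / variant.sa))


def steady_state_inactivation(v, variant) -> np.ndarray:
    """f-gate steady state 1/(1+exp((v - vina_half)/sina))."""
    variant = get_variant(variant)
    return 1.0 / (1.0 + np.exp((np.asarray(v, float) - variant.vina_half)
                               / variant.sina))


def window_current_integral(variant, v_lo: float = -60.0, v_hi: float = 40.0,
                            dv: float = 0.1) -> float:
    """Integral over voltage of activation x inactivation steady states.

    A relative index of the steady 'window' through which calcium enters;
    larger for variants whose curves overlap more.
    """
    v = np.arange(v_lo, v_hi + dv / 2, dv)
    return float(np.trapezoid(steady_state_activation(v, variant)
                              * steady_state_inactivation(v, variant), v))


def simulate_voltage_clamp(variant, protocol: VoltageClampProtocol | None = None,
                           dt: float = DT_MS):
    """Run the step protocol under voltage clamp; return per-step I_CaL traces.

    The membrane potential follows the clamp exactly; gates and intracellular
    calcium evolve under the full model.  Returns ``(times, traces)`` where
    ``times`` is the within-step time axis (ms) and ``traces`` has one row of
    I_CaL (pA/pF) per test potential.
    """
    variant = get_variant(variant)
    if protocol is None:
        protocol = VoltageClampProtocol()
    ct = CellTypeParams.for_class("ENDO")  # I_CaL identical across classes
    lut = _kernels.build_lut(dt, variant.va_half, variant.sa,
                             variant.vina_half, variant.sina, variant.tcsf)

    pre_hold_ms = 2000.0
    hold_steps = int(round(protocol.inter_step_interval / dt))
    test_steps = int(round(protocol.step_duration / dt))
    seg_v = [protocol.holding_potential]
    seg_steps = [int(round(pre_hold_ms / dt))]
    for vt in protocol.test_potentials:
        seg_v += [float(vt), protocol.holding_potential]
        seg_steps += [test_steps, hold_steps]
    seg_v = np.array(seg_v)
    seg_steps_arr = np.array(seg_steps, dtype=np.int64)

    stride = 5  # record every 0.1 ms
    n_total = int(seg_steps_arr.sum())
    rec = np.empty((n_total - 1) // stride + 1, dtype=np.float64)
    y = default_state().as_vector().reshape(1, 19)
    _kernels.run_clamp(y, lut, ct.endo_s_gate, ct.g_to, ct.g_ks, variant.csf,
                       dt, seg_v, seg_steps_arr, stride, rec)

    traces = []
    cursor = seg_steps_arr[0]
    for k in range(len(protocol.test_potentials)):
        a = int(cursor) // stride
        b = int(cursor + test_steps) // stride
        traces.append(rec[a:b].copy())
        cursor += test_steps + hold_steps
    times = np.arange(len(traces[0])) * dt * stride
    return times, np.array(traces)


def compute_iv_curve(traces, protocol: VoltageClampProtocol | None = None) -> IVCurve:
    """Peak inward (most negative) density per step, by exhaustive scan."""
    if protocol is None:
        protocol = VoltageClampProtocol()
    traces = np.asarray(traces)
    if traces.size == 0:
        raise ValueError("empty clamp traces")
    peaks = traces.min(axis=1)
    return IVCurve(np.asarray(protocol.test_potentials, float), peaks)


def _iv_minimum(variant, protocol=None, dt=DT_MS) -> float:
    _, traces = simulate_voltage_clamp(variant, protocol, dt)
    return compute_iv_curve(traces, protocol).minimum


def calibrate_csf(variant_kinetics: ICaLVariantParams, target_fold: float,
                  wt_reference: float | None = None,
                  protocol: VoltageClampProtocol | None = None,
                  rel_tol: float = 1e-4, lo: float = 0.01, hi: float = 10.0,
                  dt: float = DT_MS) -> float:
    """Find csf so the clamp I-V minimum equals ``target_fold`` x WT's.

    Deterministic bisection on csf in [lo, hi].  ``wt_reference`` (the WT I-V
    minimum) is computed if not supplied.  Raises if the root is not
    bracketed, reporting the searched interval.
    """
    if target_fold <= 0:
        raise ValueError("target_fold must be positive")
    if wt_reference is None:
        wt_reference = _iv_minimum(get_variant("WT"), protocol, dt)
    target = target_fold * wt_reference  # both negative

    def ratio_err(csf):
        probe = replace(variant_kinetics, csf=csf)
        return _iv_minimum(probe, protocol, dt) - target

    f_lo, f_hi = ratio_err(lo), ratio_err(hi)
    # peak density is increasingly negative with csf: f(lo) > 0 > f(hi)
    if not (f_lo > 0 > f_hi):
        raise ValueError(
            f"csf root not bracketed on [{lo}, {hi}]: "
            f"err({lo})={f_lo:.4g}, err({hi})={f_hi:.4g}")
    a, b = lo, hi
    while (b - a) / max(abs(a), abs(b)) > rel_tol:
        mid = 0.5 * (a + b)
        if ratio_err(mid) > 0:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


def calibrate_all(protocol: VoltageClampProtocol | None = None,
                  dt: float = DT_MS) -> dict[str, float]:
    """Calibrate csf for every allele against its experimental fold ratio."""
    wt_min = _iv_minimum(get_variant("WT"), protocol, dt)
    out = {}
    for label, fold in PEAK_DENSITY_FOLD.items():
        if label == "WT":
            out[label] = 1.0
            continue
        kin = get_variant(label)
        out[label] = calibrate_csf(kin, fold, wt_reference=wt_min,
                                   protocol=protocol, dt=dt)
    return out


def peak_density_folds(protocol: VoltageClampProtocol | None = None,
                       dt: float = DT_MS) -> dict[str, float]:
    """Simulated I-V-minimum fold ratios vs WT for all alleles (as shipped)."""
    wt_min = _iv_minimum(get_variant("WT"), protocol, dt)
    return {label: _iv_minimum(get_variant(label), protocol, dt) / wt_min
            for label in PEAK_DENSITY_FOLD}
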