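"""Experiment orchestration, synthetic-trace fixtures and the reference
comparison pipeline.

The synthetic traces are piecewise-linear action-potential trains whose
APD90, amplitude and afterdepolarization placement follow in closed form
from the spec fields, so every measurement operation is unit-testable
without running the solver.  The whole pipeline is RNG-free: identical
configurations produce bit-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import cell_protocols as cp
from .constants import (CELL_CLASSES, DT_MS, DX_TRANSMURAL_MM, D_TRANSMURAL,
                        VARIANT_ORDER)
from .cell_protocols import Trace

#: Default comparison tolerances per quantity family.
DEFAULT_TOLERANCES = {
    "ms": 2.0,           # APD / QT / RT / DOR-class quantities
    "mm/ms": 0.005,      # conduction velocity
    "dimensionless": 0.1,  # restitution slopes
    "mV": 1.0,
    "mM": 0.05,
    "percent": 0.5,
    "ms/mm": 1.0,
}


@dataclass(frozen=True)
class SyntheticTraceSpec:
    """Geometry of a piecewise-linear AP train.

    Each beat: instantaneous rise (one sample) from ``resting`` to ``peak``,
    a flat plateau of ``plateau_ms``, a linear fall over ``ramp_ms`` back to
    rest.  APD90 is then ``plateau_ms + 0.9 * ramp_ms`` in closed form.  An
    optional bump (time relative to beat start, amplitude, width) adds a
    triangular afterdepolarization.
    """
    resting: float = -85.0
    peak: float = 35.0
    plateau_ms: float = 200.0
    ramp_ms: float = 100.0
    cycle_ms: float = 1000.0
    beats: int = 1
    bump_time: float | None = None   # ms after beat start
    bump_amplitude: float = 0.0      # mV
    bump_width: float = 20.0         # ms
    dt: float = 0.1                  # ms

    @property
    def apd90(self) -> float:
        """Closed-form APD90 of the fixture."""
        return self.plateau_ms + 0.9 * self.ramp_ms

    @property
    def apd50(self) -> float:
        return self.plateau_ms + 0.5 * self.ramp_ms


def generate_synthetic_trace(spec: SyntheticTraceSpec) -> Trace:
    """Deterministic piecewise-linear AP train per the spec."""
    if spec.plateau_ms + spec.ramp_ms >= spec.cycle_ms:
        raise ValueError("beats overlap: plateau + ramp must fit in the cycle")
    if spec.bump_time is not None and not (0 < spec.bump_time < spec.cycle_ms):
        raise ValueError("bump_time must fall inside the cycle")
    n_per = int(round(spec.cycle_ms / spec.dt))
    t_beat = np.arange(n_per) * spec.dt
    vm_beat = np.full(n_per, spec.resting)
    rise_end = spec.dt  # one-sample upstroke
    in_plateau = (t_beat >= rise_end) & (t_beat < rise_end + spec.plateau_ms)
    vm_beat[in_plateau] = spec.peak
    in_ramp = (t_beat >= rise_end + spec.plateau_ms) \
        & (t_beat < rise_end + spec.plateau_ms + spec.ramp_ms)
    frac = (t_beat[in_ramp] - rise_end - spec.plateau_ms) / spec.ramp_ms
    vm_beat[in_ramp] = spec.peak + frac * (spec.resting - spec.peak)
    if spec.bump_time is not None and spec.bump_amplitude != 0.0:
        tri = 1.0 - np.abs(t_beat - spec.bump_time) / (spec.bump_width / 2)
        vm_beat = vm_beat + spec.bump_amplitude * np.clip(tri, 0.0, None)
    vm = np.tile(vm_beat, spec.beats)
    time = np.arange(len(vm)) * spec.dt
    stim_times = np.arange(spec.beats) * spec.cycle_ms
    return Trace(time, vm, stim_times=stim_times,
                 meta={"synthetic": True, "spec": spec})


# ---------------------------------------------------------------------------
# Experiment configs
# ---------------------------------------------------------------------------

_EXPERIMENTS = ("single-cell", "restitution-dynamic", "restitution-s1s2",
                "cable-cv", "cable-ecg", "mpcl", "afterdepolarizations")


@dataclass
class ExperimentConfig:
    """Validated description of one experiment run.

    Defaults equal the study conditions: PCL 1,000 ms, 100 pre-pacing beats,
    dt 0.02 ms, transmural D = 0.0385 mm^2/ms, dx = 0.15 mm.
    """
    experiment: str
    variant: str = "WT"
    cell_class: str = "ENDO"
    pcl: float = 1000.0
    n_beats: int = 100
    dt: float = DT_MS
    d_coeff: float = D_TRANSMURAL
    dx: float = DX_TRANSMURAL_MM
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.experiment not in _EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}; "
                             f"choose from {_EXPERIMENTS}")
        if self.variant not in VARIANT_ORDER:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.cell_class.upper() not in CELL_CLASSES:
            raise ValueError(f"unknown cell class {self.cell_class!r}")
        if self.pcl <= 0 or self.n_beats < 1 or self.dt <= 0:
            raise ValueError("pcl, n_beats and dt must be positive")
        num = self.d_coeff * self.dt / self.dx ** 2
        if num >= 0.5:
            raise ValueError(
                f"unstable configuration: D*dt/dx^2 = {num:.3f} >= 1/2")

    def provenance(self) -> dict:
        from . import __version__
        out = {k: getattr(self, k) for k in
               ("experiment", "variant", "cell_class", "pcl", "n_beats",
                "dt", "d_coeff", "dx")}
        out["code_version"] = __version__
        return out


def run_experiment(config: ExperimentConfig) -> dict:
    """Dispatch one experiment; returns a result bundle with provenance.

    Deterministic: no RNG anywhere in the pipeline, so identical configs give
    bit-identical results.
    """
    from . import monodomain_tissue as mt
    from . import pseudo_ecg as pe

    res: dict = {"provenance": config.provenance()}
    exp = config.experiment
    if exp == "single-cell":
        tr = cp.pace(config.cell_class, config.variant, config.pcl,
                     config.n_beats, record_last=2, dt=config.dt)
        res["apd90"] = cp.apd90(tr)
        res.update(cp.calcium_biomarkers(tr))
        res["resting_potential"] = float(tr.vm.min())
    elif exp == "restitution-dynamic":
        curve = cp.restitution_dynamic(config.cell_class, config.variant,
                                       dt=config.dt)
        res["max_slope"] = cp.max_apdr_slope(curve)
        res["curve_di"] = curve.di.tolist()
        res["curve_apd"] = curve.apd.tolist()
    elif exp == "restitution-s1s2":
        curve = cp.restitution_s1s2(config.cell_class, config.variant,
                                    s1_pcl=config.pcl, dt=config.dt)
        res["max_slope"] = cp.max_apdr_slope(curve)
        res["curve_di"] = curve.di.tolist()
        res["curve_apd"] = curve.apd.tolist()
    elif exp == "cable-cv":
        geo = mt.build_homogeneous_cable(config.extra.get("cable_class",
                                                          "MCELL"))
        params = mt.TissueParams(config.d_coeff, config.dx, config.dt)
        st = mt.run_s1_train(config.variant, config.pcl, n_beats=2,
                             geometry=geo, params=params, tail_ms=600.0)
        res["cv"] = mt.measure_cv(st)
    elif exp == "cable-ecg":
        n_beats = config.extra.get("n_beats_cable", 10)
        params = mt.TissueParams(config.d_coeff, config.dx, config.dt)
        st = mt.run_s1_train(config.variant, config.pcl, n_beats=n_beats,
                             params=params, tail_ms=600.0, rec_dt=0.5)
        beat = (n_beats - 1) * config.pcl
        ecg = pe.compute_pseudo_ecg(st)
        prof = pe.repolarization_metrics(st, beat)
        tw = pe.t_wave_metrics(ecg, beat)
        res.update(qt_interval=pe.qt_interval(ecg, beat),
                   t_wave_width=tw["width"], t_wave_amplitude=tw["amplitude"],
                   rt=prof.rt, apd_max=prof.apd_max, dor=prof.dor,
                   msg=prof.msg, msg_epi_m=prof.msg_epi_m)
    elif exp == "mpcl":
        params = mt.TissueParams(config.d_coeff, config.dx, config.dt)
        res["mpcl"] = mt.find_mpcl(config.variant, params=params)
    elif exp == "afterdepolarizations":
        tr = cp.pace(config.cell_class, config.variant, config.pcl,
                     config.n_beats, record_last=8, dt=config.dt)
        events = cp.detect_afterdepolarizations(tr)
        res["n_ead"] = sum(e.kind == "EAD" for e in events)
        res["n_dad"] = sum(e.kind == "DAD" for e in events)
        res["events"] = [(e.kind, e.onset_time, e.prominence) for e in events]
    return res


# ---------------------------------------------------------------------------
# Reference comparison
# ---------------------------------------------------------------------------

def load_reference_table() -> pd.DataFrame:
    """The published per-allele summary table shipped with the package."""
    path = resources.files("lqt8sim") / "data" / "reference_table1.csv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, comment="#")


def compare_to_reference(result: pd.DataFrame, reference: pd.DataFrame,
                         tolerances: dict | None = None) -> pd.DataFrame:
    """Cell-by-cell comparison of a result table against the reference.

    Both frames must share the ``quantity``/``units`` columns and the allele
    columns.  Returns one row per (quantity, allele) with absolute and
    relative deviations and a pass flag at the per-unit tolerance.  Failures
    are reported, never hidden.
    """
    tol = dict(DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    missing = set(reference.columns) - set(result.columns)
    if missing:
        raise ValueError(f"result table missing columns {sorted(missing)}")
    rows = []
    for _, ref_row in reference.iterrows():
        q, units = ref_row["quantity"], ref_row["units"]
        match = result[result["quantity"] == q]
        if match.empty:
            rows.append({"quantity": q, "variant": "*", "status": "missing"})
            continue
        res_row = match.iloc[0]
        for allele in VARIANT_ORDER:
            if allele not in reference.columns:
                continue
            ref_v = float(ref_row[allele])
            res_v = float(res_row[allele])
            adev = abs(res_v - ref_v)
            rdev = adev / abs(ref_v) if ref_v else np.inf
            rows.append({
                "quantity": q, "variant": allele, "units": units,
                "reference": ref_v, "result": res_v,
                "abs_dev": adev, "rel_dev": rdev,
                "tolerance": tol.get(units, np.nan),
                "status": "pass" if adev <= tol.get(units, np.inf) else "fail",
            })
    return pd.DataFrame(rows)
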