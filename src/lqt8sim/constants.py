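"""Parameter tables for the TP06 ventricular myocyte model and I_CaL variants.

The numeric source of truth is the pair of structured-text tables shipped in
``lqt8sim/data``: one for the TP06 model constants and one for the six I_CaL
variant parameter sets.  Loaders validate the schema (names, positivity) so a
corrupted table fails loudly rather than silently changing the model.
"""
from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np

#: Names that must be present in the TP06 constants table.
_REQUIRED_TP06 = {
    "R", "T", "F", "Cm", "V_c", "V_sr", "V_ss", "K_o", "Na_o", "Ca_o",
    "g_Na", "g_K1", "g_Kr", "g_Ks_epi", "g_Ks_endo", "g_Ks_m",
    "g_to_epi", "g_to_endo", "g_to_m", "g_CaL", "g_bna", "g_bca",
    "g_pCa", "K_pCa", "g_pK", "P_kna", "P_NaK", "K_mk", "K_mNa",
    "K_NaCa", "K_sat", "alpha_ncx", "gamma_ncx", "Km_Ca", "Km_Nai",
    "V_rel", "k1_prime", "k2_prime", "k3", "k4", "EC_sr", "max_sr",
    "min_sr", "V_leak", "S_over", "K_over", "w_over", "V_xfer", "Vmax_up",
    "K_up",
    "Buf_c", "K_buf_c", "Buf_sr", "K_buf_sr", "Buf_ss", "K_buf_ss",
}

_VARIANT_COLUMNS = ("label", "csf", "va_half", "sa", "vina_half", "sina",
                    "tcsf", "provenance")

#: Canonical variant ordering used throughout (increasing peak I_CaL density).
VARIANT_ORDER = ("G1783C", "WT", "P381S", "M456I", "A582D", "R858H")

#: Experimental peak-density fold ratios vs WT, in VARIANT_ORDER.
PEAK_DENSITY_FOLD = {
    "G1783C": 0.86, "WT": 1.0, "P381S": 1.04,
    "M456I": 1.08, "A582D": 1.19, "R858H": 1.54,
}

CELL_CLASSES = ("ENDO", "MCELL", "EPI")


def _read_table(name: str) -> list[list[str]]:
    text = (resources.files("lqt8sim") / "data" / name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


@lru_cache(maxsize=None)
def tp06_constants() -> dict[str, float]:
    """Load and validate the TP06 constant table."""
    rows = _read_table("tp06_constants.tsv")
    out: dict[str, float] = {}
    for row in rows:
        if len(row) < 3:
            raise ValueError(f"malformed TP06 constant row: {row!r}")
        name, value = row[0], float(row[1])
        if name in out:
            raise ValueError(f"duplicate TP06 constant {name!r}")
        out[name] = value
    missing = _REQUIRED_TP06 - out.keys()
    if missing:
        raise ValueError(f"TP06 constant table missing {sorted(missing)}")
    for name in ("g_Na", "g_K1", "g_Kr", "g_CaL", "Cm", "F", "T"):
        if out[name] <= 0:
            raise ValueError(f"TP06 constant {name!r} must be positive")
    return out


@lru_cache(maxsize=None)
def variant_table() -> dict[str, dict[str, object]]:
    """Load and validate the I_CaL variant parameter table."""
    rows = _read_table("ical_variants.tsv")
    header = tuple(rows[0])
    if header != _VARIANT_COLUMNS:
        raise ValueError(f"unexpected variant-table header {header!r}")
    out: dict[str, dict[str, object]] = {}
    for row in rows[1:]:
        rec = dict(zip(header, row))
        label = rec["label"]
        entry = {
            "label": label,
            "csf": float(rec["csf"]),
            "va_half": float(rec["va_half"]),
            "sa": float(rec["sa"]),
            "vina_half": float(rec["vina_half"]),
            "sina": float(rec["sina"]),
            "tcsf": float(rec["tcsf"]),
            "provenance": rec["provenance"],
        }
        for key in ("csf", "sa", "sina", "tcsf"):
            if entry[key] <= 0:  # type: ignore[operator]
                raise ValueError(f"variant {label}: {key} must be > 0")
        out[label] = entry
    missing = set(VARIANT_ORDER) - out.keys()
    if missing:
        raise ValueError(f"variant table missing {sorted(missing)}")
    wt = out["WT"]
    if not (wt["csf"] == 1.0 and wt["tcsf"] == 1.0):
        raise ValueError("WT row must have csf=1 and tcsf=1")
    return out


def tp06_vector() -> np.ndarray:
    """TP06 constants packed in the fixed order used by the numeric kernels."""
    c = tp06_constants()
    names = sorted(_REQUIRED_TP06)
    return np.array([c[n] for n in names], dtype=np.float64)


#: Published TP06 initial conditions (epicardial); the starting point for the
#: pre-pacing equilibration that defines each cell's working initial state.
TP06_INITIAL_STATE = {
    "vm": -85.23, "m": 0.00172, "h": 0.7444, "j": 0.7045,
    "xr1": 0.00621, "xr2": 0.4712, "xs": 0.0095, "r": 2.42e-8,
    "s": 0.999998, "d": 3.373e-5, "f": 0.7888, "f2": 0.9755,
    "fcass": 0.9953, "rbar": 0.9073, "nai": 8.604, "ki": 136.89,
    "cai": 0.000126, "cass": 0.00036, "casr": 3.64,
}

#: State-vector layout shared by the Python API and the numeric kernels.
STATE_NAMES = ("vm", "m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f",
               "f2", "fcass", "rbar", "nai", "ki", "cai", "cass", "casr")
N_STATE = len(STATE_NAMES)

GATE_NAMES = ("m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f", "f2",
              "fcass", "rbar")

#: Default solver constants (forward-Euler marching step, tissue geometry).
DT_MS = 0.02
DX_TRANSMURAL_MM = 0.15
DX_MCELL_2D_MM = 0.25
D_TRANSMURAL = 0.0385  # mm^2/ms
D_MCELL_2D = 0.154     # mm^2/ms

#: Stimulus conventions: single cell (TP06 convention) and tissue.
STIM_CELL_AMP = -52.0   # pA/pF
STIM_CELL_MS = 1.0
STIM_TISSUE_AMP = -40.0  # uA/cm^2 == pA/pF at Cm = 1 uF/cm^2
STIM_TISSUE_MS = 3.0
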