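"""Compiled numeric core: TP06 ionic kinetics and explicit tissue steppers.

The drivers here integrate the TP06 human ventricular myocyte model (with a
pluggable I_CaL variant) for single cells, voltage-clamp runs, 1D cables and
2D sheets.  Voltage-dependent gate steady states, Rush-Larsen factors and
current coefficients are pre-tabulated on a fine Vm grid (0.02 mV) and linearly
interpolated, which keeps the per-node cost low enough to run tissue problems
on one CPU.  Calcium-dependent quantities (subspace-gated inactivation, SR
release/leak, exchanger and pump saturations) are evaluated exactly each step.

State-vector layout (axis 1 of every state array; one row per node), see ``constants.STATE_NAMES``:
0 vm, 1 m, 2 h, 3 j, 4 xr1, 5 xr2, 6 xs, 7 r, 8 s, 9 d, 10 f, 11 f2,
12 fcass, 13 rbar, 14 nai, 15 ki, 16 cai, 17 cass, 18 casr
"""
from __future__ import annotations

import numpy as np
from numba import njit

from .constants import tp06_constants

_C = tp06_constants()

R = _C["R"]; T = _C["T"]; F = _C["F"]
FRT = F / (R * T)
RTF = 1.0 / FRT
CM = _C["Cm"]; V_C = _C["V_c"]; V_SR = _C["V_sr"]; V_SS = _C["V_ss"]
KO = _C["K_o"]; NAO = _C["Na_o"]; CAO = _C["Ca_o"]
G_NA = _C["g_Na"]; G_K1 = _C["g_K1"]; G_KR = _C["g_Kr"]; G_CAL = _C["g_CaL"]
G_BNA = _C["g_bna"]; G_BCA = _C["g_bca"]; G_PCA = _C["g_pCa"]
K_PCA = _C["K_pCa"]; G_PK = _C["g_pK"]; P_KNA = _C["P_kna"]
P_NAK = _C["P_NaK"]; K_MK = _C["K_mk"]; K_MNA = _C["K_mNa"]
K_NACA = _C["K_NaCa"]; K_SAT = _C["K_sat"]; ALPHA = _C["alpha_ncx"]
GAMMA = _C["gamma_ncx"]; KM_CA = _C["Km_Ca"]; KM_NAI = _C["Km_Nai"]
V_REL = _C["V_rel"]; K1P = _C["k1_prime"]; K2P = _C["k2_prime"]
K3 = _C["k3"]; K4 = _C["k4"]; EC_SR = _C["EC_sr"]
MAX_SR = _C["max_sr"]; MIN_SR = _C["min_sr"]
V_LEAK = _C["V_leak"]; V_XFER = _C["V_xfer"]
S_OVER = _C["S_over"]; K_OVER = _C["K_over"]; W_OVER = _C["w_over"]
VMAX_UP = _C["Vmax_up"]; K_UP = _C["K_up"]
BUF_C = _C["Buf_c"]; K_BUF_C = _C["K_buf_c"]
BUF_SR = _C["Buf_sr"]; K_BUF_SR = _C["K_buf_sr"]
BUF_SS = _C["Buf_ss"]; K_BUF_SS = _C["K_buf_ss"]
SQRT_KO = np.sqrt(KO / 5.4)

# ---------------------------------------------------------------------------
# Gate steady states and time constants (vectorised; used for the lookup
# table and by the reference Python model).
# ---------------------------------------------------------------------------

def gate_curves(v, va_half=-8.0, sa=7.5, vina_half=-20.0, sina=7.0, tcsf=1.0):
    """Steady states and time constants of the 12 voltage-driven gates.

    Returns a dict of (inf, tau) pairs; the activation gate ``d`` and the
    voltage-inactivation gate ``f`` use the variant midpoints/slopes and the
    ``f`` time constant is scaled by ``tcsf``.  ``s`` is returned for both the
    EPI/MCELL and the ENDO kinetics.
    """
    v = np.asarray(v, dtype=np.float64)
    out = {}
    m_inf = 1.0 / (1.0 + np.exp((-56.86 - v) / 9.03)) ** 2
    am = 1.0 / (1.0 + np.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + np.exp((v + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((v - 50.0) / 200.0))
    out["m"] = (m_inf, am * bm)

    h_inf = 1.0 / (1.0 + np.exp((v + 71.55) / 7.43)) ** 2
    ah = np.where(v < -40.0, 0.057 * np.exp(-(v + 80.0) / 6.8), 0.0)
    bh = np.where(v < -40.0,
                  2.7 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.3485 * v),
                  0.77 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1))))
    out["h"] = (h_inf, 1.0 / (ah + bh))

    with np.errstate(over="ignore"):
        aj = np.where(
            v < -40.0,
            (-2.5428e4 * np.exp(0.2444 * v) - 6.948e-6 * np.exp(-0.04391 * v))
            * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23))),
            0.0)
    bj = np.where(v < -40.0,
                  0.02424 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14))),
                  0.6 * np.exp(0.057 * v) / (1.0 + np.exp(-0.1 * (v + 32.0))))
    out["j"] = (h_inf, 1.0 / (aj + bj))

    xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - v) / 7.0))
    a = 450.0 / (1.0 + np.exp((-45.0 - v) / 10.0))
    b = 6.0 / (1.0 + np.exp((v + 30.0) / 11.5))
    out["xr1"] = (xr1_inf, a * b)

    xr2_inf = 1.0 / (1.0 + np.exp((v + 88.0) / 24.0))
    a = 3.0 / (1.0 + np.exp((-60.0 - v) / 20.0))
    b = 1.12 / (1.0 + np.exp((v - 60.0) / 20.0))
    out["xr2"] = (xr2_inf, a * b)

    xs_inf = 1.0 / (1.0 + np.exp((-5.0 - v) / 14.0))
    a = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - v) / 6.0))
    b = 1.0 / (1.0 + np.exp((v - 35.0) / 15.0))
    out["xs"] = (xs_inf, a * b + 80.0)

    r_inf = 1.0 / (1.0 + np.exp((20.0 - v) / 6.0))
    out["r"] = (r_inf, 9.5 * np.exp(-((v + 40.0) ** 2) / 1800.0) + 0.8)

    s_inf_epi = 1.0 / (1.0 + np.exp((v + 20.0) / 5.0))
    tau_s_epi = (85.0 * np.exp(-((v + 45.0) ** 2) / 320.0)
                 + 5.0 / (1.0 + np.exp((v - 20.0) / 5.0)) + 3.0)
    out["s_epi"] = (s_inf_epi, tau_s_epi)

    s_inf_endo = 1.0 / (1.0 + np.exp((v + 28.0) / 5.0))
    tau_s_endo = 1000.0 * np.exp(-((v + 67.0) ** 2) / 1000.0) + 8.0
    out["s_endo"] = (s_inf_endo, tau_s_endo)

    d_inf = 1.0 / (1.0 + np.exp((va_half - v) / sa))
    ad = 1.4 / (1.0 + np.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((v + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - v) / 20.0))
    out["d"] = (d_inf, ad * bd + gd)

    f_inf = 1.0 / (1.0 + np.exp((v - vina_half) / sina))
    tau_f = (1102.5 * np.exp(-((v + 27.0) ** 2) / 225.0)
             + 200.0 / (1.0 + np.exp((13.0 - v) / 10.0))
             + 180.0 / (1.0 + np.exp((v + 30.0) / 10.0)) + 20.0)
    out["f"] = (f_inf, tcsf * tau_f)

    f2_inf = 0.75 / (1.0 + np.exp((v + 35.0) / 7.0)) + 0.25
    tau_f2 = (600.0 * np.exp(-((v + 25.0) ** 2) / 170.0)
              + 31.0 / (1.0 + np.exp((25.0 - v) / 10.0))
              + 16.0 / (1.0 + np.exp((v + 30.0) / 10.0)))
    out["f2"] = (f2_inf, tau_f2)
    return out


# Lookup-table geometry.
LUT_V0 = -100.0
LUT_DV = 0.02
LUT_N = 9001  # covers [-100, +80] mV
LUT_NCOL = 30

_GATE_COL = {"m": 0, "h": 2, "j": 4, "xr1": 6, "xr2": 8, "xs": 10, "r": 12,
             "s_epi": 14, "s_endo": 16, "d": 18, "f": 20, "f2": 22}


def build_lut(dt: float, va_half: float = -8.0, sa: float = 7.5,
              vina_half: float = -20.0, sina: float = 7.0,
              tcsf: float = 1.0) -> np.ndarray:
    """Tabulate voltage-dependent model quantities for a fixed time step.

    Gate columns hold the steady state and the Rush-Larsen factor
    ``1 - exp(-dt/tau)``; the remaining columns hold the I_CaL driving-force
    coefficient, ``exp(2(V-15)F/RT)`` and the NCX/NaK/IpK voltage factors.
    """
    v = LUT_V0 + LUT_DV * np.arange(LUT_N)
    lut = np.empty((LUT_N, LUT_NCOL), dtype=np.float64)
    curves = gate_curves(v, va_half, sa, vina_half, sina, tcsf)
    for name, col in _GATE_COL.items():
        inf, tau = curves[name]
        lut[:, col] = inf
        lut[:, col + 1] = 1.0 - np.exp(-dt / tau)
    vm15 = v - 15.0
    e2v = np.exp(2.0 * vm15 * FRT)
    denom = e2v - 1.0
    small = np.abs(vm15) < 1e-6
    a = np.empty_like(v)
    a[~small] = G_CAL * 4.0 * vm15[~small] * F * FRT / denom[~small]
    a[small] = G_CAL * 2.0 * F  # limit V -> 15 mV
    lut[:, 24] = a
    lut[:, 25] = e2v
    lut[:, 26] = np.exp(GAMMA * v * FRT)
    lut[:, 27] = np.exp((GAMMA - 1.0) * v * FRT)
    lut[:, 28] = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * v * FRT)
                        + 0.0353 * np.exp(-v * FRT))
    lut[:, 29] = 1.0 / (1.0 + np.exp((25.0 - v) / 5.98))
    return lut


# ---------------------------------------------------------------------------
# Per-node update (lookup-table Rush-Larsen / forward-Euler step).
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always", fastmath=True)
def _node_currents_and_update(y, i, lut, endo_s, gto, gks, csf, istim, dt):
    """Advance gates and concentrations of node ``i`` one step; return Iion.

    Uses the state at entry throughout; the caller updates vm afterwards so a
    diffusion term can be added.  Returns the total transmembrane current
    (pA/pF, stimulus excluded).
    """
    v = y[i, 0]
    # table interpolation
    x = (v - LUT_V0) / LUT_DV
    if x < 0.0:
        x = 0.0
    elif x > LUT_N - 1.001:
        x = LUT_N - 1.001
    k = int(x)
    w = x - k
    r0 = lut[k]
    r1 = lut[k + 1]

    nai = y[i, 14]; ki = y[i, 15]; cai = y[i, 16]; cass = y[i, 17]; casr = y[i, 18]

    ena = RTF * np.log(NAO / nai)
    ek = RTF * np.log(KO / ki)
    eks = RTF * np.log((KO + P_KNA * NAO) / (ki + P_KNA * nai))
    eca = 0.5 * RTF * np.log(CAO / cai)

    m = y[i, 1]; h = y[i, 2]; j = y[i, 3]
    xr1 = y[i, 4]; xr2 = y[i, 5]; xs = y[i, 6]
    rg = y[i, 7]; s = y[i, 8]; d = y[i, 9]
    f = y[i, 10]; f2 = y[i, 11]; fcass = y[i, 12]; rbar = y[i, 13]

    ina = G_NA * m * m * m * h * j * (v - ena)
    icalA = r0[24] + w * (r1[24] - r0[24])
    e2v = r0[25] + w * (r1[25] - r0[25])
    ical = csf * icalA * d * f * f2 * fcass * (0.25 * cass * e2v - CAO)
    ito = gto * rg * s * (v - ek)
    ikr = G_KR * SQRT_KO * xr1 * xr2 * (v - ek)
    iks = gks * xs * xs * (v - eks)

    vek = v - ek
    ak1 = 0.1 / (1.0 + np.exp(0.06 * (vek - 200.0)))
    bk1 = (3.0 * np.exp(0.0002 * (vek + 100.0)) + np.exp(0.1 * (vek - 10.0))) \
        / (1.0 + np.exp(-0.5 * vek))
    ik1 = G_K1 * SQRT_KO * (ak1 / (ak1 + bk1)) * vek

    e1 = r0[26] + w * (r1[26] - r0[26])
    e2 = r0[27] + w * (r1[27] - r0[27])
    incx = K_NACA * (e1 * nai * nai * nai * CAO
                     - e2 * NAO * NAO * NAO * cai * ALPHA) \
        / ((KM_NAI ** 3 + NAO ** 3) * (KM_CA + CAO) * (1.0 + K_SAT * e2))
    inakf = r0[28] + w * (r1[28] - r0[28])
    inak = P_NAK * KO * nai / ((KO + K_MK) * (nai + K_MNA)) * inakf
    ipca = G_PCA * cai / (cai + K_PCA)
    ipk = G_PK * (r0[29] + w * (r1[29] - r0[29])) * vek
    ibna = G_BNA * (v - ena)
    ibca = G_BCA * (v - eca)

    # SR efflux: calcium-induced release combined with an RyR-pathway leak
    # into the dyadic subspace, plus a threshold overload-release component
    # that fires spontaneously once the SR load exceeds K_OVER.
    kcasr = MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (EC_SR / casr) ** 2)
    # overload sensitization: the release activation rate rises steeply once
    # the SR load crosses K_OVER, so release fires spontaneously from the
    # leak-elevated diastolic subspace calcium (tanh form avoids overflow)
    sens = 1.0 + S_OVER * 0.5 * (1.0 + np.tanh((casr - K_OVER) / (2.0 * W_OVER)))
    k1 = K1P / kcasr * sens
    k2 = K2P * kcasr
    o_gate = k1 * cass * cass * rbar / (K3 + k1 * cass * cass)
    irel = V_REL * o_gate * (casr - cass)
    ileak = V_LEAK * (casr - cass)
    iup = VMAX_UP / (1.0 + (K_UP / cai) ** 2)
    ixfer = V_XFER * (cass - cai)

    # gates: Rush-Larsen with tabulated factors
    y[i, 1] = m + (r0[0] + w * (r1[0] - r0[0]) - m) * (r0[1] + w * (r1[1] - r0[1]))
    y[i, 2] = h + (r0[2] + w * (r1[2] - r0[2]) - h) * (r0[3] + w * (r1[3] - r0[3]))
    y[i, 3] = j + (r0[4] + w * (r1[4] - r0[4]) - j) * (r0[5] + w * (r1[5] - r0[5]))
    y[i, 4] = xr1 + (r0[6] + w * (r1[6] - r0[6]) - xr1) * (r0[7] + w * (r1[7] - r0[7]))
    y[i, 5] = xr2 + (r0[8] + w * (r1[8] - r0[8]) - xr2) * (r0[9] + w * (r1[9] - r0[9]))
    y[i, 6] = xs + (r0[10] + w * (r1[10] - r0[10]) - xs) * (r0[11] + w * (r1[11] - r0[11]))
    y[i, 7] = rg + (r0[12] + w * (r1[12] - r0[12]) - rg) * (r0[13] + w * (r1[13] - r0[13]))
    if endo_s:
        y[i, 8] = s + (r0[16] + w * (r1[16] - r0[16]) - s) * (r0[17] + w * (r1[17] - r0[17]))
    else:
        y[i, 8] = s + (r0[14] + w * (r1[14] - r0[14]) - s) * (r0[15] + w * (r1[15] - r0[15]))
    y[i, 9] = d + (r0[18] + w * (r1[18] - r0[18]) - d) * (r0[19] + w * (r1[19] - r0[19]))
    y[i, 10] = f + (r0[20] + w * (r1[20] - r0[20]) - f) * (r0[21] + w * (r1[21] - r0[21]))
    y[i, 11] = f2 + (r0[22] + w * (r1[22] - r0[22]) - f2) * (r0[23] + w * (r1[23] - r0[23]))

    css2 = (cass / 0.05) ** 2
    fcass_inf = 0.6 / (1.0 + css2) + 0.4
    tau_fcass = 80.0 / (1.0 + css2) + 2.0
    y[i, 12] = fcass + (fcass_inf - fcass) * (1.0 - np.exp(-dt / tau_fcass))

    ar = k2 * cass + K4
    y[i, 13] = rbar + (K4 / ar - rbar) * (1.0 - np.exp(-ar * dt))

    # concentrations (forward Euler)
    bufc = 1.0 / (1.0 + BUF_C * K_BUF_C / ((cai + K_BUF_C) ** 2))
    bufsr = 1.0 / (1.0 + BUF_SR * K_BUF_SR / ((casr + K_BUF_SR) ** 2))
    bufss = 1.0 / (1.0 + BUF_SS * K_BUF_SS / ((cass + K_BUF_SS) ** 2))
    dcai = bufc * (-(ibca + ipca - 2.0 * incx) * CM / (2.0 * V_C * F)
                   - iup * V_SR / V_C + ixfer)
    dcasr = bufsr * (iup - irel - ileak)
    dcass = bufss * (-ical * CM / (2.0 * V_SS * F)
                     + (irel + ileak) * V_SR / V_SS - ixfer * V_C / V_SS)
    dnai = -(ina + ibna + 3.0 * inak + 3.0 * incx) * CM / (V_C * F)
    dki = -(ik1 + ito + ikr + iks + ipk + istim - 2.0 * inak) * CM / (V_C * F)

    y[i, 14] = nai + dt * dnai
    y[i, 15] = ki + dt * dki
    y[i, 16] = cai + dt * dcai
    y[i, 17] = cass + dt * dcass
    y[i, 18] = casr + dt * dcasr

    return (ina + ical + ito + ikr + iks + ik1 + incx + inak + ipca + ipk
            + ibna + ibca)


@njit(cache=True, inline="always", fastmath=True)
def _snapshot_channels(y, i, lut, csf):
    """(ical, incx, irel) of node ``i`` at the current state."""
    v = y[i, 0]
    x = (v - LUT_V0) / LUT_DV
    if x < 0.0:
        x = 0.0
    elif x > LUT_N - 1.001:
        x = LUT_N - 1.001
    k = int(x)
    w = x - k
    nai = y[i, 14]; cai = y[i, 16]; cass = y[i, 17]; casr = y[i, 18]
    icalA = lut[k, 24] + w * (lut[k + 1, 24] - lut[k, 24])
    e2v = lut[k, 25] + w * (lut[k + 1, 25] - lut[k, 25])
    ical = csf * icalA * y[i, 9] * y[i, 10] * y[i, 11] * y[i, 12] \
        * (0.25 * cass * e2v - CAO)
    e1 = lut[k, 26] + w * (lut[k + 1, 26] - lut[k, 26])
    e2 = lut[k, 27] + w * (lut[k + 1, 27] - lut[k, 27])
    incx = K_NACA * (e1 * nai ** 3 * CAO - e2 * NAO ** 3 * cai * ALPHA) \
        / ((KM_NAI ** 3 + NAO ** 3) * (KM_CA + CAO) * (1.0 + K_SAT * e2))
    kcasr = MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (EC_SR / casr) ** 2)
    sens = 1.0 + S_OVER * 0.5 * (1.0 + np.tanh((casr - K_OVER) / (2.0 * W_OVER)))
    k1 = K1P / kcasr * sens
    o_gate = k1 * cass * cass * y[i, 13] / (K3 + k1 * cass * cass)
    irel = V_REL * o_gate * (casr - cass)
    return ical, incx, irel


# ---------------------------------------------------------------------------
# Single-cell driver
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def run_cell(y, lut, endo_s, gto, gks, csf, dt, n_steps,
             stim_steps, stim_dur_steps, stim_amp,
             rec_stride, rec_start_step, rec):
    """Integrate one cell for ``n_steps``; record 6 channels at a stride.

    ``y`` is a (1, 19) state array updated in place.  ``stim_steps`` holds the
    onset step of every stimulus (sorted).  ``rec`` is (n_rec, 6) receiving
    (vm, ical, incx, irel, cai, casr) sampled every ``rec_stride`` steps from
    ``rec_start_step``.  Returns -1 on success or the step index at which a
    non-finite vm was produced.
    """
    n_stim = stim_steps.shape[0]
    si = 0
    irec = 0
    for step in range(n_steps):
        istim = 0.0
        while si < n_stim and step >= stim_steps[si] + stim_dur_steps:
            si += 1
        if si < n_stim and stim_steps[si] <= step < stim_steps[si] + stim_dur_steps:
            istim = stim_amp
        if step >= rec_start_step and (step - rec_start_step) % rec_stride == 0:
            if irec < rec.shape[0]:
                ical, incx, irel = _snapshot_channels(y, 0, lut, csf)
                rec[irec, 0] = y[0, 0]
                rec[irec, 1] = ical
                rec[irec, 2] = incx
                rec[irec, 3] = irel
                rec[irec, 4] = y[0, 16]
                rec[irec, 5] = y[0, 18]
                irec += 1
        iion = _node_currents_and_update(y, 0, lut, endo_s, gto, gks, csf, istim, dt)
        v_new = y[0, 0] + dt * (-iion - istim)
        if not np.isfinite(v_new):
            return step
        y[0, 0] = v_new
    return -1


@njit(cache=True, fastmath=True)
def run_clamp(y, lut, endo_s, gto, gks, csf, dt, seg_v, seg_steps,
              rec_stride, rec):
    """Voltage-clamp run: vm follows the segment schedule; record I_CaL.

    ``seg_v``/``seg_steps`` define consecutive clamp segments.  ``rec`` is a
    1D array receiving I_CaL sampled every ``rec_stride`` steps over the whole
    run.  Gates and concentrations evolve under the full model; dvm/dt = 0.
    """
    irec = 0
    step = 0
    for seg in range(seg_v.shape[0]):
        y[0, 0] = seg_v[seg]
        for _ in range(seg_steps[seg]):
            if step % rec_stride == 0 and irec < rec.shape[0]:
                ical, _, _ = _snapshot_channels(y, 0, lut, csf)
                rec[irec] = ical
                irec += 1
            _node_currents_and_update(y, 0, lut, endo_s, gto, gks, csf, 0.0, dt)
            step += 1
    return irec


# ---------------------------------------------------------------------------
# 1D cable driver
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def run_cable(y, lut, endo_flags, gto, gks, csf, dcoef, dx, dt, n_steps,
              s1_nodes, s1_steps, s2_nodes, s2_steps, stim_dur_steps, stim_amp,
              rec_stride, rec,
              act_thresh, act_times, act_counts,
              win_start, win_end, dvdt_max, dvdt_argt,
              reaction_on):
    """Monodomain 1D cable, forward Euler in time, 3-point Laplacian.

    No-flux (mirror) boundaries.  Records vm snapshots every ``rec_stride``
    steps into ``rec`` (n_rec, n).  Per node, stores upstroke times (upward
    crossings of ``act_thresh``) into ``act_times`` (n, K) / ``act_counts``
    and, within the step window [win_start, win_end), tracks the maximum
    dvm/dt and its time (ms) in ``dvdt_max`` / ``dvdt_argt``.
    Returns -1 on success, else the failing step index.
    """
    n = y.shape[0]
    lap = np.empty(n, dtype=np.float64)
    iion = np.empty(n, dtype=np.float64)
    istim = np.empty(n, dtype=np.float64)
    kmax = act_times.shape[1]
    r = dcoef / (dx * dx)
    i1 = 0
    i2 = 0
    irec = 0
    for step in range(n_steps):
        for i in range(n):
            istim[i] = 0.0
        while i1 < s1_steps.shape[0] and step >= s1_steps[i1] + stim_dur_steps:
            i1 += 1
        if i1 < s1_steps.shape[0] and s1_steps[i1] <= step < s1_steps[i1] + stim_dur_steps:
            for k in range(s1_nodes.shape[0]):
                istim[s1_nodes[k]] = stim_amp
        while i2 < s2_steps.shape[0] and step >= s2_steps[i2] + stim_dur_steps:
            i2 += 1
        if i2 < s2_steps.shape[0] and s2_steps[i2] <= step < s2_steps[i2] + stim_dur_steps:
            for k in range(s2_nodes.shape[0]):
                istim[s2_nodes[k]] = stim_amp
        if step % rec_stride == 0 and irec < rec.shape[0]:
            for i in range(n):
                rec[irec, i] = y[i, 0]
            irec += 1
        for i in range(n):
            vl = y[i - 1, 0] if i > 0 else y[1, 0]
            vr = y[i + 1, 0] if i < n - 1 else y[n - 2, 0]
            lap[i] = vl + vr - 2.0 * y[i, 0]
        if reaction_on:
            for i in range(n):
                iion[i] = _node_currents_and_update(
                    y, i, lut, endo_flags[i], gto[i], gks[i], csf,
                    istim[i], dt)
        else:
            for i in range(n):
                iion[i] = 0.0
        for i in range(n):
            dvdt = r * lap[i] - iion[i] - istim[i]
            v_new = y[i, 0] + dt * dvdt
            if not np.isfinite(v_new):
                return step
            if win_start <= step < win_end and dvdt > dvdt_max[i]:
                dvdt_max[i] = dvdt
                dvdt_argt[i] = step * dt
            if y[i, 0] < act_thresh <= v_new and act_counts[i] < kmax:
                act_times[i, act_counts[i]] = step * dt
                act_counts[i] += 1
            y[i, 0] = v_new
    return -1


# ---------------------------------------------------------------------------
# 2D sheet driver
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def run_sheet(y, lut, endo_flags, gto, gks, csf, dcoef, dx, dt, n_steps, ny, nx,
              s1_nodes, s1_steps, s2_nodes, s2_steps, stim_dur_steps, stim_amp,
              probe_idx, probe_stride, probe_rec,
              snap_stride, snaps,
              act_thresh, act_times, act_counts):
    """Monodomain 2D sheet (5-point Laplacian, no-flux boundaries).

    State ``y`` is (ny*nx, 19) with row-major node index ``iy*nx + ix``.
    Records a point trace at ``probe_idx`` every ``probe_stride`` steps,
    optional full-field snapshots every ``snap_stride`` steps (``snaps`` may
    have zero rows), and per-node upstroke times as in :func:`run_cable`.
    Returns -1 on success, else the failing step index.
    """
    n = ny * nx
    lap = np.empty(n, dtype=np.float64)
    iion = np.empty(n, dtype=np.float64)
    istim = np.empty(n, dtype=np.float64)
    vmb = np.empty(n, dtype=np.float64)   # contiguous vm for the stencil
    for i in range(n):
        vmb[i] = y[i, 0]
    kmax = act_times.shape[1]
    r = dcoef / (dx * dx)
    i1 = 0
    i2 = 0
    ip = 0
    isnap = 0
    for step in range(n_steps):
        for i in range(n):
            istim[i] = 0.0
        while i1 < s1_steps.shape[0] and step >= s1_steps[i1] + stim_dur_steps:
            i1 += 1
        if i1 < s1_steps.shape[0] and s1_steps[i1] <= step < s1_steps[i1] + stim_dur_steps:
            for k in range(s1_nodes.shape[0]):
                istim[s1_nodes[k]] = stim_amp
        while i2 < s2_steps.shape[0] and step >= s2_steps[i2] + stim_dur_steps:
            i2 += 1
        if i2 < s2_steps.shape[0] and s2_steps[i2] <= step < s2_steps[i2] + stim_dur_steps:
            for k in range(s2_nodes.shape[0]):
                istim[s2_nodes[k]] = stim_amp
        if step % probe_stride == 0 and ip < probe_rec.shape[0]:
            probe_rec[ip] = vmb[probe_idx]
            ip += 1
        if snaps.shape[0] > 0 and step % snap_stride == 0 and isnap < snaps.shape[0]:
            for i in range(n):
                snaps[isnap, i] = vmb[i]
            isnap += 1
        for iy in range(ny):
            base = iy * nx
            for ix in range(nx):
                i = base + ix
                v = vmb[i]
                vl = vmb[i - 1] if ix > 0 else vmb[i + 1]
                vr = vmb[i + 1] if ix < nx - 1 else vmb[i - 1]
                vu = vmb[i - nx] if iy > 0 else vmb[i + nx]
                vd = vmb[i + nx] if iy < ny - 1 else vmb[i - nx]
                lap[i] = vl + vr + vu + vd - 4.0 * v
        for i in range(n):
            iion[i] = _node_currents_and_update(
                y, i, lut, endo_flags[i], gto[i], gks[i], csf,
                istim[i], dt)
        for i in range(n):
            v_new = y[i, 0] + dt * (r * lap[i] - iion[i] - istim[i])
            if not np.isfinite(v_new):
                return step
            if y[i, 0] < act_thresh <= v_new and act_counts[i] < kmax:
                act_times[i, act_counts[i]] = step * dt
                act_counts[i] += 1
            y[i, 0] = v_new
            vmb[i] = v_new
    return -1
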