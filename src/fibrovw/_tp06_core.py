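"""Numerical core of the ten Tusscher-Panfilov 2006 (TP06) human ventricular myocyte model.

This module holds the reference constants table, the voltage lookup tables and the
numba kernel that advances an array of cells (optionally diffusively coupled) in time.
Everything here works on flat float64 arrays so the same kernel serves single-cell
pacing (n=1, no coupling) and 2D monodomain tissue (n = number of excitable nodes,
neighbour-index coupling with zero-flux closure by self-substitution).

Integration scheme: Rush-Larsen for the 12 voltage/Ca-gated Hodgkin-Huxley-style
gates (exact exponential update against tabulated steady states and rate
exponentials), forward Euler for the ionic concentrations, the ryanodine-receptor
state R-bar, the Ca-dependent fCass gate and the membrane potential.  Stable at
dt = 0.02 ms.

Voltage-dependent quantities are tabulated on a 0.05 mV grid over [-100, 100] mV and
linearly interpolated; the inward-rectifier curve is tabulated against V - E_K.
Tables are rebuilt per dt (the gate exponentials bake dt in).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Physical constants and fixed model parameters (TP06 reference values)
# ---------------------------------------------------------------------------
R_GAS = 8314.472          # mJ/(mol*K)
TEMP = 310.0              # K
FARADAY = 96485.3415      # C/mol
RTONF = R_GAS * TEMP / FARADAY   # mV

KO = 5.4                  # mM
CAO = 2.0                 # mM
NAO = 140.0               # mM

CAPACITANCE = 0.185       # uF, cell capacitance used in concentration balances
VC = 0.016404             # um^3 (scaled), cytoplasmic volume
VSR = 0.001094            # SR volume
VSS = 0.00005468          # subspace volume

BUFC, KBUFC = 0.2, 0.001
BUFSR, KBUFSR = 10.0, 0.3
BUFSS, KBUFSS = 0.4, 0.00025

VMAXUP, KUP = 0.006375, 0.00025
VREL, VLEAK, VXFER = 0.102, 0.00036, 0.0038
K1P, K2P, K3, K4 = 0.15, 0.045, 0.060, 0.005
MAXSR, MINSR, EC_SR = 2.5, 1.0, 1.5

PKNA = 0.03
G_K1 = 5.405
G_PCA, K_PCA = 0.1238, 0.0005
G_PK = 0.0146
G_BNA = 0.00029
G_BCA = 0.000592
P_NAK, KM_K, KM_NA = 2.724, 1.0, 40.0
K_NACA, KM_NAI, KM_CA, K_SAT, N_GAMMA, ALPHA_NACA = 1000.0, 87.5, 1.38, 0.1, 0.35, 2.5

# Maximal conductances (nS/pF); g_to and g_Ks are cell-subtype dependent.
G_NA = 14.838
G_CAL = 0.00003980
G_KR = 0.153
G_TO_EPI = 0.294
G_TO_ENDO = 0.073
G_TO_M = 0.294
G_KS_EPI = 0.392
G_KS_ENDO = 0.392
G_KS_M = 0.098

# Subtype codes
ENDO, MID, EPI = 0, 1, 2

# Published TP06 initial (approximately resting) state.
#   V, then gates m,h,j,d,f,f2,fCass,r,s,xr1,xr2,xs,
#   then concentrations Cai, CaSR, Cass, Nai, Ki and RyR adaptation R-bar.
V_INIT = -86.2
GATES_INIT = np.array(
    [0.0, 0.75, 0.75, 0.0, 1.0, 1.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0]
)
CONC_INIT = np.array([0.00007, 1.3, 0.00007, 7.67, 138.3, 1.0])

N_GATES = 12
N_CONC = 6

# Gate indices
IM, IH, IJ, ID, IF, IF2, IFCASS, IR, IS, IXR1, IXR2, IXS = range(12)
# Concentration indices
ICAI, ICASR, ICASS, INAI, IKI, IRBAR = range(6)

# Voltage-table layout
VT_MIN, VT_MAX, VT_STEP = -100.0, 100.0, 0.05
# columns (inf, exp(-dt/tau)) per gate, then current prefactors
(C_MINF, C_MEX, C_HINF, C_HEX, C_JINF, C_JEX, C_DINF, C_DEX, C_FINF, C_FEX,
 C_F2INF, C_F2EX, C_RINF, C_REX, C_XR1INF, C_XR1EX, C_XR2INF, C_XR2EX,
 C_XSINF, C_XSEX, C_SENDOINF, C_SENDOEX, C_SEPIINF, C_SEPIEX,
 C_ICALA, C_ICALB, C_NACA1, C_NACA2, C_INAK, C_IPKREC) = range(30)
N_COLS = 30

K1T_MIN, K1T_MAX, K1T_STEP = -150.0, 250.0, 0.05


def _gate_rates(v: float) -> dict:
    """Steady states and time constants (ms) of the 12 gates at potential v (mV)."""
    out = {}
    out["m_inf"] = 1.0 / (1.0 + math.exp((-56.86 - v) / 9.03)) ** 2
    am = 1.0 / (1.0 + math.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + math.exp((v + 35.0) / 5.0)) + 0.1 / (1.0 + math.exp((v - 50.0) / 200.0))
    out["tau_m"] = am * bm

    out["h_inf"] = 1.0 / (1.0 + math.exp((v + 71.55) / 7.43)) ** 2
    if v >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
    else:
        ah = 0.057 * math.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
    out["tau_h"] = 1.0 / (ah + bh)

    out["j_inf"] = out["h_inf"]
    if v >= -40.0:
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        aj = ((-2.5428e4 * math.exp(0.2444 * v) - 6.948e-6 * math.exp(-0.04391 * v))
              * (v + 37.78) / (1.0 + math.exp(0.311 * (v + 79.23))))
        bj = 0.02424 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    out["tau_j"] = 1.0 / (aj + bj)

    out["d_inf"] = 1.0 / (1.0 + math.exp((-8.0 - v) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((v + 5.0) / 5.0))
    gd = 1.0 / (1.0 + math.exp((50.0 - v) / 20.0))
    out["tau_d"] = ad * bd + gd

    out["f_inf"] = 1.0 / (1.0 + math.exp((v + 20.0) / 7.0))
    out["tau_f"] = (1102.5 * math.exp(-((v + 27.0) ** 2) / 225.0)
                    + 200.0 / (1.0 + math.exp((13.0 - v) / 10.0))
                    + 180.0 / (1.0 + math.exp((v + 30.0) / 10.0)) + 20.0)

    out["f2_inf"] = 0.67 / (1.0 + math.exp((v + 35.0) / 7.0)) + 0.33
    out["tau_f2"] = (562.0 * math.exp(-((v + 27.0) ** 2) / 240.0)
                     + 31.0 / (1.0 + math.exp((25.0 - v) / 10.0))
                     + 80.0 / (1.0 + math.exp((v + 30.0) / 10.0)))

    out["r_inf"] = 1.0 / (1.0 + math.exp((20.0 - v) / 6.0))
    out["tau_r"] = 9.5 * math.exp(-((v + 40.0) ** 2) / 1800.0) + 0.8

    out["s_endo_inf"] = 1.0 / (1.0 + math.exp((v + 28.0) / 5.0))
    out["tau_s_endo"] = 1000.0 * math.exp(-((v + 67.0) ** 2) / 1000.0) + 8.0
    out["s_epi_inf"] = 1.0 / (1.0 + math.exp((v + 20.0) / 5.0))
    out["tau_s_epi"] = (85.0 * math.exp(-((v + 45.0) ** 2) / 320.0)
                        + 5.0 / (1.0 + math.exp((v - 20.0) / 5.0)) + 3.0)

    out["xr1_inf"] = 1.0 / (1.0 + math.exp((-26.0 - v) / 7.0))
    axr1 = 450.0 / (1.0 + math.exp((-45.0 - v) / 10.0))
    bxr1 = 6.0 / (1.0 + math.exp((v + 30.0) / 11.5))
    out["tau_xr1"] = axr1 * bxr1

    out["xr2_inf"] = 1.0 / (1.0 + math.exp((v + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + math.exp((-60.0 - v) / 20.0))
    bxr2 = 1.12 / (1.0 + math.exp((v - 60.0) / 20.0))
    out["tau_xr2"] = axr2 * bxr2

    out["xs_inf"] = 1.0 / (1.0 + math.exp((-5.0 - v) / 14.0))
    axs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - v) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((v - 35.0) / 15.0))
    out["tau_xs"] = axs * bxs + 80.0
    return out


def _ical_drive(v: float) -> tuple[float, float]:
    """ICaL GHK-like driving terms A, B with ICaL = g * d f f2 fCass * (A*Cass - B)."""
    z = 2.0 * (v - 15.0) * FARADAY / (R_GAS * TEMP)
    if abs(z) < 1e-9:
        base = 2.0 * FARADAY
        ez = 1.0
    else:
        ez = math.exp(z)
        base = 4.0 * (v - 15.0) * FARADAY ** 2 / (R_GAS * TEMP) / (ez - 1.0)
    return base * 0.25 * ez, base * CAO


def make_tables(dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Build the (voltage, V-EK) lookup tables for time step dt (ms).

    Gate columns hold the steady state and exp(-dt/tau); current columns hold
    voltage-only prefactors of ICaL, INaCa, INaK and IpK.
    """
    nv = int(round((VT_MAX - VT_MIN) / VT_STEP)) + 1
    tab = np.empty((nv, N_COLS))
    den_naca = (KM_NAI ** 3 + NAO ** 3) * (KM_CA + CAO)
    for k in range(nv):
        v = VT_MIN + k * VT_STEP
        g = _gate_rates(v)
        tab[k, C_MINF] = g["m_inf"]; tab[k, C_MEX] = math.exp(-dt / g["tau_m"])
        tab[k, C_HINF] = g["h_inf"]; tab[k, C_HEX] = math.exp(-dt / g["tau_h"])
        tab[k, C_JINF] = g["j_inf"]; tab[k, C_JEX] = math.exp(-dt / g["tau_j"])
        tab[k, C_DINF] = g["d_inf"]; tab[k, C_DEX] = math.exp(-dt / g["tau_d"])
        tab[k, C_FINF] = g["f_inf"]; tab[k, C_FEX] = math.exp(-dt / g["tau_f"])
        tab[k, C_F2INF] = g["f2_inf"]; tab[k, C_F2EX] = math.exp(-dt / g["tau_f2"])
        tab[k, C_RINF] = g["r_inf"]; tab[k, C_REX] = math.exp(-dt / g["tau_r"])
        tab[k, C_XR1INF] = g["xr1_inf"]; tab[k, C_XR1EX] = math.exp(-dt / g["tau_xr1"])
        tab[k, C_XR2INF] = g["xr2_inf"]; tab[k, C_XR2EX] = math.exp(-dt / g["tau_xr2"])
        tab[k, C_XSINF] = g["xs_inf"]; tab[k, C_XSEX] = math.exp(-dt / g["tau_xs"])
        tab[k, C_SENDOINF] = g["s_endo_inf"]; tab[k, C_SENDOEX] = math.exp(-dt / g["tau_s_endo"])
        tab[k, C_SEPIINF] = g["s_epi_inf"]; tab[k, C_SEPIEX] = math.exp(-dt / g["tau_s_epi"])
        a, b = _ical_drive(v)
        tab[k, C_ICALA] = a
        tab[k, C_ICALB] = b
        e1 = math.exp(N_GAMMA * v / RTONF)
        e2 = math.exp((N_GAMMA - 1.0) * v / RTONF)
        den = den_naca * (1.0 + K_SAT * e2)
        tab[k, C_NACA1] = K_NACA * e1 * CAO / den
        tab[k, C_NACA2] = K_NACA * e2 * NAO ** 3 * ALPHA_NACA / den
        tab[k, C_INAK] = (P_NAK * KO / (KO + KM_K)
                          / (1.0 + 0.1245 * math.exp(-0.1 * v / RTONF)
                             + 0.0353 * math.exp(-v / RTONF)))
        tab[k, C_IPKREC] = 1.0 / (1.0 + math.exp((25.0 - v) / 5.98))

    nk = int(round((K1T_MAX - K1T_MIN) / K1T_STEP)) + 1
    k1tab = np.empty(nk)
    for k in range(nk):
        u = K1T_MIN + k * K1T_STEP
        a = 0.1 / (1.0 + math.exp(0.06 * (u - 200.0)))
        b = ((3.0 * math.exp(0.0002 * (u + 100.0)) + math.exp(0.1 * (u - 10.0)))
             / (1.0 + math.exp(-0.5 * u)))
        k1tab[k] = a / (a + b) * u
    return tab, k1tab


_TABLE_CACHE: dict[float, tuple[np.ndarray, np.ndarray]] = {}


def tables_for(dt: float) -> tuple[np.ndarray, np.ndarray]:
    key = round(float(dt), 12)
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = make_tables(dt)
    return _TABLE_CACHE[key]


@njit(cache=True, fastmath=True)
def advance(V, G, C, lap,
            svar, gna, gcal, gkr, gks, gto,
            nb, alpha, dt, n_steps, t0,
            stim_mask, stim_amp, stim_start, stim_stop,
            tab, k1tab,
            act_time, act_count, samp_every, exit_on_quiet, do_ionic,
            act_thr, active_thr):
    """Advance n coupled TP06 cells n_steps of length dt from absolute time t0 (ms).

    V (n,) membrane potential; G (12,n) gates; C (6,n) Cai,CaSR,Cass,Nai,Ki,Rbar.
    lap (n,) scratch. svar: 0 endo-type s-gate kinetics, 1 epi/M-type. gna..gto:
    per-node maximal conductances with subtype and infarct remodeling folded in
    (gkr already includes sqrt(Ko/5.4)).  nb (4,n): neighbour indices, self-index
    encodes a no-flux face.  alpha = D*dt/dx^2.  One stimulus window per call:
    stim_amp (pA/pF, negative = depolarizing) on nodes with stim_mask != 0 for the
    step range [stim_start, stim_stop) counted from t0; the stimulus current also
    enters the K+ balance, as in the reference model.

    act_time (n,): first upward crossing of act_thr (ms, -1 = none yet), updated
    in place.  act_count: nodes above active_thr sampled every samp_every steps.  If
    exit_on_quiet and a sample after the stimulus window is zero, returns early
    (no further activity is possible without a stimulus).  do_ionic=False gives a
    pure diffusion step (membrane frozen), used for numerical diagnostics.

    Returns (steps_done, blowup_index); blowup_index >= 0 flags a non-finite V.
    """
    n = V.shape[0]
    inv_vstep = 1.0 / VT_STEP
    inv_k1step = 1.0 / K1T_STEP
    nv = tab.shape[0]
    nk = k1tab.shape[0]
    gk1c = G_K1 * math.sqrt(KO / 5.4)
    cm_2vcf = CAPACITANCE / (2.0 * VC * FARADAY)
    cm_2vssf = CAPACITANCE / (2.0 * VSS * FARADAY)
    cm_vcf = CAPACITANCE / (VC * FARADAY)
    vsr_vc = VSR / VC
    vsr_vss = VSR / VSS
    vc_vss = VC / VSS

    n_samples = 0
    for step in range(n_steps):
        stim_on = (step >= stim_start) and (step < stim_stop)
        # diffusion pass (uses pre-step V everywhere)
        if alpha != 0.0:
            for i in range(n):
                lap[i] = alpha * (V[nb[0, i]] + V[nb[1, i]] + V[nb[2, i]]
                                  + V[nb[3, i]] - 4.0 * V[i])
        else:
            for i in range(n):
                lap[i] = 0.0
        if not do_ionic:
            for i in range(n):
                V[i] += lap[i]
        else:
            for i in range(n):
                v = V[i]
                # magnitude guard: fastmath folds NaN/inf-aware predicates, so
                # runaway potentials are caught by bound and NaNs by the driver
                if v > 1.0e6 or v < -1.0e6:
                    return step, i
                # table lookup with linear interpolation
                x = (v - VT_MIN) * inv_vstep
                if x < 0.0:
                    x = 0.0
                elif x > nv - 1.001:
                    x = nv - 1.001
                k = int(x)
                w = x - k
                t0r = tab[k]
                t1r = tab[k + 1]

                m = G[IM, i]; h = G[IH, i]; j = G[IJ, i]
                d = G[ID, i]; f = G[IF, i]; f2 = G[IF2, i]
                fcass = G[IFCASS, i]; r = G[IR, i]; s = G[IS, i]
                xr1 = G[IXR1, i]; xr2 = G[IXR2, i]; xs = G[IXS, i]
                cai = C[ICAI, i]; casr = C[ICASR, i]; cass = C[ICASS, i]
                nai = C[INAI, i]; ki = C[IKI, i]; rbar = C[IRBAR, i]

                ek = RTONF * math.log(KO / ki)
                ena = RTONF * math.log(NAO / nai)
                eks = RTONF * math.log((KO + PKNA * NAO) / (ki + PKNA * nai))
                eca = 0.5 * RTONF * math.log(CAO / cai)

                ina = gna[i] * m * m * m * h * j * (v - ena)
                a_cal = t0r[C_ICALA] + w * (t1r[C_ICALA] - t0r[C_ICALA])
                b_cal = t0r[C_ICALB] + w * (t1r[C_ICALB] - t0r[C_ICALB])
                ical = gcal[i] * d * f * f2 * fcass * (a_cal * cass - b_cal)
                u = v - ek
                y = (u - K1T_MIN) * inv_k1step
                if y < 0.0:
                    y = 0.0
                elif y > nk - 1.001:
                    y = nk - 1.001
                ky = int(y)
                wy = y - ky
                ik1 = gk1c * (k1tab[ky] + wy * (k1tab[ky + 1] - k1tab[ky]))
                ikr = gkr[i] * xr1 * xr2 * u
                iks = gks[i] * xs * xs * (v - eks)
                ito = gto[i] * r * s * u
                naca1 = t0r[C_NACA1] + w * (t1r[C_NACA1] - t0r[C_NACA1])
                naca2 = t0r[C_NACA2] + w * (t1r[C_NACA2] - t0r[C_NACA2])
                inaca = naca1 * nai * nai * nai - naca2 * cai
                inakv = t0r[C_INAK] + w * (t1r[C_INAK] - t0r[C_INAK])
                inak = inakv * nai / (nai + KM_NA)
                ipca = G_PCA * cai / (cai + K_PCA)
                ipkr = t0r[C_IPKREC] + w * (t1r[C_IPKREC] - t0r[C_IPKREC])
                ipk = G_PK * ipkr * u
                ibna = G_BNA * (v - ena)
                ibca = G_BCA * (v - eca)

                istim = stim_amp if (stim_on and stim_mask[i] != 0) else 0.0

                # Ca release / uptake subsystem
                kcasr = MAXSR - (MAXSR - MINSR) / (1.0 + (EC_SR / casr) ** 2)
                k1rel = K1P / kcasr
                k2rel = K2P * kcasr
                rbar += dt * (-k2rel * cass * rbar + K4 * (1.0 - rbar))
                oo = k1rel * cass * cass * rbar / (K3 + k1rel * cass * cass)
                irel = VREL * oo * (casr - cass)
                ileak = VLEAK * (casr - cai)
                iup = VMAXUP / (1.0 + (KUP / cai) ** 2)
                ixfer = VXFER * (cass - cai)

                bufc = 1.0 / (1.0 + BUFC * KBUFC / ((cai + KBUFC) * (cai + KBUFC)))
                dcai = bufc * ((ileak - iup) * vsr_vc + ixfer
                               - (ibca + ipca - 2.0 * inaca) * cm_2vcf)
                bufsr = 1.0 / (1.0 + BUFSR * KBUFSR / ((casr + KBUFSR) * (casr + KBUFSR)))
                dcasr = bufsr * (iup - irel - ileak)
                bufss = 1.0 / (1.0 + BUFSS * KBUFSS / ((cass + KBUFSS) * (cass + KBUFSS)))
                dcass = bufss * (-ical * cm_2vssf + irel * vsr_vss - ixfer * vc_vss)
                dnai = -(ina + ibna + 3.0 * inak + 3.0 * inaca) * cm_vcf
                dki = -(ik1 + ito + ikr + iks - 2.0 * inak + ipk + istim) * cm_vcf

                C[ICAI, i] = cai + dt * dcai
                C[ICASR, i] = casr + dt * dcasr
                C[ICASS, i] = cass + dt * dcass
                C[INAI, i] = nai + dt * dnai
                C[IKI, i] = ki + dt * dki
                C[IRBAR, i] = rbar

                # Rush-Larsen gate updates
                G[IM, i] = t0r[C_MINF] + w * (t1r[C_MINF] - t0r[C_MINF]) \
                    + (m - (t0r[C_MINF] + w * (t1r[C_MINF] - t0r[C_MINF]))) \
                    * (t0r[C_MEX] + w * (t1r[C_MEX] - t0r[C_MEX]))
                hinf = t0r[C_HINF] + w * (t1r[C_HINF] - t0r[C_HINF])
                G[IH, i] = hinf + (h - hinf) * (t0r[C_HEX] + w * (t1r[C_HEX] - t0r[C_HEX]))
                jinf = t0r[C_JINF] + w * (t1r[C_JINF] - t0r[C_JINF])
                G[IJ, i] = jinf + (j - jinf) * (t0r[C_JEX] + w * (t1r[C_JEX] - t0r[C_JEX]))
                dinf = t0r[C_DINF] + w * (t1r[C_DINF] - t0r[C_DINF])
                G[ID, i] = dinf + (d - dinf) * (t0r[C_DEX] + w * (t1r[C_DEX] - t0r[C_DEX]))
                finf = t0r[C_FINF] + w * (t1r[C_FINF] - t0r[C_FINF])
                G[IF, i] = finf + (f - finf) * (t0r[C_FEX] + w * (t1r[C_FEX] - t0r[C_FEX]))
                f2inf = t0r[C_F2INF] + w * (t1r[C_F2INF] - t0r[C_F2INF])
                G[IF2, i] = f2inf + (f2 - f2inf) * (t0r[C_F2EX] + w * (t1r[C_F2EX] - t0r[C_F2EX]))
                rinf = t0r[C_RINF] + w * (t1r[C_RINF] - t0r[C_RINF])
                G[IR, i] = rinf + (r - rinf) * (t0r[C_REX] + w * (t1r[C_REX] - t0r[C_REX]))
                if svar[i] == 0:
                    sinf = t0r[C_SENDOINF] + w * (t1r[C_SENDOINF] - t0r[C_SENDOINF])
                    sex = t0r[C_SENDOEX] + w * (t1r[C_SENDOEX] - t0r[C_SENDOEX])
                else:
                    sinf = t0r[C_SEPIINF] + w * (t1r[C_SEPIINF] - t0r[C_SEPIINF])
                    sex = t0r[C_SEPIEX] + w * (t1r[C_SEPIEX] - t0r[C_SEPIEX])
                G[IS, i] = sinf + (s - sinf) * sex
                xr1inf = t0r[C_XR1INF] + w * (t1r[C_XR1INF] - t0r[C_XR1INF])
                G[IXR1, i] = xr1inf + (xr1 - xr1inf) * (t0r[C_XR1EX] + w * (t1r[C_XR1EX] - t0r[C_XR1EX]))
                xr2inf = t0r[C_XR2INF] + w * (t1r[C_XR2INF] - t0r[C_XR2INF])
                G[IXR2, i] = xr2inf + (xr2 - xr2inf) * (t0r[C_XR2EX] + w * (t1r[C_XR2EX] - t0r[C_XR2EX]))
                xsinf = t0r[C_XSINF] + w * (t1r[C_XSINF] - t0r[C_XSINF])
                G[IXS, i] = xsinf + (xs - xsinf) * (t0r[C_XSEX] + w * (t1r[C_XSEX] - t0r[C_XSEX]))
                # fCass: Ca-dependent, forward Euler (tau >= 2 ms)
                css2 = (cass / 0.05) ** 2
                fcinf = 0.6 / (1.0 + css2) + 0.4
                taufc = 80.0 / (1.0 + css2) + 2.0
                G[IFCASS, i] = fcass + dt * (fcinf - fcass) / taufc

                iion = (ina + ik1 + ito + ikr + iks + ical + inaca + inak
                        + ipca + ipk + ibna + ibca)
                vnew = v + lap[i] - dt * (iion + istim)
                V[i] = vnew
                if act_time[i] < 0.0 and v <= act_thr and vnew > act_thr:
                    act_time[i] = t0 + (step + 1) * dt

        if samp_every > 0 and (step + 1) % samp_every == 0:
            cnt = 0
            for i in range(n):
                if V[i] > active_thr:
                    cnt += 1
            act_count[n_samples] = cnt
            n_samples += 1
            if exit_on_quiet and cnt == 0 and step >= stim_stop:
                return step + 1, -1
    return n_steps, -1
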