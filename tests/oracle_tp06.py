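"""Independent TP06 reference integration used only as a test oracle.

A literal scalar transcription of the published model equations, integrated
with scipy's implicit BDF solver.  Shares no code with the production kernel
(no lookup tables, no Rush-Larsen splitting, different state ordering), so
agreement between the two routes is a meaningful cross-check of both.
"""

import numpy as np
from scipy.integrate import solve_ivp

R = 8314.472
T = 310.0
F = 96485.3415
RTF = R * T / F

Ko, Cao, Nao = 5.4, 2.0, 140.0
Cm, Vc, Vsr, Vss = 0.185, 0.016404, 0.001094, 0.00005468
Bufc, Kbufc, Bufsr, Kbufsr, Bufss, Kbufss = 0.2, 0.001, 10.0, 0.3, 0.4, 0.00025
Vmaxup, Kup = 0.006375, 0.00025
Vrel, Vleak, Vxfer = 0.102, 0.00036, 0.0038
k1p, k2p, k3, k4 = 0.15, 0.045, 0.060, 0.005
maxsr, minsr, EC = 2.5, 1.0, 1.5
pKNa = 0.03
GK1, GpCa, KpCa, GpK, GbNa, GbCa = 5.405, 0.1238, 0.0005, 0.0146, 0.00029, 0.000592
PNaK, KmK, KmNa = 2.724, 1.0, 40.0
knaca, KmNai, KmCa, ksat, gam, alf = 1000.0, 87.5, 1.38, 0.1, 0.35, 2.5
GNa, GCaL, GKr = 14.838, 0.00003980, 0.153

SUBTYPE_G = {  # (g_to, g_Ks)
    "ENDO": (0.073, 0.392),
    "M": (0.294, 0.098),
    "EPI": (0.294, 0.392),
}

# state order: V, m, h, j, d, f, f2, fCass, r, s, xr1, xr2, xs,
#              Cai, CaSR, Cass, Nai, Ki, Rbar
Y0 = np.array([-86.2, 0.0, 0.75, 0.75, 0.0, 1.0, 1.0, 1.0, 0.0, 1.0, 0.0, 1.0,
               0.0, 0.00007, 1.3, 0.00007, 7.67, 138.3, 1.0])


def rhs(t, y, subtype="M", scale=(1.0, 1.0, 1.0, 1.0), i_stim=0.0):
    (V, m, h, j, d, f, f2, fcass, r, s, xr1, xr2, xs,
     Cai, CaSR, Cass, Nai, Ki, Rb) = y
    fna, fcal, fkr, fks = scale
    gto, gks = SUBTYPE_G[subtype]

    EK = RTF * np.log(Ko / Ki)
    ENa = RTF * np.log(Nao / Nai)
    EKs = RTF * np.log((Ko + pKNa * Nao) / (Ki + pKNa * Nai))
    ECa = 0.5 * RTF * np.log(Cao / Cai)

    INa = GNa * fna * m ** 3 * h * j * (V - ENa)
    z = 2.0 * (V - 15.0) / RTF
    if abs(z) < 1e-7:
        drive = 2.0 * F * (0.25 * Cass - Cao)
    else:
        drive = (4.0 * (V - 15.0) * F / RTF / (np.exp(z) - 1.0)
                 * (0.25 * np.exp(z) * Cass - Cao))
    ICaL = GCaL * fcal * d * f * f2 * fcass * drive
    ak1 = 0.1 / (1.0 + np.exp(0.06 * (V - EK - 200.0)))
    bk1 = ((3.0 * np.exp(0.0002 * (V - EK + 100.0)) + np.exp(0.1 * (V - EK - 10.0)))
           / (1.0 + np.exp(-0.5 * (V - EK))))
    IK1 = GK1 * np.sqrt(Ko / 5.4) * ak1 / (ak1 + bk1) * (V - EK)
    IKr = GKr * fkr * np.sqrt(Ko / 5.4) * xr1 * xr2 * (V - EK)
    IKs = gks * fks * xs ** 2 * (V - EKs)
    Ito = gto * r * s * (V - EK)
    INaCa = (knaca
             * (np.exp(gam * V / RTF) * Nai ** 3 * Cao
                - np.exp((gam - 1.0) * V / RTF) * Nao ** 3 * Cai * alf)
             / ((KmNai ** 3 + Nao ** 3) * (KmCa + Cao)
                * (1.0 + ksat * np.exp((gam - 1.0) * V / RTF))))
    INaK = (PNaK * Ko * Nai
            / ((Ko + KmK) * (Nai + KmNa))
            / (1.0 + 0.1245 * np.exp(-0.1 * V / RTF) + 0.0353 * np.exp(-V / RTF)))
    IpCa = GpCa * Cai / (Cai + KpCa)
    IpK = GpK * (V - EK) / (1.0 + np.exp((25.0 - V) / 5.98))
    IbNa = GbNa * (V - ENa)
    IbCa = GbCa * (V - ECa)

    Iion = (INa + IK1 + Ito + IKr + IKs + ICaL + INaCa + INaK + IpCa + IpK
            + IbNa + IbCa)

    # gates
    minf = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    taum = (1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
            * (0.1 / (1.0 + np.exp((V + 35.0) / 5.0))
               + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0))))
    hinf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    if V >= -40.0:
        tauh = 1.0 / (0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))))
    else:
        ah = 0.057 * np.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V)
        tauh = 1.0 / (ah + bh)
    jinf = hinf
    if V >= -40.0:
        tauj = (1.0 + np.exp(-0.1 * (V + 32.0))) / (0.6 * np.exp(0.057 * V))
    else:
        aj = ((-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
              * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))))
        bj = (0.02424 * np.exp(-0.01052 * V)
              / (1.0 + np.exp(-0.1378 * (V + 40.14))))
        tauj = 1.0 / (aj + bj)
    dinf = 1.0 / (1.0 + np.exp((-8.0 - V) / 7.5))
    taud = ((1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25)
            * (1.4 / (1.0 + np.exp((V + 5.0) / 5.0)))
            + 1.0 / (1.0 + np.exp((50.0 - V) / 20.0)))
    finf = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tauf = (1102.5 * np.exp(-((V + 27.0) ** 2) / 225.0)
            + 200.0 / (1.0 + np.exp((13.0 - V) / 10.0))
            + 180.0 / (1.0 + np.exp((V + 30.0) / 10.0)) + 20.0)
    f2inf = 0.67 / (1.0 + np.exp((V + 35.0) / 7.0)) + 0.33
    tauf2 = (562.0 * np.exp(-((V + 27.0) ** 2) / 240.0)
             + 31.0 / (1.0 + np.exp((25.0 - V) / 10.0))
             + 80.0 / (1.0 + np.exp((V + 30.0) / 10.0)))
    fcassinf = 0.6 / (1.0 + (Cass / 0.05) ** 2) + 0.4
    taufcass = 80.0 / (1.0 + (Cass / 0.05) ** 2) + 2.0
    rinf = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    taur = 9.5 * np.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8
    if subtype == "ENDO":
        sinf = 1.0 / (1.0 + np.exp((V + 28.0) / 5.0))
        taus = 1000.0 * np.exp(-((V + 67.0) ** 2) / 1000.0) + 8.0
    else:
        sinf = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
        taus = (85.0 * np.exp(-((V + 45.0) ** 2) / 320.0)
                + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0)) + 3.0)
    xr1inf = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    tauxr1 = (450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
              * 6.0 / (1.0 + np.exp((V + 30.0) / 11.5)))
    xr2inf = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    tauxr2 = (3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
              * 1.12 / (1.0 + np.exp((V - 60.0) / 20.0)))
    xsinf = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    tauxs = (1400.0 / np.sqrt(1.0 + np.exp((5.0 - V) / 6.0))
             * 1.0 / (1.0 + np.exp((V - 35.0) / 15.0)) + 80.0)

    # Ca subsystem
    kcasr = maxsr - (maxsr - minsr) / (1.0 + (EC / CaSR) ** 2)
    k1 = k1p / kcasr
    k2 = k2p * kcasr
    dRb = -k2 * Cass * Rb + k4 * (1.0 - Rb)
    O = k1 * Cass ** 2 * Rb / (k3 + k1 * Cass ** 2)
    Irel = Vrel * O * (CaSR - Cass)
    Ileak = Vleak * (CaSR - Cai)
    Iup = Vmaxup / (1.0 + (Kup / Cai) ** 2)
    Ixfer = Vxfer * (Cass - Cai)

    bc = 1.0 / (1.0 + Bufc * Kbufc / (Cai + Kbufc) ** 2)
    dCai = bc * ((Ileak - Iup) * Vsr / Vc + Ixfer
                 - (IbCa + IpCa - 2.0 * INaCa) * Cm / (2.0 * Vc * F))
    bsr = 1.0 / (1.0 + Bufsr * Kbufsr / (CaSR + Kbufsr) ** 2)
    dCaSR = bsr * (Iup - Irel - Ileak)
    bss = 1.0 / (1.0 + Bufss * Kbufss / (Cass + Kbufss) ** 2)
    dCass = bss * (-ICaL * Cm / (2.0 * Vss * F) + Irel * Vsr / Vss
                   - Ixfer * Vc / Vss)
    dNai = -(INa + IbNa + 3.0 * INaK + 3.0 * INaCa) * Cm / (Vc * F)
    dKi = -(IK1 + Ito + IKr + IKs - 2.0 * INaK + IpK + i_stim) * Cm / (Vc * F)

    return [
        -(Iion + i_stim),
        (minf - m) / taum, (hinf - h) / tauh, (jinf - j) / tauj,
        (dinf - d) / taud, (finf - f) / tauf, (f2inf - f2) / tauf2,
        (fcassinf - fcass) / taufcass, (rinf - r) / taur, (sinf - s) / taus,
        (xr1inf - xr1) / tauxr1, (xr2inf - xr2) / tauxr2, (xsinf - xs) / tauxs,
        dCai, dCaSR, dCass, dNai, dKi, dRb,
    ]


def _solve(y0, t_span, subtype, scale, i_stim, t_eval=None):
    sol = solve_ivp(rhs, t_span, y0, method="BDF", t_eval=t_eval,
                    args=(subtype, scale, i_stim), rtol=1e-6, atol=1e-8,
                    max_step=5.0)
    if not sol.success:
        raise RuntimeError(f"oracle integration failed: {sol.message}")
    return sol


def resting_vm(subtype="M", scale=(1.0, 1.0, 1.0, 1.0), settle_ms=3000.0):
    """Membrane potential after settling unstimulated from the published state."""
    sol = _solve(Y0, (0.0, settle_ms), subtype, scale, 0.0)
    return float(sol.y[0, -1])


def paced_beat(subtype="M", scale=(1.0, 1.0, 1.0, 1.0), bcl=1000.0, n_beats=5,
               stim=-52.0, stim_ms=1.0, record_dt=0.5):
    """Pace n_beats and return (t, V) of the final beat, t relative to its onset."""
    y = Y0.copy()
    t = v = None
    for b in range(n_beats):
        record = b == n_beats - 1
        sol = _solve(y, (0.0, stim_ms), subtype, scale, stim,
                     t_eval=np.arange(0.0, stim_ms + 1e-9, record_dt) if record else None)
        y = sol.y[:, -1]
        sol2 = _solve(y, (stim_ms, bcl), subtype, scale, 0.0,
                      t_eval=np.arange(stim_ms, bcl + 1e-9, record_dt) if record else None)
        y = sol2.y[:, -1]
        if record:
            t = np.concatenate([sol.t, sol2.t[1:]])
            v = np.concatenate([sol.y[0], sol2.y[0, 1:]])
    return t, v
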