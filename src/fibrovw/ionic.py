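"""Single-cell interface to the TP06 human ventricular myocyte model.

Exposes the parameter set (with the infarct ionic remodeling used throughout the
tissue studies), the state container, a one-step integrator and a steady-state
pacing routine.  Infarct remodeling scales the four maximal conductances that
carry the remodeled peak currents: I_Na to 38%, I_CaL to 31%, I_Kr to 30% and
I_Ks to 20% of their reference values; all other parameters are untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _tp06_core as core

SUBTYPES = ("ENDO", "M", "EPI")

# Infarct remodeling fractions (remodeled peak current / normal peak current)
REMODEL_F_NA = 0.38
REMODEL_F_CAL = 0.31
REMODEL_F_KR = 0.30
REMODEL_F_KS = 0.20


class NumericalBlowupError(RuntimeError):
    """Raised when the integrator produces a non-finite quantity."""


@dataclass(frozen=True)
class CellParams:
    """TP06 parameter set for one cell subtype plus infarct remodeling fractions.

    ``gNa_max`` etc. are the reference maximal conductances (nS/pF); the
    effective, possibly remodeled conductances are the ``g_na`` ... properties.
    ``c_m`` is the membrane capacitance of the monodomain equation (uF/cm^2);
    TP06 currents are expressed per capacitance (pA/pF) so I_ion/C_m has units
    mV/ms directly.
    """

    subtype: str
    gNa_max: float = core.G_NA
    gCaL_max: float = core.G_CAL
    gKr_max: float = core.G_KR
    gKs_max: float = field(default=0.0)
    gTo_max: float = field(default=0.0)
    gK1_max: float = core.G_K1
    p_NaK: float = core.P_NAK
    k_NaCa: float = core.K_NACA
    gpCa_max: float = core.G_PCA
    gpK_max: float = core.G_PK
    gbNa_max: float = core.G_BNA
    gbCa_max: float = core.G_BCA
    f_na: float = 1.0
    f_cal: float = 1.0
    f_kr: float = 1.0
    f_ks: float = 1.0
    c_m: float = 1.0

    def __post_init__(self):
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown cell subtype {self.subtype!r}; expected one of {SUBTYPES}")
        for name in ("f_na", "f_cal", "f_kr", "f_ks"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"remodeling fraction {name}={v} outside [0, 1]")
        for name in ("gNa_max", "gCaL_max", "gKr_max", "gKs_max", "gTo_max", "gK1_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative conductance {name}")

    # effective (remodeled) maximal conductances
    @property
    def g_na(self) -> float:
        return self.gNa_max * self.f_na

    @property
    def g_cal(self) -> float:
        return self.gCaL_max * self.f_cal

    @property
    def g_kr(self) -> float:
        return self.gKr_max * self.f_kr

    @property
    def g_ks(self) -> float:
        return self.gKs_max * self.f_ks

    @property
    def g_to(self) -> float:
        return self.gTo_max

    @property
    def subtype_index(self) -> int:
        return SUBTYPES.index(self.subtype)

    @property
    def s_gate_variant(self) -> int:
        """0 = endocardial s-gate kinetics, 1 = epicardial/mid kinetics."""
        return 0 if self.subtype == "ENDO" else 1


def make_cell_params(subtype: str, remodeled: bool = False) -> CellParams:
    """Reference TP06 parameters for ``subtype``, optionally with infarct remodeling.

    ``remodeled=True`` applies the multiplicative down-scaling of the four
    remodeled currents (f_Na=0.38, f_CaL=0.31, f_Kr=0.30, f_Ks=0.20);
    ``remodeled=False`` returns the normal cell (all fractions 1).
    """
    if subtype not in SUBTYPES:
        raise ValueError(f"unknown cell subtype {subtype!r}; expected one of {SUBTYPES}")
    gto = {"ENDO": core.G_TO_ENDO, "M": core.G_TO_M, "EPI": core.G_TO_EPI}[subtype]
    gks = {"ENDO": core.G_KS_ENDO, "M": core.G_KS_M, "EPI": core.G_KS_EPI}[subtype]
    p = CellParams(subtype=subtype, gKs_max=gks, gTo_max=gto)
    if remodeled:
        p = replace(p, f_na=REMODEL_F_NA, f_cal=REMODEL_F_CAL,
                    f_kr=REMODEL_F_KR, f_ks=REMODEL_F_KS)
    return p


_STATE_FIELDS = ("vm", "m", "h", "j", "d", "f", "f2", "fcass", "r", "s",
                 "xr1", "xr2", "xs", "cai", "casr", "cass", "nai", "ki", "rbar")


@dataclass
class IonicState:
    """Full TP06 state: membrane potential, 12 gates, 5 concentrations and R-bar."""

    vm: float = core.V_INIT
    m: float = 0.0
    h: float = 0.75
    j: float = 0.75
    d: float = 0.0
    f: float = 1.0
    f2: float = 1.0
    fcass: float = 1.0
    r: float = 0.0
    s: float = 1.0
    xr1: float = 0.0
    xr2: float = 1.0
    xs: float = 0.0
    cai: float = 0.00007
    casr: float = 1.3
    cass: float = 0.00007
    nai: float = 7.67
    ki: float = 138.3
    rbar: float = 1.0

    def validate(self) -> None:
        for name in _STATE_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise NumericalBlowupError(f"non-finite state quantity {name!r} = {v}")
        for g in ("m", "h", "j", "d", "f", "f2", "fcass", "r", "s", "xr1", "xr2", "xs"):
            v = getattr(self, g)
            if not -1e-9 <= v <= 1.0 + 1e-9:
                raise ValueError(f"gate {g}={v} outside [0, 1]")
        for c in ("cai", "casr", "cass", "nai", "ki"):
            if getattr(self, c) <= 0:
                raise ValueError(f"non-positive concentration {c}")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        V = np.array([self.vm])
        G = np.array([[self.m], [self.h], [self.j], [self.d], [self.f], [self.f2],
                      [self.fcass], [self.r], [self.s], [self.xr1], [self.xr2], [self.xs]])
        C = np.array([[self.cai], [self.casr], [self.cass], [self.nai], [self.ki], [self.rbar]])
        return V, G, C

    @classmethod
    def from_arrays(cls, V, G, C, i: int = 0) -> "IonicState":
        g = [float(G[k, i]) for k in range(12)]
        c = [float(C[k, i]) for k in range(6)]
        return cls(float(V[i]), *g, *c)

    def to_text(self) -> str:
        return "".join(f"{k} = {float(getattr(self, k))!r}\n" for k in _STATE_FIELDS)

    @classmethod
    def from_text(cls, text: str) -> "IonicState":
        kv = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            kv[k.strip()] = float(v)
        return cls(**kv)


def _run_cell(V, G, C, params: CellParams, dt: float, n_steps: int, t0: float,
              stim_amp: float, stim_start_step: int, stim_stop_step: int,
              act_time=None):
    tab, k1tab = core.tables_for(dt)
    n = V.shape[0]
    lap = np.zeros(n)
    nb = np.zeros((4, n), dtype=np.int64)
    svar = np.full(n, params.s_gate_variant, dtype=np.int8)
    gna = np.full(n, params.g_na)
    gcal = np.full(n, params.g_cal)
    gkr = np.full(n, params.g_kr * math.sqrt(core.KO / 5.4))
    gks = np.full(n, params.g_ks)
    gto = np.full(n, params.g_to)
    stim_mask = np.ones(n, dtype=np.uint8)
    if act_time is None:
        act_time = np.full(n, -1.0)
    act_count = np.zeros(1, dtype=np.int64)
    done, bad = core.advance(V, G, C, lap, svar, gna, gcal, gkr, gks, gto,
                             nb, 0.0, dt, n_steps, t0,
                             stim_mask, stim_amp, stim_start_step, stim_stop_step,
                             tab, k1tab, act_time, act_count, 0, False, True,
                             0.0, -40.0)
    if bad >= 0:
        raise NumericalBlowupError(
            f"non-finite membrane potential at t = {t0 + done * dt:.3f} ms")
    return act_time


def step_ionic(state: IonicState, params: CellParams, dt: float,
               i_stim: float = 0.0) -> IonicState:
    """Advance one cell by dt (ms) under stimulus current i_stim (pA/pF, negative
    = depolarizing).  dt must not exceed 0.02 ms; dt = 0 returns the state
    unchanged."""
    if dt < 0 or dt > 0.02:
        raise ValueError(f"dt={dt} ms outside (0, 0.02] stability range")
    state.validate()
    V, G, C = state.as_arrays()
    if dt == 0.0:
        return IonicState.from_arrays(V, G, C)
    _run_cell(V, G, C, params, dt, 1, 0.0, i_stim, 0, 1)
    return IonicState.from_arrays(V, G, C)


@dataclass
class PacingResult:
    """Final-beat voltage trace and end state of a steady-state pacing run."""

    time: np.ndarray            # ms, relative to final-beat stimulus onset
    vm: np.ndarray              # mV
    final_state: IonicState
    apd90_per_beat: dict        # beat number -> APD90 (ms), recorded beats only
    excited: bool               # True if every recorded beat reached Vm > 0
    bcl: float
    n_beats: int

    @property
    def apd90(self) -> float:
        return self.apd90_per_beat[self.n_beats]


def apd90_of_trace(t: np.ndarray, v: np.ndarray) -> float:
    """Action-potential duration at 90% repolarization from one beat's trace.

    Measured between the upward and downward crossings of
    V90 = V_peak - 0.9 * (V_peak - V_rest), with V_rest the pre-stimulus
    potential; crossings located by linear interpolation.  NaN if the beat
    never depolarizes above 0 mV or never repolarizes to V90.
    """
    v_rest = v[0]
    v_peak = float(np.max(v))
    if v_peak <= 0.0:
        return float("nan")
    v90 = v_peak - 0.9 * (v_peak - v_rest)
    up = np.nonzero((v[:-1] <= v90) & (v[1:] > v90))[0]
    if up.size == 0:
        return float("nan")
    iu = up[0]
    t_up = t[iu] + (t[iu + 1] - t[iu]) * (v90 - v[iu]) / (v[iu + 1] - v[iu])
    ipk = int(np.argmax(v))
    down = np.nonzero((v[ipk:-1] >= v90) & (v[ipk + 1:] < v90))[0]
    if down.size == 0:
        return float("nan")
    k = ipk + down[0]
    t_dn = t[k] + (t[k + 1] - t[k]) * (v90 - v[k]) / (v[k + 1] - v[k])
    return float(t_dn - t_up)


def pace_single_cell(params: CellParams, bcl: float = 1000.0, n_beats: int = 100,
                     dt: float = 0.02, stim_amp: float = -52.0,
                     stim_duration: float = 1.0, record_beats: int = 2,
                     record_dt: float = 0.1) -> PacingResult:
    """Pace one cell to steady state: ``n_beats`` stimuli at cycle length ``bcl``.

    Only the last ``record_beats`` beats are recorded (voltage at ``record_dt``
    resolution) and APD90-measured; earlier beats run at full speed.  A beat
    that never reaches Vm > 0 sets ``excited=False`` on the result rather than
    raising.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    state = IonicState()
    V, G, C = state.as_arrays()
    steps_per_beat = int(round(bcl / dt))
    stim_steps = int(round(stim_duration / dt))
    record_beats = min(record_beats, n_beats)
    n_fast = n_beats - record_beats
    for b in range(n_fast):
        _run_cell(V, G, C, params, dt, steps_per_beat, b * bcl,
                  stim_amp, 0, stim_steps)

    rec_every = max(1, int(round(record_dt / dt)))
    apd = {}
    excited = True
    time = vm = None
    for b in range(n_fast, n_beats):
        n_chunks = steps_per_beat // rec_every
        tr = np.empty(n_chunks + 1)
        vr = np.empty(n_chunks + 1)
        tr[0], vr[0] = 0.0, V[0]
        act = np.full(1, -1.0)
        for c in range(n_chunks):
            s0 = c * rec_every
            _run_cell(V, G, C, params, dt, rec_every, b * bcl + s0 * dt,
                      stim_amp, -s0, stim_steps - s0, act_time=act)
            tr[c + 1] = (c + 1) * rec_every * dt
            vr[c + 1] = V[0]
        a = apd90_of_trace(tr, vr)
        apd[b + 1] = a
        if act[0] < 0:
            excited = False
        time, vm = tr, vr

    return PacingResult(time=time, vm=vm, final_state=IonicState.from_arrays(V, G, C),
                        apd90_per_beat=apd, excited=excited, bcl=bcl, n_beats=n_beats)


def write_ap_trace(path, t: np.ndarray, vm: np.ndarray) -> None:
    """Write an AP trace as a two-column CSV (time_ms, Vm_mV)."""
    arr = np.column_stack([t, vm])
    np.savetxt(path, arr, delimiter=",", header="time_ms,Vm_mV", comments="")
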