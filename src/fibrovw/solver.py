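"""Isotropic monodomain reaction-diffusion solver on a TissueGrid.

The membrane equation dVm/dt = D * lap(Vm) - I_ion is integrated by forward
Euler with a 5-point Laplacian.  No-flux (Neumann) closure holds at domain
edges and at every face shared with a FIBROTIC or VOID node; it is implemented
by self-substitution in the neighbour stencil (mirroring), which makes the
diffusion operator exactly conservative over the excitable nodes.  TP06
currents are in pA/pF, numerically equal to mV/ms at C_m = 1 uF/cm^2, so I_ion
is applied without further capacitance scaling; the stimulus current uses the
same convention (negative amplitude depolarizes).

Only NORMAL and INFARCT nodes carry membrane state; INFARCT nodes use the
remodeled TP06 parameter set.  FIBROTIC and VOID nodes have no state and
contribute zero flux, which is the zero-sided-coupling model of fibrosis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _tp06_core as core
from .geometry import Label, TissueGrid
from .ionic import CellParams, IonicState, NumericalBlowupError, make_cell_params


@dataclass
class SolverConfig:
    """Numerical configuration of a tissue run.

    D in mm^2/ms, dt in ms, duration in ms.  ``activation_threshold`` defines
    activation maps (first upward crossing), ``activity_threshold`` the "active
    fraction" used for reentry detection; both in mV.
    """

    D: float = 0.154
    dt: float = 0.02
    duration: float = 1000.0
    dim: int = 2
    snapshot_stride: float = 0.0    # ms between Vm snapshots; 0 = none
    sample_every: float = 1.0       # ms between active-fraction samples
    activation_threshold: float = 0.0
    activity_threshold: float = -40.0


@dataclass
class StabilityReport:
    ratio: float
    bound: float

    @property
    def ok(self) -> bool:
        return self.ratio < self.bound

    @property
    def margin(self) -> float:
        return self.bound - self.ratio


def check_stability(config: SolverConfig, dx: float) -> StabilityReport:
    """Forward-Euler diffusion stability: D*dt/dx^2 must stay below 1/(2d)."""
    ratio = config.D * config.dt / dx ** 2
    return StabilityReport(ratio=ratio, bound=1.0 / (2.0 * config.dim))


@dataclass
class Recording:
    """Time series and maps collected during a tissue run."""

    sample_times: np.ndarray        # ms
    active_fraction: np.ndarray     # fraction of excitable nodes above threshold
    activation_map: np.ndarray      # ms of first Vm>0 crossing, NaN = never (2D)
    snapshots: list                 # (t_ms, Vm 2D array with NaN off-tissue)
    duration: float                 # ms actually simulated
    n_excitable: int
    early_exit: bool = False

    def active_fraction_at(self, t: float) -> float:
        """Active fraction at the latest sample not later than t (0 if
        simulation quiesced and exited before t)."""
        if self.sample_times.size == 0:
            return 0.0
        k = np.searchsorted(self.sample_times, t + 1e-9) - 1
        if k < 0:
            return float(self.active_fraction[0])
        if t > self.sample_times[-1] + 1e-9:
            return 0.0 if self.early_exit else float(self.active_fraction[-1])
        return float(self.active_fraction[k])

    def save_npz(self, path) -> None:
        snaps_t = np.array([t for t, _ in self.snapshots])
        snaps_v = (np.stack([v for _, v in self.snapshots])
                   if self.snapshots else np.empty((0, 0, 0)))
        np.savez_compressed(path, sample_times=self.sample_times,
                            active_fraction=self.active_fraction,
                            activation_map=self.activation_map,
                            snapshot_times=snaps_t, snapshots=snaps_v,
                            duration=self.duration, n_excitable=self.n_excitable,
                            early_exit=self.early_exit)


class MonodomainTissue:
    """Mutable simulation state of one tissue: the FieldState of the model.

    Construction precomputes the excitable-node arrays, neighbour stencil and
    per-node TP06 parameters; `run` advances the state through stimulus
    protocols.  `save_state` / `load_state` give cheap checkpointing, which the
    S1-S2 scan uses to share the S1 prefix across coupling intervals.
    """

    def __init__(self, grid: TissueGrid, config: SolverConfig,
                 subtype_map: np.ndarray | None = None,
                 init_states: dict | None = None):
        rep = check_stability(config, grid.dx)
        if not rep.ok:
            raise ValueError(
                f"unstable configuration: D*dt/dx^2 = {rep.ratio:.5g} >= {rep.bound}")
        self.grid = grid
        self.config = config
        labels = grid.labels
        ny, nx = labels.shape
        excitable = (labels == Label.NORMAL) | (labels == Label.INFARCT)
        self.excitable_mask = excitable
        self.active_index = np.full(labels.size, -1, dtype=np.int64)
        flat_idx = np.flatnonzero(excitable.ravel())
        self.flat_idx = flat_idx
        self.n = flat_idx.size
        if self.n == 0:
            raise ValueError("grid has no excitable nodes")
        self.active_index[flat_idx] = np.arange(self.n)

        # neighbour stencil with self-substitution (no-flux closure)
        nb = np.empty((4, self.n), dtype=np.int64)
        ii, jj = np.divmod(flat_idx, nx)
        me = np.arange(self.n)
        for k, (di, dj) in enumerate(((-1, 0), (1, 0), (0, -1), (0, 1))):
            ni, nj = ii + di, jj + dj
            ok = (ni >= 0) & (ni < ny) & (nj >= 0) & (nj < nx)
            ref = np.where(ok, self.active_index[np.clip(ni, 0, ny - 1) * nx
                                                 + np.clip(nj, 0, nx - 1)], -1)
            nb[k] = np.where(ref >= 0, ref, me)
        self.nb = nb

        # per-node parameters
        if subtype_map is None:
            sub = np.full(self.n, 1, dtype=np.int8)          # mid-myocardial
        else:
            sub = subtype_map.ravel()[flat_idx].astype(np.int8)
            if np.any(sub < 0):
                raise ValueError("subtype map undefined on some excitable nodes")
        remod = (labels.ravel()[flat_idx] == Label.INFARCT)
        self.subtype = sub
        self.remodeled = remod
        names = ("ENDO", "M", "EPI")
        self.gna = np.empty(self.n); self.gcal = np.empty(self.n)
        self.gkr = np.empty(self.n); self.gks = np.empty(self.n)
        self.gto = np.empty(self.n)
        self.svar = np.empty(self.n, dtype=np.int8)
        self.V = np.empty(self.n)
        self.G = np.empty((core.N_GATES, self.n))
        self.C = np.empty((core.N_CONC, self.n))
        sqko = math.sqrt(core.KO / 5.4)
        default_init = IonicState()
        for s in range(3):
            for rm in (False, True):
                sel = (sub == s) & (remod == rm)
                if not sel.any():
                    continue
                p = make_cell_params(names[s], remodeled=rm)
                self.gna[sel] = p.g_na
                self.gcal[sel] = p.g_cal
                self.gkr[sel] = p.g_kr * sqko
                self.gks[sel] = p.g_ks
                self.gto[sel] = p.g_to
                self.svar[sel] = p.s_gate_variant
                st = default_init
                if init_states:
                    st = init_states.get((names[s], rm), default_init)
                sv, sg, sc = st.as_arrays()
                self.V[sel] = sv[0]
                self.G[:, sel] = sg
                self.C[:, sel] = sc

        self._lap = np.zeros(self.n)
        self.t = 0.0
        self.act_time = np.full(self.n, -1.0)
        self._tab, self._k1tab = core.tables_for(config.dt)
        self.alpha = config.D * config.dt / grid.dx ** 2

    # ---- checkpointing ----
    def save_state(self):
        return (self.V.copy(), self.G.copy(), self.C.copy(), self.t,
                self.act_time.copy())

    def load_state(self, st) -> None:
        V, G, C, t, act = st
        self.V[:] = V
        self.G[:] = G
        self.C[:] = C
        self.t = t
        self.act_time[:] = act

    def reset_activation(self) -> None:
        self.act_time[:] = -1.0

    def node_mask(self, flat_nodes: np.ndarray) -> np.ndarray:
        """uint8 stimulus mask over active nodes from full-grid flat indices."""
        mask = np.zeros(self.n, dtype=np.uint8)
        act = self.active_index[np.asarray(flat_nodes, dtype=np.int64)]
        if np.any(act < 0):
            raise ValueError("stimulus site contains non-excitable nodes")
        mask[act] = 1
        return mask

    def activation_map(self) -> np.ndarray:
        out = np.full(self.grid.labels.size, np.nan)
        at = self.act_time
        out[self.flat_idx] = np.where(at >= 0, at, np.nan)
        return out.reshape(self.grid.shape)

    def vm_map(self) -> np.ndarray:
        out = np.full(self.grid.labels.size, np.nan)
        out[self.flat_idx] = self.V
        return out.reshape(self.grid.shape)

    def _advance(self, n_steps, stim_mask, stim_amp, stim_start, stim_stop,
                 act_count, samp_every, exit_on_quiet, do_ionic=True):
        done, bad = core.advance(
            self.V, self.G, self.C, self._lap, self.svar,
            self.gna, self.gcal, self.gkr, self.gks, self.gto,
            self.nb, self.alpha, self.config.dt, n_steps, self.t,
            stim_mask, stim_amp, stim_start, stim_stop,
            self._tab, self._k1tab, self.act_time, act_count,
            samp_every, exit_on_quiet, do_ionic,
            self.config.activation_threshold, self.config.activity_threshold)
        if bad < 0 and not np.all(np.isfinite(self.V)):
            bad = int(np.flatnonzero(~np.isfinite(self.V))[0])
        if bad >= 0:
            i = self.flat_idx[bad]
            ny, nx = self.grid.shape
            raise NumericalBlowupError(
                f"non-finite Vm at node ({i // nx}, {i % nx}), "
                f"t = {self.t + done * self.config.dt:.3f} ms")
        self.t += done * self.config.dt
        return done

    def diffuse(self, n_steps: int) -> None:
        """Pure diffusion steps with the membrane frozen (numerical diagnostics)."""
        cnt = np.zeros(1, dtype=np.int64)
        self._advance(n_steps, np.zeros(self.n, np.uint8), 0.0, 0, 0,
                      cnt, 0, False, do_ionic=False)

    def step(self, n_steps: int = 1, stim_mask=None, stim_amp: float = 0.0) -> None:
        """Advance n_steps full reaction-diffusion steps (optional stimulus on)."""
        if stim_mask is None:
            stim_mask = np.zeros(self.n, np.uint8)
        cnt = np.zeros(1, dtype=np.int64)
        self._advance(n_steps, stim_mask, stim_amp, 0, n_steps if stim_amp else 0,
                      cnt, 0, False)

    def run(self, until: float, stimuli=(), exit_on_quiet: bool = False,
            collect=None) -> bool:
        """Advance to absolute time ``until`` (ms) applying StimulusEvents.

        ``stimuli`` is an iterable of protocol.StimulusEvent; events outside
        (self.t, until] are ignored.  ``collect`` is an optional dict with keys
        ``times``/``fractions``/``snapshots`` (lists, appended in place).
        Returns False if the tissue quiesced and the run exited early.
        """
        cfg = self.config
        dt = cfg.dt
        events = sorted((s for s in stimuli if s.onset < until and
                         s.onset + s.duration > self.t), key=lambda s: s.onset)
        samp_every = max(1, int(round(cfg.sample_every / dt)))
        snap_times = []
        if collect is not None and cfg.snapshot_stride > 0:
            k0 = math.floor(self.t / cfg.snapshot_stride) + 1
            snap_times = [k * cfg.snapshot_stride for k in
                          range(int(k0), int(math.floor(until / cfg.snapshot_stride)) + 1)]

        # segment boundaries: stimulus on/off edges and snapshot times
        bounds = {until}
        for s in events:
            bounds.add(min(s.onset, until))
            bounds.add(min(s.onset + s.duration, until))
        bounds.update(t for t in snap_times if self.t < t <= until)
        last_stim_end = max((s.onset + s.duration for s in events), default=-np.inf)

        for b in sorted(bounds):
            if b <= self.t + 1e-9:
                continue
            n_steps = int(round((b - self.t) / dt))
            if n_steps <= 0:
                continue
            stim = next((s for s in events
                         if s.onset - 1e-9 <= self.t < s.onset + s.duration - 1e-9), None)
            if stim is not None:
                mask = self.node_mask(stim.site)
                amp = stim.amplitude
                s_start, s_stop = 0, n_steps
            else:
                mask = np.zeros(self.n, np.uint8)
                amp = 0.0
                s_start = s_stop = 0
            cnt = np.zeros(n_steps // samp_every + 1, dtype=np.int64)
            allow_exit = exit_on_quiet and self.t >= last_stim_end
            t_before = self.t
            done = self._advance(n_steps, mask, amp, s_start, s_stop, cnt,
                                 samp_every, allow_exit)
            if collect is not None:
                ks = np.arange(1, done // samp_every + 1)
                collect.setdefault("times", []).extend(t_before + ks * samp_every * dt)
                collect.setdefault("fractions", []).extend(cnt[:ks.size] / self.n)
                if cfg.snapshot_stride > 0 and any(abs(self.t - st) < dt / 2
                                                   for st in snap_times):
                    collect.setdefault("snapshots", []).append(
                        (self.t, self.vm_map()))
            if done < n_steps:
                return False
        return True


def run_simulation(grid: TissueGrid, config: SolverConfig, protocol,
                   subtype_map: np.ndarray | None = None,
                   init_states: dict | None = None,
                   exit_on_quiet: bool = False) -> Recording:
    """Run a full stimulation protocol on a tissue and collect a Recording.

    ``protocol`` is a list of protocols.StimulusEvent.  The activation map
    holds each node's first crossing of the activation threshold over the whole
    run.  Stimuli at or beyond the configured duration never fire, so a
    duration shorter than the first onset yields an all-quiescent recording.
    With ``exit_on_quiet`` the run stops once every node is below the activity
    threshold after the last stimulus (no activity can reappear).
    """
    sim = MonodomainTissue(grid, config, subtype_map, init_states)
    coll: dict = {"times": [], "fractions": [], "snapshots": []}
    finished = sim.run(config.duration, stimuli=protocol,
                       exit_on_quiet=exit_on_quiet, collect=coll)
    return Recording(sample_times=np.asarray(coll["times"]),
                     active_fraction=np.asarray(coll["fractions"]),
                     activation_map=sim.activation_map(),
                     snapshots=coll["snapshots"],
                     duration=sim.t, n_excitable=sim.n,
                     early_exit=not finished)
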