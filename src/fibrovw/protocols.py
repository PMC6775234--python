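"""Stimulation protocols and arrhythmia-vulnerability measurements.

The S1-S2 protocol conditions the tissue with an S1 stimulus and probes it with
a premature S2 at the same site after a varying coupling interval.  An S2
outcome counts as reentry when excitation is still present ``sustained_ms``
(default 800 ms) after S2 onset — without further stimuli no activity can
reappear once the tissue quiesces, so the scan may stop a trial early as soon
as the active fraction reaches zero.  The vulnerable window (VW) is the range
of coupling intervals with a reentry verdict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import Label, TissueGrid
from .solver import MonodomainTissue, Recording, SolverConfig


@dataclass
class StimulusEvent:
    """One stimulus: onset (ms), node set (full-grid flat indices), amplitude
    (pA/pF, negative = depolarizing) and duration (ms)."""

    onset: float
    site: np.ndarray
    amplitude: float = -150.0
    duration: float = 3.0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        self.site = np.asarray(self.site, dtype=np.int64)
        if self.site.size == 0:
            raise ValueError("stimulus site is empty")


def left_edge_band(grid: TissueGrid, width_nodes: int = 3) -> np.ndarray:
    """Full-height stimulus band on the left edge, ``width_nodes`` columns wide."""
    sel = np.zeros(grid.shape, dtype=bool)
    sel[:, :width_nodes] = True
    sel &= (grid.labels == Label.NORMAL) | (grid.labels == Label.INFARCT)
    idx = np.flatnonzero(sel.ravel())
    if idx.size == 0:
        raise ValueError("left-edge band contains no excitable nodes")
    return idx


def endocardial_block(grid: TissueGrid, angle: float = math.pi,
                      size: int = 10) -> np.ndarray:
    """``size`` x ``size`` stimulus block on the inner (endocardial) wall.

    The block sits just outside the cavity along the ray at ``angle``
    (counterclockwise from +x); only its excitable nodes are returned.
    """
    ny, nx = grid.shape
    c = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    exc = (grid.labels == Label.NORMAL) | (grid.labels == Label.INFARCT)
    ii, jj = np.nonzero(exc)
    rr = np.hypot(ii - c[0], jj - c[1])
    r_in = rr.min()
    r_c = r_in + size / 2.0
    bi = c[0] - r_c * math.sin(angle)
    bj = c[1] + r_c * math.cos(angle)
    i0, j0 = int(round(bi - size / 2)), int(round(bj - size / 2))
    sel = np.zeros(grid.shape, dtype=bool)
    sel[max(i0, 0):i0 + size, max(j0, 0):j0 + size] = True
    sel &= exc
    idx = np.flatnonzero(sel.ravel())
    if idx.size == 0:
        raise ValueError("endocardial stimulus block contains no excitable nodes")
    return idx


def detect_reentry(recording: Recording, s2_onset: float,
                   sustained_ms: float = 800.0,
                   persistence_ms: float = 0.0) -> bool:
    """True iff excitation persists ``sustained_ms`` after S2 onset.

    Operationalized on the active-fraction trace: some node must be above the
    activity threshold at t = s2_onset + sustained_ms, and — if a persistence
    window is configured — at every sample in the following ``persistence_ms``
    (rejecting a front that merely grazes the cutoff while dying).  A recording
    that quiesced and exited early yields False; otherwise it must extend to
    the end of the checked window.
    """
    t_end = s2_onset + sustained_ms + persistence_ms
    if not recording.early_exit and recording.duration < t_end - 1e-9:
        raise ValueError(
            f"recording ends at {recording.duration} ms, before the sustained "
            f"criterion at {t_end} ms")
    if recording.active_fraction_at(s2_onset + sustained_ms) <= 0.0:
        return False
    if persistence_ms > 0:
        t = recording.sample_times
        sel = (t >= s2_onset + sustained_ms - 1e-9) & (t <= t_end + 1e-9)
        if recording.early_exit and recording.sample_times[-1] < t_end:
            return False
        if not np.all(recording.active_fraction[sel] > 0.0):
            return False
    return True


@dataclass
class VWResult:
    """Outcome of one S1-S2 vulnerable-window scan (one tissue realization)."""

    intervals: np.ndarray       # scanned S1-S2 coupling intervals (ms)
    reentry: np.ndarray         # bool verdict per interval
    conducted: np.ndarray       # bool: S2 elicited a propagating wave
    start: float                # first scanned interval (ms)
    step: float                 # scan resolution (ms)
    seed: int | None = None     # fibrosis placement seed of the tissue
    sustained_ms: float = 800.0

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.reentry = np.asarray(self.reentry, dtype=bool)
        self.conducted = np.asarray(self.conducted, dtype=bool)

    @property
    def vw_lower(self) -> float:
        pos = self.intervals[self.reentry]
        return float(pos.min()) if pos.size else float("nan")

    @property
    def vw_upper(self) -> float:
        pos = self.intervals[self.reentry]
        return float(pos.max()) if pos.size else float("nan")

    @property
    def width(self) -> float:
        """VW width = upper - lower bound; 0 when no interval induces reentry."""
        pos = self.intervals[self.reentry]
        return float(pos.max() - pos.min()) if pos.size else 0.0

    @property
    def n_reentry(self) -> int:
        return int(self.reentry.sum())

    @property
    def conduction_lower_bound(self) -> float:
        """Smallest interval at which S2 conducts (the lower bound reported
        alongside a 0-ms VW)."""
        ok = self.intervals[self.conducted]
        return float(ok.min()) if ok.size else float("nan")


def scan_vw(grid: TissueGrid, config: SolverConfig, s1_site: np.ndarray,
            start: float = 480.0, step: float = 5.0, max_interval: float = 600.0,
            amplitude: float = -150.0, stim_duration: float = 3.0,
            sustained_ms: float = 800.0, persistence_ms: float = 0.0,
            subtype_map=None, init_states=None, seed=None) -> VWResult:
    """Scan S1-S2 coupling intervals for reentry and return the VW.

    S1 fires at t = 0; for every interval from ``start`` to ``max_interval`` in
    ``step`` ms increments, S2 fires at the same site and amplitude and the
    tissue is followed up to ``sustained_ms`` (+ persistence) past S2.  The S1
    prefix is shared across intervals through checkpointing, and each trial
    stops as soon as the tissue quiesces.  Deterministic for a given
    (grid, config) pair.
    """
    if step <= 0 or max_interval < start:
        raise ValueError("need step > 0 and max_interval >= start")
    sim = MonodomainTissue(grid, config, subtype_map, init_states)
    site_n = int(sim.node_mask(s1_site).sum())
    s1 = StimulusEvent(onset=0.0, site=s1_site, amplitude=amplitude,
                       duration=stim_duration)
    sim.run(start, stimuli=[s1])
    base = sim.save_state()

    intervals = np.arange(start, max_interval + step / 2, step)
    verdicts = np.zeros(intervals.size, dtype=bool)
    conducted = np.zeros(intervals.size, dtype=bool)
    for k, iv in enumerate(intervals):
        sim.load_state(base)
        if iv > sim.t:
            sim.run(iv)                  # quiescent gap up to S2 onset
            base = sim.save_state()      # reuse for the next (longer) interval
        sim.reset_activation()
        s2 = StimulusEvent(onset=float(iv), site=s1_site, amplitude=amplitude,
                           duration=stim_duration)
        coll: dict = {}
        finished = sim.run(iv + sustained_ms + persistence_ms + config.sample_every,
                           stimuli=[s2], exit_on_quiet=True, collect=coll)
        rec = Recording(sample_times=np.asarray(coll.get("times", [])),
                        active_fraction=np.asarray(coll.get("fractions", [])),
                        activation_map=sim.activation_map(),
                        snapshots=[], duration=sim.t, n_excitable=sim.n,
                        early_exit=not finished)
        verdicts[k] = detect_reentry(rec, float(iv), sustained_ms, persistence_ms)
        conducted[k] = (sim.act_time >= 0).sum() >= 2 * site_n
    return VWResult(intervals=intervals, reentry=verdicts, conducted=conducted,
                    start=start, step=step, seed=seed, sustained_ms=sustained_ms)


@dataclass
class CVResult:
    cv: float                   # mm/ms (NaN when blocked)
    t_first: float
    t_second: float
    blocked: bool


def measure_cv(activation_map: np.ndarray, dx: float, col_a: int, col_b: int,
               rows=None) -> CVResult:
    """Planar conduction velocity between two probe columns of an activation map.

    Activation times are averaged along each probe line (restricted to ``rows``
    if given).  An unactivated probe reports a block (cv = NaN), not an error.
    """
    sub = slice(None) if rows is None else rows
    ta = activation_map[sub, col_a]
    tb = activation_map[sub, col_b]
    ta = ta[np.isfinite(ta)]
    tb = tb[np.isfinite(tb)]
    if ta.size == 0 or tb.size == 0:
        return CVResult(cv=float("nan"), t_first=float("nan"),
                        t_second=float("nan"), blocked=True)
    t1, t2 = float(ta.mean()), float(tb.mean())
    if t2 == t1:
        return CVResult(cv=float("inf"), t_first=t1, t_second=t2, blocked=False)
    return CVResult(cv=abs(col_b - col_a) * dx / (t2 - t1),
                    t_first=t1, t_second=t2, blocked=False)


@dataclass
class SeedAggregate:
    mean: float
    sd: float
    n: int
    widths: np.ndarray
    single_seed: bool = False   # SD reported as 0 by convention when n = 1


def aggregate_seeds(results: list[VWResult]) -> SeedAggregate:
    """Sample mean and SD of VW widths over seeds (SD with n-1 denominator)."""
    if not results:
        raise ValueError("no results to aggregate")
    steps = {r.step for r in results}
    starts = {r.start for r in results}
    if len(steps) > 1 or len(starts) > 1:
        raise ValueError("mixed scan settings: all results must share step and start")
    widths = np.array([r.width for r in results], dtype=float)
    n = widths.size
    if n == 1:
        return SeedAggregate(mean=float(widths[0]), sd=0.0, n=1, widths=widths,
                             single_seed=True)
    return SeedAggregate(mean=float(widths.mean()), sd=float(widths.std(ddof=1)),
                         n=n, widths=widths)
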