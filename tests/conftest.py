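"""Shared fixtures: paced cells, small tissues and the reduced-scale scan tables.

The expensive vulnerable-window scans are session-scoped and shared between the
protocol/experiment unit tests and the acceptance tests, so each condition is
simulated once per session.  Scan settings used here (grid scale, 40 ms scan
step, one seed) are the desk-scale realization described in docs/methods.md.
"""

import numpy as np
import pytest

from fibrovw import experiments, geometry as geo, ionic, protocols as proto, solver
from fibrovw.geometry import Label, TissueGrid

DESK_RING_SCALE = 0.2       # ring grid 120 (42 mm)
DESK_SQUARE_SCALE = 0.1     # square grid 100 (25 mm)
DESK_SCAN = dict(step=40.0, max_interval=520.0)
PREPACE_BEATS = 100


@pytest.fixture(scope="session")
def m_params():
    return ionic.make_cell_params("M")


@pytest.fixture(scope="session")
def paced_m_100():
    """Normal mid-myocardial cell paced 100 beats at bcl 1000 ms."""
    return ionic.pace_single_cell(ionic.make_cell_params("M"), bcl=1000.0,
                                  n_beats=100, record_beats=2)


@pytest.fixture(scope="session")
def paced_infarct_100():
    return ionic.pace_single_cell(ionic.make_cell_params("M", remodeled=True),
                                  bcl=1000.0, n_beats=100, record_beats=2)


@pytest.fixture(scope="session")
def init_states():
    return experiments.tissue_init_states(PREPACE_BEATS)


def make_strip(label=Label.NORMAL, fib_pct=0, seed=1, n=160, h=12, dx=0.25):
    g = TissueGrid(np.full((h, n), label, dtype=np.int8), dx)
    if fib_pct:
        g = geo.sprinkle_random_fibrosis(g, g.indices_of(Label(label)), fib_pct, seed)
    return g


def strip_cv(grid, init_states=None, D=0.154, dt=0.02, col_a=40, col_b=120):
    cfg = solver.SolverConfig(D=D, dt=dt, duration=160.0)
    rec = solver.run_simulation(
        grid, cfg, [proto.StimulusEvent(0.0, proto.left_edge_band(grid))],
        init_states=init_states, exit_on_quiet=True)
    return proto.measure_cv(rec.activation_map, grid.dx, col_a, col_b)


@pytest.fixture(scope="session")
def cv_by_condition(init_states):
    """Planar CV on strips: normal, infarct, infarct + 20% fibrosis."""
    out = {}
    for name, lab, fib in [("normal", Label.NORMAL, 0),
                           ("infarct", Label.INFARCT, 0),
                           ("infarct_fib20", Label.INFARCT, 20)]:
        out[name] = strip_cv(make_strip(lab, fib), init_states).cv
    return out


@pytest.fixture(scope="session")
def ring_width_sweep(init_states):
    """Infarct-width sweep (25/50/75%) x fibrosis (0/20%) on the desk-scale ring."""
    return experiments.exp_ring_sweep(
        "width", values=(25.0, 50.0, 75.0), fibrosis=(0, 20), seeds=(1,),
        scale=DESK_RING_SCALE, init_states=init_states, **DESK_SCAN)


@pytest.fixture(scope="session")
def ring_position_mid(init_states):
    """Mid-wall infarct position (25%), no fibrosis, desk-scale ring."""
    return experiments.exp_ring_sweep(
        "position", values=(25.0,), fibrosis=(0,), seeds=(1,),
        scale=DESK_RING_SCALE, init_states=init_states, **DESK_SCAN)


@pytest.fixture(scope="session")
def distribution_31(init_states):
    """Random vs gradient fibrosis at the highest level (31%), desk-scale square."""
    return experiments.exp_distribution(
        levels=(31,), seeds=(1,), scale=DESK_SQUARE_SCALE,
        init_states=init_states, **DESK_SCAN)


@pytest.fixture(scope="session")
def scar_surrogates(init_states):
    """Ring-strip surrogates of the two measured scars, desk scale."""
    thin = experiments.exp_scar_surrogate(25.0, 35.0, 10.0, fibrosis=(0, 20),
                                          seeds=(1,), scale=DESK_RING_SCALE,
                                          init_states=init_states, **DESK_SCAN)
    wide = experiments.exp_scar_surrogate(25.0, 60.0, 10.0, fibrosis=(20,),
                                          seeds=(1,), scale=DESK_RING_SCALE,
                                          init_states=init_states, **DESK_SCAN)
    return {"thin": thin, "wide": wide}
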