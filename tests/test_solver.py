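"""Monodomain solver: stability contract, diffusion numerics, wave propagation."""

import numpy as np
import pytest

from conftest import make_strip, strip_cv
from fibrovw import geometry as geo, protocols as proto, solver
from fibrovw.geometry import Label, TissueGrid
from fibrovw.solver import MonodomainTissue, SolverConfig, check_stability


class TestStability:
    @pytest.mark.parametrize("D,dt,dx,ok,ratio", [
        (0.154, 0.02, 0.35, True, 0.02514),     # tissue default
        (0.154, 0.02, 0.05, False, 1.232),      # too fine a grid for this dt
        (0.154, 0.0, 0.35, True, 0.0),          # degenerate dt
    ])
    def test_bound_arithmetic(self, D, dt, dx, ok, ratio):
        rep = check_stability(SolverConfig(D=D, dt=dt), dx)
        assert rep.bound == 0.25
        assert rep.ratio == pytest.approx(ratio, abs=2e-4)
        assert rep.ok is ok

    def test_unstable_configuration_refused_by_solver(self):
        g = TissueGrid(np.full((8, 8), Label.NORMAL, dtype=np.int8), dx=0.05)
        with pytest.raises(ValueError, match="unstable"):
            MonodomainTissue(g, SolverConfig())


def _random_tissue(seed=0, n=48):
    rng = np.random.default_rng(seed)
    labels = np.full((n, n), Label.NORMAL, dtype=np.int8)
    labels[rng.random((n, n)) < 0.2] = Label.FIBROTIC
    labels[:, -4:] = Label.VOID
    return TissueGrid(labels, 0.25)


class TestDiffusionOnly:
    def test_uniform_field_is_invariant(self):
        sim = MonodomainTissue(_random_tissue(), SolverConfig())
        sim.V[:] = -20.0
        sim.diffuse(100)
        assert np.all(sim.V == -20.0)

    def test_conservation_and_maximum_principle(self):
        sim = MonodomainTissue(_random_tissue(1), SolverConfig())
        rng = np.random.default_rng(2)
        sim.V[:] = rng.uniform(-80.0, 20.0, sim.n)
        total0 = sim.V.sum()
        lo, hi = sim.V.min(), sim.V.max()
        for _ in range(10):
            sim.diffuse(20)
            assert abs(sim.V.sum() - total0) / abs(total0) <= 1e-9
        assert sim.V.min() >= lo - 1e-12
        assert sim.V.max() <= hi + 1e-12

    def test_fibrosis_enclosed_node_cannot_excite_neighbours(self):
        labels = np.full((9, 9), Label.NORMAL, dtype=np.int8)
        labels[3:6, 3:6] = Label.FIBROTIC
        labels[4, 4] = Label.NORMAL
        g = TissueGrid(labels, 0.25)
        cfg = SolverConfig(duration=60.0)
        site = np.array([4 * 9 + 4])
        rec = solver.run_simulation(g, cfg, [proto.StimulusEvent(0.0, site, -150.0, 3.0)])
        act = rec.activation_map
        assert np.isfinite(act[4, 4])
        outside = np.isfinite(act)
        outside[4, 4] = False
        assert not outside.any()


class TestPropagation:
    def test_planar_isochrones_are_vertical_and_monotone(self):
        g = TissueGrid(np.full((40, 80), Label.NORMAL, dtype=np.int8), 0.25)
        cfg = SolverConfig(duration=60.0)
        rec = solver.run_simulation(g, cfg, [proto.StimulusEvent(0.0, proto.left_edge_band(g))],
                                    exit_on_quiet=False)
        act = rec.activation_map
        assert np.isfinite(act).all()
        assert np.ptp(act, axis=0).max() < 1e-9          # vertical isochrones
        assert np.all(np.diff(act.mean(axis=0)[3:]) > 0)  # monotone in x

    def test_symmetric_ring_gives_symmetric_activation(self, init_states):
        spec = geo.RingSpec(grid_n=80, length_frac=0.25, width_frac=0.5)
        g, _ = geo.build_ring(spec, 0.35)
        cfg = SolverConfig(duration=120.0)
        site = proto.endocardial_block(g)
        # the stimulus block must itself be mirror-symmetric for this check
        sel = np.zeros(g.labels.size, bool)
        sel[site] = True
        sel2 = sel.reshape(g.shape)[::-1, :].ravel()
        site = np.flatnonzero(sel & sel2)
        rec = solver.run_simulation(g, cfg, [proto.StimulusEvent(0.0, site)],
                                    init_states=init_states)
        act = rec.activation_map
        diff = np.abs(act - act[::-1, :])
        assert np.nanmax(diff) < 1.0     # within one sample of mirror symmetry

    def test_random_fibrosis_delays_activation(self):
        g0 = TissueGrid(np.full((60, 60), Label.NORMAL, dtype=np.int8), 0.25)
        gf = geo.sprinkle_random_fibrosis(g0, g0.indices_of(Label.NORMAL), 30, seed=4)
        cfg = SolverConfig(duration=120.0)
        t = {}
        for name, g in [("none", g0), ("fib", gf)]:
            rec = solver.run_simulation(g, cfg, [proto.StimulusEvent(0.0, proto.left_edge_band(g))],
                                        exit_on_quiet=False)
            t[name] = np.nanmean(rec.activation_map)
        assert t["fib"] > t["none"]

    def test_duration_before_first_stimulus_is_quiescent(self):
        g = TissueGrid(np.full((20, 20), Label.NORMAL, dtype=np.int8), 0.25)
        cfg = SolverConfig(duration=5.0)
        rec = solver.run_simulation(g, cfg, [proto.StimulusEvent(50.0, proto.left_edge_band(g))])
        assert not np.isfinite(rec.activation_map).any()
        assert np.all(rec.active_fraction == 0.0)

    def test_blowup_is_reported_with_location(self):
        g = TissueGrid(np.full((10, 10), Label.NORMAL, dtype=np.int8), 0.25)
        sim = MonodomainTissue(g, SolverConfig())
        sim.V[5] = np.inf
        from fibrovw.ionic import NumericalBlowupError
        with pytest.raises(NumericalBlowupError, match="node"):
            sim.step(2)


class TestConductionVelocity:
    def test_halving_dt_changes_cv_by_under_2_percent(self, init_states):
        g = make_strip()
        cv1 = strip_cv(g, init_states, dt=0.02).cv
        cv2 = strip_cv(g, init_states, dt=0.01).cv
        assert abs(cv1 - cv2) / cv2 < 0.02

    def test_cv_monotone_in_diffusion_coefficient(self, init_states):
        g = make_strip()
        cvs = [strip_cv(g, init_states, D=D).cv for D in (0.077, 0.154, 0.308)]
        assert cvs[0] < cvs[1] < cvs[2]
        # approximately sqrt scaling: doubling D gives ~sqrt(2) speed-up
        assert cvs[2] / cvs[1] == pytest.approx(np.sqrt(2.0), rel=0.10)

    def test_probe_separation_does_not_change_cv(self, init_states):
        g = make_strip(n=200)
        cfg = SolverConfig(duration=160.0)
        rec = solver.run_simulation(g, cfg, [proto.StimulusEvent(0.0, proto.left_edge_band(g))],
                                    init_states=init_states, exit_on_quiet=True)
        cv_a = proto.measure_cv(rec.activation_map, g.dx, 50, 110).cv
        cv_b = proto.measure_cv(rec.activation_map, g.dx, 50, 170).cv
        assert cv_b == pytest.approx(cv_a, rel=0.02)

    def test_recording_saves_to_npz(self, tmp_path):
        g = TissueGrid(np.full((20, 20), Label.NORMAL, dtype=np.int8), 0.25)
        cfg = SolverConfig(duration=20.0, snapshot_stride=10.0)
        rec = solver.run_simulation(g, cfg, [proto.StimulusEvent(0.0, proto.left_edge_band(g))])
        p = tmp_path / "rec.npz"
        rec.save_npz(p)
        back = np.load(p)
        assert np.array_equal(back["active_fraction"], rec.active_fraction)
        assert back["snapshots"].shape[0] == len(rec.snapshots) > 0
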