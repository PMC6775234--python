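"""S1-S2 protocol machinery: reentry detection, CV probes, seed aggregation."""

import numpy as np
import pytest

from fibrovw import geometry as geo, protocols as proto, solver
from fibrovw.protocols import StimulusEvent, VWResult, aggregate_seeds, detect_reentry
from fibrovw.solver import Recording, SolverConfig


def make_recording(last_active_ms, duration, early_exit=False, dt=1.0):
    """Synthetic active-fraction recording: active until last_active_ms."""
    t = np.arange(dt, duration + dt / 2, dt)
    frac = np.where(t <= last_active_ms, 0.3, 0.0)
    return Recording(sample_times=t, active_fraction=frac,
                     activation_map=np.zeros((2, 2)), snapshots=[],
                     duration=duration, n_excitable=4, early_exit=early_exit)


class TestStimulusEvent:
    def test_empty_site_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            StimulusEvent(0.0, np.array([], dtype=int))

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            StimulusEvent(0.0, np.array([1]), duration=0.0)


class TestDetectReentry:
    def test_quiescent_recording_is_not_reentry(self):
        rec = make_recording(last_active_ms=0, duration=1400, early_exit=True)
        assert detect_reentry(rec, s2_onset=500.0) is False

    def test_single_ectopic_beat_is_not_reentry(self):
        # S2 wave that fully repolarizes 400 ms after onset
        rec = make_recording(last_active_ms=900, duration=950, early_exit=True)
        assert detect_reentry(rec, s2_onset=500.0) is False

    def test_sustained_activity_is_reentry(self):
        rec = make_recording(last_active_ms=1400, duration=1400)
        assert detect_reentry(rec, s2_onset=500.0) is True

    def test_short_recording_rejected(self):
        rec = make_recording(last_active_ms=900, duration=900)
        with pytest.raises(ValueError, match="before the sustained"):
            detect_reentry(rec, s2_onset=500.0)

    def test_persistence_window_only_demotes(self):
        # active exactly at s2+800 but quiet during the trailing window
        rec = make_recording(last_active_ms=1302, duration=1400)
        assert detect_reentry(rec, 500.0, persistence_ms=0.0) is True
        assert detect_reentry(rec, 500.0, persistence_ms=20.0) is False


class TestVWResult:
    def test_width_is_upper_minus_lower(self):
        res = VWResult(intervals=[480, 485, 490, 495], reentry=[0, 1, 1, 0],
                       conducted=[1, 1, 1, 1], start=480, step=5)
        assert (res.vw_lower, res.vw_upper, res.width) == (485.0, 490.0, 5.0)

    def test_no_reentry_reports_zero_width_and_conduction_bound(self):
        res = VWResult(intervals=[480, 485], reentry=[0, 0],
                       conducted=[0, 1], start=480, step=5)
        assert res.width == 0.0
        assert np.isnan(res.vw_lower)
        assert res.conduction_lower_bound == 485.0


class TestMeasureCV:
    def test_linear_activation_gradient_gives_exact_cv(self):
        act = np.tile(np.arange(50, dtype=float) * 0.5, (6, 1))   # 0.5 ms/node
        res = proto.measure_cv(act, dx=0.25, col_a=10, col_b=40)
        assert res.cv == pytest.approx(0.25 / 0.5)
        assert not res.blocked

    def test_unactivated_probe_reports_block(self):
        act = np.full((6, 50), np.nan)
        act[:, :10] = 1.0
        res = proto.measure_cv(act, dx=0.25, col_a=5, col_b=40)
        assert res.blocked and np.isnan(res.cv)


class TestAggregateSeeds:
    def _res(self, width, step=5.0):
        iv = np.array([480.0, 480.0 + width]) if width else np.array([480.0])
        re = np.ones_like(iv, bool) if width else np.array([False])
        return VWResult(intervals=iv, reentry=re, conducted=np.ones_like(iv, bool),
                        start=480.0, step=step)

    def test_identical_widths_have_zero_sd(self):
        agg = aggregate_seeds([self._res(10)] * 3)
        assert (agg.mean, agg.sd, agg.n) == (10.0, 0.0, 3)

    def test_hand_computed_mean_and_sd(self):
        widths = [0, 5, 10, 5, 0, 10]
        agg = aggregate_seeds([self._res(w) for w in widths])
        assert agg.mean == pytest.approx(5.0)
        assert agg.sd == pytest.approx(4.472, abs=0.001)

    def test_single_seed_flagged_with_zero_sd(self):
        agg = aggregate_seeds([self._res(7)])
        assert agg.sd == 0.0 and agg.single_seed

    def test_mixed_scan_steps_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            aggregate_seeds([self._res(5, step=5.0), self._res(5, step=1.0)])


class TestScanVW:
    def test_homogeneous_ring_has_zero_width_and_conducts(self, init_states):
        """A normal ring without infarct shows no reentry at any interval."""
        spec = geo.RingSpec(grid_n=80, length_frac=0.0)
        g, _ = geo.build_ring(spec, 0.35)
        cfg = SolverConfig(duration=2000.0)
        res = proto.scan_vw(g, cfg, proto.endocardial_block(g), start=480,
                            step=60, max_interval=540, init_states=init_states)
        assert res.width == 0.0
        assert res.conducted.all()
        assert res.reentry.shape == res.intervals.shape    # verdict per interval

    def test_scan_is_deterministic(self, init_states):
        spec = geo.RingSpec(grid_n=80, length_frac=0.25, width_frac=0.5)
        g, inf = geo.build_ring(spec, 0.35)
        g = geo.sprinkle_random_fibrosis(g, inf, 20, seed=3)
        cfg = SolverConfig(duration=2000.0)
        site = proto.endocardial_block(g)
        r1 = proto.scan_vw(g, cfg, site, start=480, step=60, max_interval=540,
                           init_states=init_states)
        r2 = proto.scan_vw(g, cfg, site, start=480, step=60, max_interval=540,
                           init_states=init_states)
        assert np.array_equal(r1.reentry, r2.reentry)
        assert np.array_equal(r1.conducted, r2.conducted)
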