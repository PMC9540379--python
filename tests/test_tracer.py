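import math

import numpy as np
import pytest
import scipy.ndimage as ndi
from hypothesis import given, settings
from hypothesis import strategies as st

import ciliawave as cw
from ciliawave.tracer import SegmentContext, _select_candidate


def straight_filament_frame(h=64, w=64, y0=32.0, amp=1.0, sigma=1.0):
    """Horizontal bright ridge at row y0 on a dark background."""
    y = np.arange(h)[:, None]
    return np.broadcast_to(amp * np.exp(-((y - y0) ** 2) / (2 * sigma**2)), (h, w)).copy()


def make_context(**kw):
    defaults = dict(
        prev_theta_in_frame=0.0,
        prev_frame_theta=0.0,
        prev_frame_node=(10.0, 32.0),
        prev_frame_theta_prev=0.0,
        dt_s=2.0,
    )
    defaults.update(kw)
    return SegmentContext(**defaults)


class TestInitSeed:
    def test_straight_polyline_45deg(self):
        d = 20.0 / math.sqrt(2)
        seed = cw.Seed(base_xy=(10.0, 10.0), polyline=[[10.0, 10.0], [10.0 + d, 10.0 + d]])
        cfg = cw.TraceConfig(segment_length_px=4.0)
        tr = cw.init_seed(np.zeros((64, 64)), seed, cfg)
        assert tr.n_segments == 5
        np.testing.assert_allclose(tr.theta, math.pi / 4)
        np.testing.assert_allclose(np.linalg.norm(np.diff(tr.nodes, axis=0), axis=1), 4.0)

    def test_floor_rule_drops_tip_remainder(self):
        seed = cw.Seed(base_xy=(5.0, 5.0), polyline=[[5.0, 5.0], [15.0, 5.0]])
        tr = cw.init_seed(np.zeros((32, 32)), seed, cw.TraceConfig(segment_length_px=4.0))
        assert tr.n_segments == 2

    def test_too_short_polyline(self):
        seed = cw.Seed(base_xy=(5.0, 5.0), polyline=[[5.0, 5.0], [8.0, 5.0]])
        with pytest.raises(ValueError, match="shorter"):
            cw.init_seed(np.zeros((32, 32)), seed, cw.TraceConfig(segment_length_px=4.0))

    def test_polyline_outside_image(self):
        seed = cw.Seed(base_xy=(30.0, 5.0), polyline=[[30.0, 5.0], [50.0, 5.0]])
        with pytest.raises(ValueError, match="leaves"):
            cw.init_seed(np.zeros((32, 32)), seed, cw.TraceConfig(segment_length_px=4.0))

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.floats(-3, 3), st.floats(-3, 3)), min_size=1, max_size=6),
           st.floats(1.0, 5.0))
    def test_exact_segment_lengths_any_polyline(self, deltas, ds):
        # random wiggly polylines anchored mid-image
        pts = [np.array([50.0, 50.0])]
        for dx, dy in deltas:
            pts.append(pts[-1] + [dx + 3.5, dy])  # biased forward so length grows
        poly = np.array(pts)
        total = np.linalg.norm(np.diff(poly, axis=0), axis=1).sum()
        if total < ds:
            return
        seed = cw.Seed(base_xy=tuple(poly[0]), polyline=poly)
        tr = cw.init_seed(np.zeros((100, 100)), seed, cw.TraceConfig(segment_length_px=ds))
        np.testing.assert_allclose(
            np.linalg.norm(np.diff(tr.nodes, axis=0), axis=1), ds, rtol=1e-12
        )
        np.testing.assert_allclose(tr.nodes[0], poly[0])


class TestSegmentCost:
    def test_constant_image_symmetric(self):
        cfg = cw.TraceConfig(w_curvature=0, w_tvel=0, w_rvel=0, w_dcurv=0)
        frame = np.full((64, 64), 3.0)
        cands = cfg.candidate_grid(0.0)
        comp = cw.segment_cost(frame, (32, 32), cands, make_context(), cfg)
        assert np.ptp(comp["total"]) <= 1e-12  # identical up to accumulation order

    def test_straight_filament_argmin_at_zero(self):
        frame = straight_filament_frame()
        cfg = cw.TraceConfig(w_curvature=0, w_tvel=0, w_rvel=0, w_dcurv=0)
        cands = cfg.candidate_grid(0.0)
        comp = cw.segment_cost(frame, (20.0, 32.0), cands, make_context(), cfg)
        assert cands[np.argmin(comp["total"])] == pytest.approx(0.0, abs=1e-12)

    def test_huge_curvature_weight_forces_prev_angle(self):
        frame = straight_filament_frame()
        cfg = cw.TraceConfig(w_intensity=0, w_curvature=1e9, w_tvel=0, w_rvel=0, w_dcurv=0)
        ctx = make_context(prev_theta_in_frame=0.2)
        cands = cfg.candidate_grid(0.0)
        comp = cw.segment_cost(frame, (20.0, 32.0), cands, ctx, cfg)
        best = cands[np.argmin(comp["total"])]
        assert abs(best - 0.2) <= cfg.angle_step_rad / 2 + 1e-12

    def test_total_is_sum_of_components(self):
        frame = straight_filament_frame()
        cfg = cw.TraceConfig()
        cands = cfg.candidate_grid(0.1)
        comp = cw.segment_cost(frame, (20.0, 30.0), cands, make_context(), cfg)
        np.testing.assert_array_equal(
            comp["total"],
            comp["intensity"] + comp["curvature"] + comp["tvel"] + comp["rvel"] + comp["dcurv"],
        )

    def test_scalar_candidate_returns_floats(self):
        comp = cw.segment_cost(np.zeros((32, 32)), (16, 16), 0.3, make_context(), cw.TraceConfig())
        assert isinstance(comp["total"], float)


class TestTraceFrame:
    def _seed_trace(self, theta0=0.0, base=(16.0, 32.0), n=4, ds=4.0):
        nodes = np.zeros((n + 1, 2))
        nodes[0] = base
        for i in range(n):
            nodes[i + 1] = nodes[i] + ds * np.array([math.cos(theta0), math.sin(theta0)])
        return cw.FrameTrace(nodes=nodes, theta=np.full(n, theta0), frame_index=0)

    def test_fixed_point_on_same_frame(self):
        frame = straight_filament_frame(h=64, w=64, y0=32.0)
        prev = self._seed_trace()
        cfg = cw.TraceConfig(smooth_sigma_px=0.0)
        new, _ = cw.trace_frame(frame, prev, cfg, seed_theta0=0.0, dt_s=2.0)
        np.testing.assert_allclose(new.theta, prev.theta, atol=cfg.angle_step_rad + 1e-12)

    def test_tie_break_returns_center_on_constant_image(self):
        frame = np.full((64, 64), 5.0)
        prev = self._seed_trace(theta0=0.37)
        cfg = cw.TraceConfig(w_curvature=0, w_tvel=0, w_rvel=0, w_dcurv=0, smooth_sigma_px=0.0)
        new, _ = cw.trace_frame(frame, prev, cfg, seed_theta0=0.37)
        np.testing.assert_allclose(new.theta, 0.37)

    def test_truncation_when_probe_leaves_image(self):
        frame = straight_filament_frame(h=40, w=40, y0=20.0)
        prev = self._seed_trace(base=(34.0, 20.0), n=4, ds=4.0)
        cfg = cw.TraceConfig(smooth_sigma_px=0.0)
        new, _ = cw.trace_frame(frame, prev, cfg, seed_theta0=0.0)
        assert new.truncated_at is not None
        # chain still complete with exact segment lengths
        np.testing.assert_allclose(np.linalg.norm(np.diff(new.nodes, axis=0), axis=1), 4.0)

    def test_base_is_anchored(self):
        frame = straight_filament_frame()
        prev = self._seed_trace(base=(16.0, 32.0))
        new, _ = cw.trace_frame(frame, prev, cw.TraceConfig(), seed_theta0=0.0)
        np.testing.assert_array_equal(new.nodes[0], prev.nodes[0])


class TestGridOptimality:
    """The chosen angle must equal the argmin of an independently coded
    exhaustive evaluation of the cost over the same candidate grid."""

    def test_tracer_matches_exhaustive_search(self):
        from oracles import reference_segment_cost

        rng = np.random.default_rng(42)
        cfg = cw.TraceConfig(normalize_frames=False, smooth_sigma_px=0.0)
        for _ in range(20):
            frame = ndi.gaussian_filter(rng.uniform(0, 1, (48, 48)), 1.2)
            start = rng.uniform(15, 33, size=2)
            theta_c = rng.uniform(-math.pi, math.pi)
            nodes = np.array([start, start + cfg.segment_length_px * np.array([math.cos(theta_c), math.sin(theta_c)])])
            prev = cw.FrameTrace(nodes=nodes, theta=np.array([theta_c]))
            s0 = theta_c + rng.normal(0, 0.2)
            new, _ = cw.trace_frame(frame, prev, cfg, seed_theta0=s0, prev_seed_theta0=s0, dt_s=2.0)
            ctx = SegmentContext(
                prev_theta_in_frame=s0, prev_frame_theta=theta_c,
                prev_frame_node=tuple(nodes[1]), prev_frame_theta_prev=s0, dt_s=2.0,
            )
            fill = float(np.median(frame))
            cands = cfg.candidate_grid(theta_c)
            ref = [reference_segment_cost(frame, start, th, ctx, cfg, fill) for th in cands]
            assert new.theta[0] == cands[int(np.argmin(ref))]


class TestTraceMovie:
    def test_static_movie_constant_theta(self):
        frame = straight_filament_frame(h=64, w=96, y0=32.0)
        stack = cw.ImageStack(frames=np.stack([frame] * 6), pixel_size_um=0.35, frame_interval_s=2.0)
        seed = cw.Seed(base_xy=(10.0, 32.0), polyline=[[10.0, 32.0], [40.0, 32.0]])
        trace, costs = cw.trace_movie(stack, seed)
        assert trace.n_frames == 6
        np.testing.assert_allclose(trace.theta - trace.theta[0], 0.0, atol=1e-12)
        assert len(costs.total) == 6

    def test_deterministic(self, small_movie, small_seed):
        stack, _ = small_movie
        t1, c1 = cw.trace_movie(stack, small_seed)
        t2, c2 = cw.trace_movie(stack, small_seed)
        np.testing.assert_array_equal(t1.theta, t2.theta)
        np.testing.assert_array_equal(t1.nodes, t2.nodes)
        np.testing.assert_array_equal(c1.total, c2.total)

    def test_exact_segment_lengths_every_frame(self, small_movie, small_seed):
        stack, _ = small_movie
        trace, _ = cw.trace_movie(stack, small_seed)
        lens = np.linalg.norm(np.diff(trace.nodes, axis=1), axis=2)
        np.testing.assert_allclose(lens, trace.segment_length_px, rtol=1e-9)

    def test_base_anchored_every_frame(self, small_movie, small_seed):
        stack, _ = small_movie
        trace, _ = cw.trace_movie(stack, small_seed)
        np.testing.assert_allclose(
            trace.nodes[:, 0, :] - np.asarray(small_seed.base_xy), 0.0, atol=1e-9
        )

    def test_tracks_rigid_pivot(self, small_movie, small_seed):
        stack, truth = small_movie
        trace, _ = cw.trace_movie(stack, small_seed)
        s_mid = (np.arange(trace.n_segments) + 0.5) * trace.segment_length_px
        err = np.array(
            [np.abs(trace.theta[t] - truth.theta_at(s_mid, t)) for t in range(trace.n_frames)]
        )
        assert np.degrees(np.median(err)) <= 2.0

    def test_frame_range_restricts_output(self, small_movie, small_seed):
        stack, _ = small_movie
        trace, costs = cw.trace_movie(stack, small_seed, frame_range=cw.FrameRange(0, 10))
        assert trace.n_frames == 10
        np.testing.assert_array_equal(trace.frame_indices, np.arange(10))

    def test_total_cost_is_sum_of_components(self, small_movie, small_seed):
        stack, _ = small_movie
        _, costs = cw.trace_movie(stack, small_seed, frame_range=cw.FrameRange(0, 8))
        np.testing.assert_array_equal(
            costs.total, costs.intensity + costs.curvature + costs.tvel + costs.rvel + costs.dcurv
        )

    def test_csv_roundtrip(self, tmp_path, small_movie, small_seed):
        stack, _ = small_movie
        trace, _ = cw.trace_movie(stack, small_seed, frame_range=cw.FrameRange(0, 5))
        path = trace.to_csv(tmp_path / "trace.csv")
        back = cw.CiliumTrace.from_csv(path)
        np.testing.assert_allclose(back.theta, trace.theta, atol=1e-12)
        np.testing.assert_allclose(back.nodes, trace.nodes, atol=1e-9)
        assert back.pixel_size_um == trace.pixel_size_um


class TestRotationEquivariance:
    def test_quarter_turn_scene(self):
        from ciliawave.pipeline import seed_from_truth

        model = cw.WaveformModel(base_xy=(64.0, 64.0), base_angle_rad=0.4, length_um=6.0)
        render = cw.RenderParams(rng_seed=2, noise_sigma=0.0)
        stack, truth = cw.simulate_cilium_movie(model, render, n_frames=8, shape=(128, 128))
        cfg = cw.TraceConfig(w_curvature=0, w_tvel=0, w_rvel=0, w_dcurv=0)
        seed = seed_from_truth(truth)
        t1, _ = cw.trace_movie(stack, seed, cfg)

        w = stack.frames.shape[2]
        rot = np.stack([np.rot90(f) for f in stack.frames])
        stack2 = cw.ImageStack(frames=rot, pixel_size_um=0.35, frame_interval_s=2.0)
        poly2 = np.stack([seed.polyline[:, 1], w - 1 - seed.polyline[:, 0]], axis=1)
        seed2 = cw.Seed(base_xy=(poly2[0, 0], poly2[0, 1]), polyline=poly2)
        t2, _ = cw.trace_movie(stack2, seed2, cfg)

        diff = np.abs((t2.theta - (t1.theta - np.pi / 2) + np.pi) % (2 * np.pi) - np.pi)
        assert diff.max() <= cfg.angle_step_rad


class TestCostDiagnostics:
    def _costs(self, total):
        total = np.asarray(total, dtype=float)
        z = np.zeros_like(total)
        return cw.CostBreakdown(
            frame_indices=np.arange(len(total)), intensity=total, curvature=z,
            tvel=z, rvel=z, dcurv=z, total=total,
        )

    def test_hand_computed_bands(self):
        diag = cw.cost_diagnostics(self._costs([1, 2, 3, 4, 5]))
        assert diag["mean"] == pytest.approx(3.0)
        assert diag["upper"] == pytest.approx(3.0 + 2.0 * math.sqrt(2.0))
        assert diag["lower"] == pytest.approx(3.0 - 2.0 * math.sqrt(2.0))

    def test_constant_series_collapses(self):
        diag = cw.cost_diagnostics(self._costs([2.0, 2.0, 2.0]))
        assert diag["sd"] == 0.0
        assert diag["upper"] == diag["lower"] == diag["mean"]
        assert diag["outlier_frames"].size == 0

    def test_spike_flagged(self):
        diag = cw.cost_diagnostics(self._costs([1.0] * 20 + [50.0]))
        assert 20 in diag["outlier_frames"]

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            cw.cost_diagnostics(self._costs([1.0]))


class TestSelectCandidate:
    def test_ties_resolve_to_nearest_center_then_smaller(self):
        cands = np.array([-0.1, 0.0, 0.1, 0.2])
        total = np.array([1.0, 1.0, 1.0, 1.0])
        assert _select_candidate(cands, total, 0.0) == 1
        total2 = np.array([0.5, 1.0, 0.5, 1.0])
        # two minima equidistant from center 0.0 -> smaller angle wins
        assert _select_candidate(cands, total2, 0.0) == 0
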