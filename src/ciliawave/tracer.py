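"""Seeded frame-by-frame tracing of one cilium by penalized cost minimization.

On the first analyzed frame the user marks the stationary ciliary base and
clicks a polyline from base to tip; this fixes the cilium length (a chain of
N equal-length segments) and the initial tangent angle.  Every subsequent
frame is traced automatically, segment by segment from the base outward: for
each segment a fan of candidate tangent angles around the previous frame's
angle is scored, and the angle minimizing a penalized cost is kept.

The cost of a candidate angle theta for segment i of frame t is

    E = -w_I * <I>_probe                          (intensity reward)
      + w_curv  * wrap(theta - theta_{i-1,t})^2                (curvature)
      + w_tvel  * |endnode(theta) - node_{i,t-1}|^2 / dt^2     (transl. velocity)
      + w_rvel  * wrap(theta - theta_{i,t-1})^2 / dt^2         (rot. velocity)
      + w_dcurv * (wrap(theta - theta_{i-1,t})
                   - wrap(theta_{i,t-1} - theta_{i-1,t-1}))^2 / dt^2,

where <I>_probe is the weighted mean of bilinearly interpolated intensities
under a rectangular probe array spanning the segment's length and width,
rotated to the candidate angle.  The penalties keep the trace on track when
noise, poor contrast or focus make the intensity term ambiguous.  All angle
differences are wrapped to (-pi, pi].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from ._util import bilinear_sample, wrap_angle
from .stack import FrameRange, ImageStack

__all__ = [
    "Seed",
    "TraceConfig",
    "SegmentContext",
    "FrameTrace",
    "CiliumTrace",
    "CostBreakdown",
    "init_seed",
    "segment_cost",
    "trace_frame",
    "trace_movie",
    "cost_diagnostics",
    "normalize_frame",
]


@dataclass(frozen=True)
class Seed:
    """User-identified cilium base and initial base-to-tip polyline."""

    base_xy: tuple[float, float]
    polyline: np.ndarray

    def __post_init__(self):
        poly = np.asarray(self.polyline, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 2:
            raise ValueError("polyline must be an (M >= 2) x 2 array of (x, y) points")
        if not np.allclose(poly[0], self.base_xy):
            raise ValueError("polyline must start at base_xy")
        object.__setattr__(self, "polyline", poly)

    @classmethod
    def from_dict(cls, d: dict) -> "Seed":
        return cls(base_xy=tuple(d["base"]), polyline=np.asarray(d["polyline"], dtype=float))

    def to_dict(self) -> dict:
        return {"base": list(self.base_xy), "polyline": self.polyline.tolist()}


@dataclass(frozen=True)
class TraceConfig:
    """Tracing parameters.

    segment_length_px (ds) sets the angular resolution / noise trade-off per
    segment; the candidate fan spans +/- angle_search_halfwidth_rad around
    the previous frame's angle in steps of angle_step_rad (the fan width
    doubles as a hard limit on per-frame rotational velocity).  The probe
    array has probe_samples = (n_along, n_across) sample points covering
    ds x probe_width_px; the transverse weighting ('gaussian', sigma = w/4,
    or 'uniform') favors candidates centered on the filament.

    Frames are Gaussian-smoothed by smooth_sigma_px (matched-filter-style
    noise suppression; 0 disables) and min-max normalized before costing,
    so the penalty weights transfer across movies of different brightness.
    """

    segment_length_px: float = 4.0
    probe_width_px: float = 3.0
    probe_samples: tuple[int, int] = (5, 7)
    angle_search_halfwidth_rad: float = math.radians(30.0)
    angle_step_rad: float = math.radians(1.0)
    w_intensity: float = 1.0
    w_curvature: float = 0.05
    w_tvel: float = 0.005
    w_rvel: float = 0.05
    w_dcurv: float = 0.02
    transverse_weight_profile: str = "gaussian"
    normalize_frames: bool = True
    smooth_sigma_px: float = 1.0

    def __post_init__(self):
        if not self.segment_length_px > 0:
            raise ValueError("segment_length_px must be positive")
        if not self.probe_width_px > 0:
            raise ValueError("probe_width_px must be positive")
        if min(self.probe_samples) < 1:
            raise ValueError("probe_samples must be >= 1 in both directions")
        if not self.angle_step_rad > 0:
            raise ValueError("angle_step_rad must be positive")
        if self.angle_search_halfwidth_rad < self.angle_step_rad:
            raise ValueError("angle_search_halfwidth_rad must be >= angle_step_rad")
        for name in ("w_intensity", "w_curvature", "w_tvel", "w_rvel", "w_dcurv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.transverse_weight_profile not in ("gaussian", "uniform"):
            raise ValueError("transverse_weight_profile must be 'gaussian' or 'uniform'")
        if self.smooth_sigma_px < 0:
            raise ValueError("smooth_sigma_px must be >= 0")

    def candidate_grid(self, theta_center: float) -> np.ndarray:
        n = int(math.floor(self.angle_search_halfwidth_rad / self.angle_step_rad + 1e-9))
        return theta_center + np.arange(-n, n + 1) * self.angle_step_rad


@dataclass(frozen=True)
class SegmentContext:
    """Neighborhood values entering the penalty terms of one segment.

    prev_theta_in_frame  : theta_{i-1, t}, the already-traced angle of the
                           previous segment in the current frame (for the
                           first segment: the seed's initial angle).
    prev_frame_theta     : theta_{i, t-1}.
    prev_frame_node      : end node of segment i in frame t-1 (x, y).
    prev_frame_theta_prev: theta_{i-1, t-1} (first segment: seed angle).
    dt_s                 : frame interval (s), denominator of the velocity terms.
    """

    prev_theta_in_frame: float
    prev_frame_theta: float
    prev_frame_node: tuple[float, float]
    prev_frame_theta_prev: float
    dt_s: float = 1.0


@dataclass(frozen=True)
class FrameTrace:
    """Equal-length segment chain of one frame.

    nodes is (N+1) x 2 with node 0 anchored at the seed base; theta[i] is the
    angle of the segment from node i to node i+1 w.r.t. the x-axis
    (image convention, y down).  truncated_at marks the first segment whose
    probe left the image entirely, if any.
    """

    nodes: np.ndarray
    theta: np.ndarray
    frame_index: int = 0
    truncated_at: int | None = None

    def __post_init__(self):
        nodes = np.asarray(self.nodes, dtype=float)
        theta = np.asarray(self.theta, dtype=float)
        if nodes.shape != (theta.shape[0] + 1, 2):
            raise ValueError("nodes must be (N+1) x 2 for N = len(theta)")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "theta", theta)

    @property
    def n_segments(self) -> int:
        return self.theta.shape[0]


@dataclass(frozen=True)
class CiliumTrace:
    """Raw angle data of one cilium over the analyzed frame range."""

    theta: np.ndarray  # (T, N)
    nodes: np.ndarray  # (T, N+1, 2)
    frame_indices: np.ndarray  # (T,)
    segment_length_px: float
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self):
        theta = np.asarray(self.theta, dtype=float)
        nodes = np.asarray(self.nodes, dtype=float)
        fi = np.asarray(self.frame_indices, dtype=int)
        if theta.ndim != 2 or nodes.shape != (theta.shape[0], theta.shape[1] + 1, 2):
            raise ValueError("inconsistent theta/nodes shapes")
        if fi.shape != (theta.shape[0],):
            raise ValueError("frame_indices length must match theta")
        if fi.size > 1 and not np.all(np.diff(fi) == 1):
            raise ValueError("frame indices must be contiguous")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "frame_indices", fi)

    @property
    def n_frames(self) -> int:
        return self.theta.shape[0]

    @property
    def n_segments(self) -> int:
        return self.theta.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: one row per (frame, node); theta_rad is the
        angle of the segment ending at that node (NaN for the base row)."""
        t, n1 = self.nodes.shape[:2]
        frames = np.repeat(self.frame_indices, n1)
        seg = np.tile(np.arange(n1), t)
        theta_col = np.full((t, n1), np.nan)
        theta_col[:, 1:] = self.theta
        return pd.DataFrame(
            {
                "frame": frames,
                "segment": seg,
                "s_um": seg * self.segment_length_px * self.pixel_size_um,
                "x_px": self.nodes[:, :, 0].ravel(),
                "y_px": self.nodes[:, :, 1].ravel(),
                "theta_rad": theta_col.ravel(),
            }
        )

    def to_csv(self, path) -> str:
        df = self.to_dataframe()
        with open(path, "w") as fh:
            fh.write(
                f"# segment_length_px={self.segment_length_px!r} "
                f"pixel_size_um={self.pixel_size_um!r} "
                f"frame_interval_s={self.frame_interval_s!r}\n"
            )
            df.to_csv(fh, index=False)
        return str(path)

    @classmethod
    def from_csv(cls, path) -> "CiliumTrace":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(
                kv.split("=") for kv in header.lstrip("#").strip().split() if "=" in kv
            )
            df = pd.read_csv(fh)
        frames = np.sort(df["frame"].unique())
        n1 = int(df["segment"].max()) + 1
        nodes = np.empty((len(frames), n1, 2))
        theta = np.empty((len(frames), n1 - 1))
        for k, f in enumerate(frames):
            sub = df[df["frame"] == f].sort_values("segment")
            nodes[k, :, 0] = sub["x_px"].to_numpy()
            nodes[k, :, 1] = sub["y_px"].to_numpy()
            theta[k] = sub["theta_rad"].to_numpy()[1:]
        return cls(
            theta=theta,
            nodes=nodes,
            frame_indices=frames,
            segment_length_px=float(meta["segment_length_px"]),
            pixel_size_um=float(meta["pixel_size_um"]),
            frame_interval_s=float(meta["frame_interval_s"]),
        )


@dataclass(frozen=True)
class CostBreakdown:
    """Per-frame cost components (sums over segments) of a traced movie."""

    frame_indices: np.ndarray
    intensity: np.ndarray
    curvature: np.ndarray
    tvel: np.ndarray
    rvel: np.ndarray
    dcurv: np.ndarray
    total: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame_indices,
                "intensity": self.intensity,
                "curv": self.curvature,
                "tvel": self.tvel,
                "rvel": self.rvel,
                "dcurv": self.dcurv,
                "total": self.total,
            }
        )

    def to_csv(self, path) -> str:
        self.to_dataframe().to_csv(path, index=False)
        return str(path)


def normalize_frame(frame: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1] (float64).

    Applied per frame before costing so that the penalty weights are
    transferable across movies with different absolute brightness.  A
    constant frame maps to all zeros.
    """
    frame = np.asarray(frame, dtype=np.float64)
    lo = frame.min()
    span = frame.max() - lo
    if span == 0:
        return np.zeros_like(frame)
    return (frame - lo) / span


def _prep_frame(frame: np.ndarray, config: TraceConfig) -> np.ndarray:
    """Smoothing + normalization applied before costing a frame."""
    frame = np.asarray(frame, dtype=np.float64)
    if config.smooth_sigma_px > 0:
        frame = ndi.gaussian_filter(frame, config.smooth_sigma_px)
    if config.normalize_frames:
        frame = normalize_frame(frame)
    return frame


def init_seed(first_frame: np.ndarray, seed: Seed, config: TraceConfig) -> FrameTrace:
    """Resample the user polyline into N equal segments of length ds.

    N = floor(polyline_length / ds); the remainder at the tip is dropped
    (the seed fixes the cilium length once, for all frames).  The returned
    trace is the frame-0 context for the first automatically traced frame.
    """
    poly = seed.polyline
    seglens = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    total = float(seglens.sum())
    ds = config.segment_length_px
    n = int(math.floor(total / ds + 1e-9))
    if n < 1:
        raise ValueError(
            f"seed polyline length {total:.2f} px is shorter than one segment ({ds} px)"
        )
    # arc-length resampling at s = 0, ds, ..., N*ds
    cum = np.concatenate([[0.0], np.cumsum(seglens)])
    s_targets = np.arange(n + 1) * ds
    px = np.interp(s_targets, cum, poly[:, 0])
    py = np.interp(s_targets, cum, poly[:, 1])
    theta = np.arctan2(np.diff(py), np.diff(px))
    # rebuild the chain so that every segment has length exactly ds
    nodes = np.empty((n + 1, 2))
    nodes[0] = seed.base_xy
    for i in range(n):
        nodes[i + 1] = nodes[i] + ds * np.array([math.cos(theta[i]), math.sin(theta[i])])

    h, w = np.asarray(first_frame).shape
    if (
        nodes[:, 0].min() < 0
        or nodes[:, 0].max() > w - 1
        or nodes[:, 1].min() < 0
        or nodes[:, 1].max() > h - 1
    ):
        raise ValueError("seed polyline leaves the image")
    return FrameTrace(nodes=nodes, theta=theta, frame_index=0)


def _probe_offsets(config: TraceConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Along/across sample offsets of the probe array and their weights."""
    n_along, n_across = config.probe_samples
    ds = config.segment_length_px
    w = config.probe_width_px
    along = (np.arange(n_along) + 0.5) * ds / n_along
    if n_across == 1:
        across = np.zeros(1)
    else:
        across = np.linspace(-w / 2.0, w / 2.0, n_across)
    if config.transverse_weight_profile == "gaussian":
        sigma = w / 4.0
        wt = np.exp(-(across**2) / (2.0 * sigma * sigma))
    else:
        wt = np.ones_like(across)
    weights = np.broadcast_to(wt[None, :], (n_along, n_across)).ravel()
    weights = weights / weights.sum()
    return along, across, weights


def segment_cost(
    frame: np.ndarray,
    start_node,
    candidate_theta,
    context: SegmentContext,
    config: TraceConfig,
    fill_value: float | None = None,
):
    """Cost components of candidate angle(s) for one segment.

    candidate_theta may be a scalar or an array; components are returned in a
    dict of matching shape with keys ``intensity``, ``curvature``, ``tvel``,
    ``rvel``, ``dcurv``, ``total`` and ``inside_fraction`` (fraction of probe
    samples inside the image, used to detect truncation at the border).
    Probe samples outside the image take ``fill_value`` (default: the frame
    median, a background estimate).
    """
    frame = np.asarray(frame, dtype=np.float64)
    if fill_value is None:
        fill_value = float(np.median(frame))
    theta = np.atleast_1d(np.asarray(candidate_theta, dtype=float))
    scalar = np.isscalar(candidate_theta) or np.ndim(candidate_theta) == 0

    along, across, weights = _probe_offsets(config)
    cos_t = np.cos(theta)[:, None, None]
    sin_t = np.sin(theta)[:, None, None]
    a = along[None, :, None]
    c = across[None, None, :]
    x0, y0 = float(start_node[0]), float(start_node[1])
    # probe point = start + a * u(theta) + c * n(theta), n = u rotated +90 deg
    xs = x0 + a * cos_t - c * sin_t
    ys = y0 + a * sin_t + c * cos_t

    h, w = frame.shape
    inside = (xs >= 0.0) & (xs <= w - 1.0) & (ys >= 0.0) & (ys <= h - 1.0)
    vals = bilinear_sample(frame, xs, ys, fill_value)
    flat = vals.reshape(theta.shape[0], -1)
    mean_intensity = flat @ weights
    inside_fraction = inside.reshape(theta.shape[0], -1).mean(axis=1)

    dt2 = context.dt_s * context.dt_s
    d_curv_now = wrap_angle(theta - context.prev_theta_in_frame)
    d_curv_prev = wrap_angle(context.prev_frame_theta - context.prev_frame_theta_prev)
    end_x = x0 + config.segment_length_px * np.cos(theta)
    end_y = y0 + config.segment_length_px * np.sin(theta)
    disp2 = (end_x - context.prev_frame_node[0]) ** 2 + (end_y - context.prev_frame_node[1]) ** 2

    intensity = -config.w_intensity * mean_intensity
    curvature = config.w_curvature * d_curv_now**2
    tvel = config.w_tvel * disp2 / dt2
    rvel = config.w_rvel * wrap_angle(theta - context.prev_frame_theta) ** 2 / dt2
    dcurv = config.w_dcurv * (d_curv_now - d_curv_prev) ** 2 / dt2
    total = intensity + curvature + tvel + rvel + dcurv

    out = {
        "intensity": intensity,
        "curvature": curvature,
        "tvel": tvel,
        "rvel": rvel,
        "dcurv": dcurv,
        "total": total,
        "inside_fraction": inside_fraction,
    }
    if scalar:
        out = {k: float(v[0]) for k, v in out.items()}
    return out


def _select_candidate(candidates: np.ndarray, total: np.ndarray, theta_center: float) -> int:
    """Deterministic argmin: lowest cost, ties to the candidate nearest the
    center of the fan, then to the numerically smaller angle."""
    order = np.lexsort((candidates, np.abs(candidates - theta_center), total))
    return int(order[0])


def trace_frame(
    frame: np.ndarray,
    prev_trace: FrameTrace,
    config: TraceConfig,
    seed_theta0: float | None = None,
    prev_seed_theta0: float | None = None,
    dt_s: float = 1.0,
    frame_index: int | None = None,
) -> tuple[FrameTrace, dict]:
    """Trace one frame given the previous frame's trace.

    Segments are chosen in order from the base: for segment i the candidate
    fan is centered on theta_{i, t-1} and the penalized cost minimizer is
    kept; the within-frame curvature reference of the first segment is the
    seed's initial angle (``seed_theta0``).  Returns the new FrameTrace and a
    dict of that frame's cost components summed over segments.

    If every candidate probe of a segment falls entirely outside the image,
    the trace is truncated there: the remaining segments keep the previous
    frame's angles and ``truncated_at`` records the segment index.
    """
    frame = _prep_frame(frame, config)
    fill = float(np.median(frame))
    if seed_theta0 is None:
        seed_theta0 = float(prev_trace.theta[0])
    if prev_seed_theta0 is None:
        prev_seed_theta0 = seed_theta0

    n = prev_trace.n_segments
    ds = config.segment_length_px
    new_theta = np.empty(n)
    new_nodes = np.empty((n + 1, 2))
    new_nodes[0] = prev_trace.nodes[0]
    totals = {k: 0.0 for k in ("intensity", "curvature", "tvel", "rvel", "dcurv", "total")}
    truncated_at = None

    for i in range(n):
        theta_center = float(prev_trace.theta[i])
        context = SegmentContext(
            prev_theta_in_frame=float(new_theta[i - 1]) if i > 0 else float(seed_theta0),
            prev_frame_theta=theta_center,
            prev_frame_node=(float(prev_trace.nodes[i + 1, 0]), float(prev_trace.nodes[i + 1, 1])),
            prev_frame_theta_prev=(
                float(prev_trace.theta[i - 1]) if i > 0 else float(prev_seed_theta0)
            ),
            dt_s=dt_s,
        )
        candidates = config.candidate_grid(theta_center)
        comp = segment_cost(frame, new_nodes[i], candidates, context, config, fill_value=fill)
        if np.max(comp["inside_fraction"]) == 0.0:
            truncated_at = i
            new_theta[i:] = prev_trace.theta[i:]
            for j in range(i, n):
                new_nodes[j + 1] = new_nodes[j] + ds * np.array(
                    [math.cos(new_theta[j]), math.sin(new_theta[j])]
                )
            break
        k = _select_candidate(candidates, comp["total"], theta_center)
        new_theta[i] = candidates[k]
        new_nodes[i + 1] = new_nodes[i] + ds * np.array(
            [math.cos(new_theta[i]), math.sin(new_theta[i])]
        )
        for key in totals:
            totals[key] += float(comp[key][k])

    # report the frame total as the exact sum of its accumulated components
    totals["total"] = (
        totals["intensity"] + totals["curvature"] + totals["tvel"] + totals["rvel"] + totals["dcurv"]
    )
    fi = frame_index if frame_index is not None else prev_trace.frame_index + 1
    return (
        FrameTrace(nodes=new_nodes, theta=new_theta, frame_index=fi, truncated_at=truncated_at),
        totals,
    )


def trace_movie(
    stack: ImageStack,
    seed: Seed,
    config: TraceConfig | None = None,
    frame_range: FrameRange | None = None,
) -> tuple[CiliumTrace, CostBreakdown]:
    """Trace a cilium through a (stabilized) movie.

    The seed polyline is resampled on the first frame of the range; each
    subsequent frame is traced with the previous frame as temporal context.
    The first frame's cost entry scores the seed chain itself (its temporal
    penalties are zero by construction).  Fully deterministic: identical
    inputs give bit-identical traces.
    """
    if config is None:
        config = TraceConfig()
    if frame_range is None:
        frame_range = FrameRange(0, stack.n_frames)
    if frame_range.end > stack.n_frames:
        raise ValueError("frame range out of bounds")
    dt = stack.frame_interval_s

    frames = stack.frames[frame_range.start : frame_range.end]
    first = _prep_frame(frames[0], config)
    trace0 = init_seed(first, seed, config)
    trace0 = replace(trace0, frame_index=frame_range.start)
    seed_theta0 = float(trace0.theta[0])

    traces = [trace0]
    cost_rows = [_score_chain(first, trace0, config, seed_theta0, dt)]
    prev = trace0
    for t in range(1, len(frames)):
        new_trace, totals = trace_frame(
            frames[t],
            prev,
            config,
            seed_theta0=seed_theta0,
            prev_seed_theta0=seed_theta0,
            dt_s=dt,
            frame_index=frame_range.start + t,
        )
        traces.append(new_trace)
        cost_rows.append(totals)
        prev = new_trace

    theta = np.stack([tr.theta for tr in traces])
    nodes = np.stack([tr.nodes for tr in traces])
    fi = np.array([tr.frame_index for tr in traces])
    trace = CiliumTrace(
        theta=theta,
        nodes=nodes,
        frame_indices=fi,
        segment_length_px=config.segment_length_px,
        pixel_size_um=stack.pixel_size_um,
        frame_interval_s=stack.frame_interval_s,
    )
    costs = CostBreakdown(
        frame_indices=fi,
        intensity=np.array([r["intensity"] for r in cost_rows]),
        curvature=np.array([r["curvature"] for r in cost_rows]),
        tvel=np.array([r["tvel"] for r in cost_rows]),
        rvel=np.array([r["rvel"] for r in cost_rows]),
        dcurv=np.array([r["dcurv"] for r in cost_rows]),
        total=np.array([r["total"] for r in cost_rows]),
    )
    return trace, costs


def _score_chain(
    frame: np.ndarray, chain: FrameTrace, config: TraceConfig, seed_theta0: float, dt: float
) -> dict:
    """Cost of an existing chain on a frame, with itself as temporal context
    (velocity terms vanish)."""
    fill = float(np.median(frame))
    totals = {k: 0.0 for k in ("intensity", "curvature", "tvel", "rvel", "dcurv", "total")}
    for i in range(chain.n_segments):
        context = SegmentContext(
            prev_theta_in_frame=float(chain.theta[i - 1]) if i > 0 else seed_theta0,
            prev_frame_theta=float(chain.theta[i]),
            prev_frame_node=(float(chain.nodes[i + 1, 0]), float(chain.nodes[i + 1, 1])),
            prev_frame_theta_prev=float(chain.theta[i - 1]) if i > 0 else seed_theta0,
            dt_s=dt,
        )
        comp = segment_cost(
            frame, chain.nodes[i], float(chain.theta[i]), context, config, fill_value=fill
        )
        for key in totals:
            totals[key] += comp[key]
    totals["total"] = (
        totals["intensity"] + totals["curvature"] + totals["tvel"] + totals["rvel"] + totals["dcurv"]
    )
    return totals


def cost_diagnostics(costs: CostBreakdown) -> dict:
    """Mean and +/- 2 SD bands of the total-cost series; frames above the
    upper band are flagged as candidate tracking failures for manual review.

    The SD is the population SD of the per-frame totals.
    """
    total = np.asarray(costs.total, dtype=float)
    if total.shape[0] < 2:
        raise ValueError("cost diagnostics need at least 2 frames")
    mean = float(total.mean())
    sd = float(total.std(ddof=0))
    upper = mean + 2.0 * sd
    lower = mean - 2.0 * sd
    outliers = costs.frame_indices[total > upper]
    return {
        "mean": mean,
        "sd": sd,
        "upper": upper,
        "lower": lower,
        "outlier_frames": np.asarray(outliers, dtype=int),
    }
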