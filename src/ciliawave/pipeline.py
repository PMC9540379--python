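"""Structured run configuration and end-to-end orchestration.

A single YAML config drives the full pipeline: (optional) synthetic movie
generation, drift stabilization, seeded tracing, waveform metrics and
diagnostic plots.  Every artifact is written under one output directory,
together with the effective config, so a run can be reproduced from its own
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import numpy as np
import pandas as pd
import yaml

from .metrics import summarize
from .stabilize import apply_correction, estimate_drift
from .stack import FrameRange, ImageStack, read_stack, select_frames, write_stack
from .synthetic import GroundTruth, RenderParams, WaveformModel, simulate_cilium_movie
from .tracer import Seed, TraceConfig, trace_movie
from .viz import plot_cost_series, plot_waveform_heatmap

logger = logging.getLogger(__name__)

_DEFAULTS = {
    "seed": 0,
    "pixel_size_um": 0.35,
    "frame_interval_s": 2.0,
    "output_dir": "ciliawave_out",
    "input_stack": None,
    "frames": None,
    "simulate": {"enabled": False, "n_frames": 120, "shape": [512, 512], "model": {}, "render": {}},
    "stabilize": {"enabled": True, "upsample": 10, "window": True, "save_stabilized": False},
    "seed_points": None,
    "trace": {},
    "log_level": "INFO",
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    cfg = {}
    for key, default in _DEFAULTS.items():
        if isinstance(default, dict):
            cfg[key] = {**default, **(user.get(key) or {})}
        else:
            cfg[key] = user.get(key, default)
    return cfg


def validate_config(cfg: dict) -> list[str]:
    """Return the full list of config violations (empty = valid)."""
    errors = []
    if not cfg.get("pixel_size_um", 0) > 0:
        errors.append("pixel_size_um must be positive")
    if not cfg.get("frame_interval_s", 0) > 0:
        errors.append("frame_interval_s must be positive")
    sim = cfg.get("simulate", {})
    if not sim.get("enabled"):
        stack = cfg.get("input_stack")
        if not stack:
            errors.append("either input_stack or simulate.enabled is required")
        elif not os.path.exists(stack):
            errors.append(f"input_stack does not exist: {stack}")
        if cfg.get("seed_points") is None:
            errors.append("seed_points is required when tracing a real movie")
    else:
        if sim.get("n_frames", 0) < 1:
            errors.append("simulate.n_frames must be >= 1")
    frames = cfg.get("frames")
    if frames is not None:
        if len(frames) != 2 or not frames[0] < frames[1] or frames[0] < 0:
            errors.append(f"frames must be [start, end) with 0 <= start < end, got {frames}")
    st = cfg.get("stabilize", {})
    if st.get("enabled") and st.get("upsample", 1) < 1:
        errors.append("stabilize.upsample must be >= 1")
    try:
        _trace_config(cfg)
    except (ValueError, TypeError) as exc:
        errors.append(f"trace config: {exc}")
    return errors


def _trace_config(cfg: dict) -> TraceConfig:
    opts = dict(cfg.get("trace") or {})
    opts.pop("seed_json", None)
    fields = {f.name for f in dataclasses.fields(TraceConfig)}
    unknown = set(opts) - fields
    if unknown:
        raise ValueError(f"unknown trace options: {sorted(unknown)}")
    if "probe_samples" in opts:
        opts["probe_samples"] = tuple(opts["probe_samples"])
    return TraceConfig(**opts)


def seed_from_truth(truth: GroundTruth, n_points: int = 12) -> Seed:
    """Build a tracing seed from the frame-0 ground-truth centerline.

    Convenience for synthetic runs: emulates a user clicking n_points evenly
    spaced along the cilium on the first frame.
    """
    nodes = truth.centerline[0]
    idx = np.linspace(0, nodes.shape[0] - 1, n_points).round().astype(int)
    pts = nodes[idx]
    return Seed(base_xy=(float(pts[0, 0]), float(pts[0, 1])), polyline=pts)


def run_pipeline(cfg: dict, output_dir: str | None = None) -> dict:
    """Execute simulate (optional) -> stabilize -> trace -> metrics -> plots.

    Returns a dict of artifact paths.  Raises ValueError listing every
    config violation at once if the config is invalid.
    """
    cfg = merge_config(cfg)
    if output_dir is not None:
        cfg["output_dir"] = output_dir
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config:\n- " + "\n- ".join(errors))
    logging.basicConfig(level=getattr(logging, str(cfg["log_level"]).upper(), logging.INFO))

    out_dir = cfg["output_dir"]
    os.makedirs(out_dir, exist_ok=True)
    artifacts = {}

    truth = None
    if cfg["simulate"]["enabled"]:
        sim = cfg["simulate"]
        model = WaveformModel(**{k: tuple(v) if k == "base_xy" else v for k, v in sim["model"].items()})
        render_opts = dict(sim["render"])
        render_opts.setdefault("rng_seed", cfg["seed"])
        render = RenderParams(**{k: tuple(v) if isinstance(v, list) else v for k, v in render_opts.items()})
        stack, truth = simulate_cilium_movie(
            model,
            render,
            n_frames=sim["n_frames"],
            shape=tuple(sim["shape"]),
            pixel_size_um=cfg["pixel_size_um"],
            frame_interval_s=cfg["frame_interval_s"],
        )
        movie_path = os.path.join(out_dir, "movie.tif")
        write_stack(stack, movie_path)
        artifacts["movie"] = movie_path
        truth_path = os.path.join(out_dir, "truth.json")
        _write_truth(truth, truth_path)
        artifacts["truth"] = truth_path
        logger.info("simulated %d-frame movie -> %s", stack.n_frames, movie_path)
    else:
        stack = read_stack(
            cfg["input_stack"],
            pixel_size_um=cfg["pixel_size_um"],
            frame_interval_s=cfg["frame_interval_s"],
        )

    if cfg["frames"] is not None:
        stack = select_frames(stack, FrameRange(int(cfg["frames"][0]), int(cfg["frames"][1])))

    if cfg["stabilize"]["enabled"] and stack.n_frames >= 2:
        drift = estimate_drift(
            stack, upsample=int(cfg["stabilize"]["upsample"]), window=bool(cfg["stabilize"]["window"])
        )
        stack = apply_correction(stack, drift)
        drift_path = os.path.join(out_dir, "drift.csv")
        pd.DataFrame(
            {
                "frame": np.arange(len(drift)),
                "dx_px": drift.shifts[:, 0],
                "dy_px": drift.shifts[:, 1],
            }
        ).to_csv(drift_path, index=False)
        artifacts["drift"] = drift_path
        if cfg["stabilize"]["save_stabilized"]:
            stab_path = os.path.join(out_dir, "stabilized.tif")
            write_stack(stack, stab_path)
            artifacts["stabilized"] = stab_path

    if cfg["seed_points"] is not None:
        seed = Seed.from_dict(cfg["seed_points"])
    else:
        seed = seed_from_truth(truth)
    trace_cfg = _trace_config(cfg)
    trace, costs = trace_movie(stack, seed, trace_cfg)

    trace_path = os.path.join(out_dir, "trace.csv")
    trace.to_csv(trace_path)
    artifacts["trace"] = trace_path
    costs_path = os.path.join(out_dir, "costs.csv")
    costs.to_csv(costs_path)
    artifacts["costs"] = costs_path

    metrics = summarize(trace)
    metrics_path = os.path.join(out_dir, "metrics.json")
    metrics.to_json(metrics_path)
    artifacts["metrics"] = metrics_path

    if trace.n_frames >= 2:
        artifacts["waveform_plot"] = plot_waveform_heatmap(
            trace, os.path.join(out_dir, "waveform.png")
        )
        artifacts["cost_plot"] = plot_cost_series(costs, os.path.join(out_dir, "costs.png"))

    cfg_path = os.path.join(out_dir, "config_used.yaml")
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    artifacts["config"] = cfg_path
    logger.info("pipeline artifacts: %s", sorted(artifacts))
    return artifacts


def _write_truth(truth: GroundTruth, path) -> str:
    payload = {
        "model": dataclasses.asdict(truth.model),
        "pixel_size_um": truth.pixel_size_um,
        "frame_interval_s": truth.frame_interval_s,
        "s_grid_px": truth.s_grid_px.tolist(),
        "drift": truth.drift.tolist(),
        "theta": truth.theta.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
    return str(path)
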