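"""Diagnostic plots: temporal waveform heatmap and cost-series panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.cm import ScalarMappable
from matplotlib.colors import Normalize

from .tracer import CiliumTrace, CostBreakdown, cost_diagnostics


def plot_waveform_heatmap(trace: CiliumTrace, out) -> str:
    """Overlay every frame's traced centerline, colored by time.

    The panel mirrors the image coordinate system (y down) so the overlay
    matches the movie orientation; the colorbar maps color to seconds from
    the first analyzed frame.
    """
    if trace.n_frames < 1:
        raise ValueError("empty trace")
    times = (trace.frame_indices - trace.frame_indices[0]) * trace.frame_interval_s
    tmax = float(times[-1]) if times[-1] > 0 else 1.0
    norm = Normalize(vmin=0.0, vmax=tmax)
    cmap = plt.get_cmap("viridis")

    fig, ax = plt.subplots(figsize=(5, 5))
    for k in range(trace.n_frames):
        ax.plot(
            trace.nodes[k, :, 0],
            trace.nodes[k, :, 1],
            color=cmap(norm(times[k])),
            linewidth=1.0,
            alpha=0.8,
        )
    ax.set_aspect("equal")
    ax.invert_yaxis()
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title("Cilium waveform (temporal heatmap)")
    fig.colorbar(ScalarMappable(norm=norm, cmap=cmap), ax=ax, label="time (s)")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return str(out)


def plot_cost_series(costs: CostBreakdown, out) -> str:
    """Per-term penalties and total cost vs frame.

    The total-cost panel shows a dashed mean line and the mean +/- 2 SD
    bands; frames above the upper band are candidate tracking failures.
    """
    if np.asarray(costs.total).shape[0] < 2:
        raise ValueError("cost plot needs at least 2 frames")
    diag = cost_diagnostics(costs)
    frames = costs.frame_indices

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    for name, series in [
        ("intensity", costs.intensity),
        ("curvature", costs.curvature),
        ("transl. velocity", costs.tvel),
        ("rot. velocity", costs.rvel),
        ("d curvature/dt", costs.dcurv),
    ]:
        ax1.plot(frames, series, label=name, linewidth=1.0)
    ax1.set_ylabel("cost component")
    ax1.legend(fontsize=7, ncol=2)

    ax2.plot(frames, costs.total, color="black", linewidth=1.0, label="total")
    ax2.axhline(diag["mean"], linestyle="--", color="gray", label="mean")
    ax2.axhline(diag["upper"], color="red", linewidth=0.8, label="mean + 2 SD")
    ax2.axhline(diag["lower"], color="green", linewidth=0.8, label="mean - 2 SD")
    ax2.set_xlabel("frame")
    ax2.set_ylabel("total cost")
    ax2.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return str(out)
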