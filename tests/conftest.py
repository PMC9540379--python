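import numpy as np
import pytest

import ciliawave as cw
from ciliawave.pipeline import seed_from_truth


def make_trace(theta, segment_length_px=4.0, pixel_size_um=0.35, frame_interval_s=2.0, base=(0.0, 0.0)):
    """Build a CiliumTrace directly from a (T, N) angle array.

    Nodes are integrated from the base with exact segment lengths, matching
    the tracer's chain construction.
    """
    theta = np.asarray(theta, dtype=float)
    t, n = theta.shape
    nodes = np.zeros((t, n + 1, 2))
    nodes[:, 0] = base
    for i in range(n):
        nodes[:, i + 1, 0] = nodes[:, i, 0] + segment_length_px * np.cos(theta[:, i])
        nodes[:, i + 1, 1] = nodes[:, i, 1] + segment_length_px * np.sin(theta[:, i])
    return cw.CiliumTrace(
        theta=theta,
        nodes=nodes,
        frame_indices=np.arange(t),
        segment_length_px=segment_length_px,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
    )


@pytest.fixture(scope="session")
def small_movie():
    """Compact rigid-pivot scene for unit tests: 40 frames, 128 x 128, SNR 10."""
    model = cw.WaveformModel(base_xy=(64.0, 64.0), base_angle_rad=-0.6, length_um=6.0)
    render = cw.RenderParams(rng_seed=5, noise_sigma=18.0)
    stack, truth = cw.simulate_cilium_movie(model, render, n_frames=40, shape=(128, 128))
    return stack, truth


@pytest.fixture(scope="session")
def small_seed(small_movie):
    _, truth = small_movie
    return seed_from_truth(truth)
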