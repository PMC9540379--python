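"""Synthetic beating-cilium movies with exact ground truth.

The generator renders a single fluorescently labeled cilium beating inside a
tissue-like field, so that the tracer and the waveform metrics can be
validated by parameter recovery without any real acquisition.  The tangent
angle of the filament follows a single-harmonic traveling wave

    theta(s, t) = theta0 + A * sin(phase(t) - k * s + phi0),

where s is arc length from the base (um), A the angular amplitude (rad),
phase(t) = 2*pi*t/T_beat for a regular beat (optional per-cycle period
jitter makes the beat irregular), and k the spatial wavenumber (k = 0 is a
rigid pivot about the base).  The centerline is obtained by integrating the
tangent field from the fixed base and rendered with a Gaussian transverse
profile of sub-micron width, over a constant background, optional static
tissue blobs, cumulative random-walk drift of the whole field, and additive
Gaussian noise.  The signal-to-noise ratio of a scene is
(peak_intensity - background) / noise_sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .stack import ImageStack

_ARC_STEP_PX = 0.4  # integration / rendering step along the filament


@dataclass(frozen=True)
class WaveformModel:
    """Ground-truth beat model of one cilium.

    base_xy is in pixels (x = column, y = row); angles follow the image
    convention (y grows downward).  wavenumber_per_um = 0 gives a rigid pivot;
    positive values make the bend travel base-to-tip.  period_jitter_sd is
    the SD of a multiplicative Gaussian perturbation applied to each beat
    cycle's period (0 = perfectly regular beat).
    """

    base_xy: tuple[float, float] = (256.0, 256.0)
    base_angle_rad: float = -0.6
    length_um: float = 8.0
    amplitude_rad: float = 0.3
    period_s: float = 24.0
    wavenumber_per_um: float = 0.0
    phase0_rad: float = 0.0
    period_jitter_sd: float = 0.0

    def __post_init__(self):
        if not self.length_um > 0:
            raise ValueError("length_um must be positive")
        if self.amplitude_rad < 0:
            raise ValueError("amplitude_rad must be >= 0")
        if not self.period_s > 0:
            raise ValueError("period_s must be positive")
        if self.wavenumber_per_um < 0:
            raise ValueError("wavenumber_per_um must be >= 0")
        if self.period_jitter_sd < 0:
            raise ValueError("period_jitter_sd must be >= 0")


@dataclass(frozen=True)
class RenderParams:
    """Optical and noise parameters of the rendered movie.

    psf_sigma_um sets the Gaussian transverse half-width of the filament
    (default 0.25 um: diffraction-limited, sub-micron apparent width).
    n_blobs static Gaussian blobs emulate out-of-focus tissue fluorescence
    around the cilium; they move with the field drift and give the
    whole-field registration something to hold on to, as surrounding tissue
    does in a real movie.
    """

    psf_sigma_um: float = 0.25
    peak_intensity: float = 200.0
    background: float = 20.0
    noise_sigma: float = 18.0
    drift_sigma_px: float = 0.0
    rng_seed: int = 0
    n_blobs: int = 0
    blob_sigma_um: tuple[float, float] = (1.0, 3.0)
    blob_rel_intensity: tuple[float, float] = (0.1, 0.5)

    def __post_init__(self):
        if not self.psf_sigma_um > 0:
            raise ValueError("psf_sigma_um must be positive")
        if not self.peak_intensity > self.background >= 0:
            raise ValueError("need peak_intensity > background >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.drift_sigma_px < 0:
            raise ValueError("drift_sigma_px must be >= 0")
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be >= 0")

    @property
    def snr(self) -> float:
        if self.noise_sigma == 0:
            return math.inf
        return (self.peak_intensity - self.background) / self.noise_sigma


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-frame truth emitted alongside a synthetic movie.

    theta[t, j] is the true tangent angle at arc position s_grid_px[j]
    (drift-independent).  centerline[t, j] is the rendered (x, y) position of
    the node at s_grid_px[j], drift included.  drift[t] is the cumulative
    whole-field (dx, dy); drift[0] = (0, 0).
    """

    model: WaveformModel
    s_grid_px: np.ndarray
    theta: np.ndarray
    centerline: np.ndarray
    drift: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    phase: np.ndarray = field(repr=False, default=None)

    def theta_at(self, s_px, frame: int):
        """Closed-form true tangent angle at arc position(s) s_px (pixels)."""
        s_um = np.asarray(s_px, dtype=float) * self.pixel_size_um
        m = self.model
        return m.base_angle_rad + m.amplitude_rad * np.sin(
            self.phase[frame] - m.wavenumber_per_um * s_um + m.phase0_rad
        )


def _beat_phase(model: WaveformModel, times_s: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Phase(t) of the beat; piecewise linear across jittered cycles."""
    if model.period_jitter_sd == 0:
        return 2.0 * np.pi * times_s / model.period_s
    duration = float(times_s[-1]) if len(times_s) else 0.0
    periods = []
    total = 0.0
    while total <= duration + model.period_s:
        p = model.period_s * max(0.1, 1.0 + rng.normal(0.0, model.period_jitter_sd))
        periods.append(p)
        total += p
    starts = np.concatenate([[0.0], np.cumsum(periods)])
    cyc = np.searchsorted(starts, times_s, side="right") - 1
    periods = np.asarray(periods)
    frac = (times_s - starts[cyc]) / periods[cyc]
    return 2.0 * np.pi * (cyc + frac)


def _integrate_centerline(
    base_xy, theta_of_s_px, length_px: float
) -> tuple[np.ndarray, np.ndarray]:
    """Midpoint-rule integration of the tangent field from the base.

    Returns (s_grid, nodes) where nodes[j] is the point at arc length
    s_grid[j]; the step never exceeds _ARC_STEP_PX.
    """
    n_steps = max(1, int(math.ceil(length_px / _ARC_STEP_PX)))
    s_grid = np.linspace(0.0, length_px, n_steps + 1)
    s_mid = 0.5 * (s_grid[:-1] + s_grid[1:])
    th = theta_of_s_px(s_mid)
    steps = np.diff(s_grid)
    dx = np.concatenate([[0.0], np.cumsum(steps * np.cos(th))])
    dy = np.concatenate([[0.0], np.cumsum(steps * np.sin(th))])
    nodes = np.stack([base_xy[0] + dx, base_xy[1] + dy], axis=-1)
    return s_grid, nodes


def _splat_filament(canvas: np.ndarray, points: np.ndarray, sigma_px: float) -> None:
    """Max-splat unit-amplitude Gaussians at each centerline point.

    Taking the maximum (not the sum) of per-point contributions yields a tube
    of constant peak brightness independent of the sampling density along the
    curve.
    """
    h, w = canvas.shape
    r = int(math.ceil(4.0 * sigma_px)) + 1
    inv2s2 = 1.0 / (2.0 * sigma_px * sigma_px)
    for x, y in points:
        x0 = max(0, int(math.floor(x)) - r)
        x1 = min(w, int(math.floor(x)) + r + 1)
        y0 = max(0, int(math.floor(y)) - r)
        y1 = min(h, int(math.floor(y)) + r + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        g = np.exp(-((xx - x) ** 2 + (yy - y) ** 2) * inv2s2)
        np.maximum(canvas[y0:y1, x0:x1], g, out=canvas[y0:y1, x0:x1])


def _render_blobs(shape, blobs, drift_xy) -> np.ndarray:
    h, w = shape
    out = np.zeros(shape, dtype=np.float64)
    for cx, cy, sigma, amp in blobs:
        x = cx + drift_xy[0]
        y = cy + drift_xy[1]
        r = int(math.ceil(4.0 * sigma)) + 1
        x0 = max(0, int(math.floor(x)) - r)
        x1 = min(w, int(math.floor(x)) + r + 1)
        y0 = max(0, int(math.floor(y)) - r)
        y1 = min(h, int(math.floor(y)) + r + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        out[y0:y1, x0:x1] += amp * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma * sigma)
        )
    return out


def simulate_cilium_movie(
    model: WaveformModel,
    render: RenderParams,
    n_frames: int = 300,
    shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = 0.35,
    frame_interval_s: float = 2.0,
) -> tuple[ImageStack, GroundTruth]:
    """Render a ground-truthed beating-cilium movie.

    Defaults mirror a typical confocal live-imaging session: 512 x 512 field
    at 0.35 um/pixel, one frame every 2 s, 300 frames (10 min).  Identical
    RenderParams.rng_seed gives a bit-identical movie.

    Raises ValueError if the filament (including drift) would leave the frame.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    h, w = shape
    if h < 2 or w < 2:
        raise ValueError("frame geometry must be at least 2 x 2")

    rng = np.random.default_rng(render.rng_seed)
    times = np.arange(n_frames, dtype=float) * frame_interval_s
    phase = _beat_phase(model, times, rng)

    # static tissue blobs (scene coordinates; drift moves them)
    blobs = []
    for _ in range(render.n_blobs):
        cx = rng.uniform(0.08 * w, 0.92 * w)
        cy = rng.uniform(0.08 * h, 0.92 * h)
        sigma = rng.uniform(*render.blob_sigma_um) / pixel_size_um
        amp = rng.uniform(*render.blob_rel_intensity) * (
            render.peak_intensity - render.background
        )
        blobs.append((cx, cy, sigma, amp))

    # cumulative random-walk drift, drift[0] = 0
    drift = np.zeros((n_frames, 2))
    if render.drift_sigma_px > 0 and n_frames > 1:
        steps = rng.normal(0.0, render.drift_sigma_px, size=(n_frames - 1, 2))
        drift[1:] = np.cumsum(steps, axis=0)

    length_px = model.length_um / pixel_size_um
    sigma_px = render.psf_sigma_um / pixel_size_um
    amp_fil = render.peak_intensity - render.background

    frames = np.empty((n_frames, h, w), dtype=np.float32)
    thetas = []
    centerlines = []
    s_grid = None
    for t in range(n_frames):

        def theta_of(s_px, _t=t):
            s_um = np.asarray(s_px) * pixel_size_um
            return model.base_angle_rad + model.amplitude_rad * np.sin(
                phase[_t] - model.wavenumber_per_um * s_um + model.phase0_rad
            )

        s_grid, nodes = _integrate_centerline(model.base_xy, theta_of, length_px)
        nodes_drifted = nodes + drift[t]
        if (
            nodes_drifted[:, 0].min() < 0
            or nodes_drifted[:, 0].max() > w - 1
            or nodes_drifted[:, 1].min() < 0
            or nodes_drifted[:, 1].max() > h - 1
        ):
            raise ValueError(f"filament leaves the frame at frame {t}")
        thetas.append(theta_of(s_grid))
        centerlines.append(nodes_drifted)

        profile = np.zeros((h, w), dtype=np.float64)
        _splat_filament(profile, nodes_drifted, sigma_px)
        scene = render.background + amp_fil * profile
        if blobs:
            scene = scene + _render_blobs((h, w), blobs, drift[t])
        if render.noise_sigma > 0:
            scene = scene + rng.normal(0.0, render.noise_sigma, size=(h, w))
            np.clip(scene, 0.0, None, out=scene)
        frames[t] = scene.astype(np.float32)

    stack = ImageStack(frames=frames, pixel_size_um=pixel_size_um, frame_interval_s=frame_interval_s)
    truth = GroundTruth(
        model=model,
        s_grid_px=np.asarray(s_grid),
        theta=np.asarray(thetas),
        centerline=np.asarray(centerlines),
        drift=drift,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        phase=phase,
    )
    return stack, truth


def add_noise(frame: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Additive Gaussian noise, clipped at zero; deterministic per seed."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    frame = np.asarray(frame, dtype=float)
    if sigma == 0:
        return frame.copy()
    rng = np.random.default_rng(seed)
    out = frame + rng.normal(0.0, sigma, size=frame.shape)
    np.clip(out, 0.0, None, out=out)
    return out


def apply_drift(stack: ImageStack, drift: np.ndarray) -> ImageStack:
    """Translate frame t by drift[t] = (dx, dy) with bilinear interpolation.

    Fabricates whole-field specimen motion for testing the stabilizer; pixels
    shifted in from outside take the frame median.
    """
    drift = np.asarray(drift, dtype=float)
    if drift.shape != (stack.n_frames, 2):
        raise ValueError(
            f"drift shape {drift.shape} does not match stack with T={stack.n_frames}"
        )
    out = np.empty_like(stack.frames, dtype=np.float32)
    for t in range(stack.n_frames):
        frame = np.asarray(stack.frames[t], dtype=float)
        dx, dy = drift[t]
        shifted = ndi.shift(frame, (dy, dx), order=1, mode="constant", cval=float(np.median(frame)))
        out[t] = shifted.astype(np.float32)
    return ImageStack(frames=out, pixel_size_um=stack.pixel_size_um, frame_interval_s=stack.frame_interval_s)
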