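"""Whole-field drift estimation and removal by FFT phase correlation.

Specimens can translate during live imaging (treatments, osmotic pressure
changes), and the tracer assumes a stationary ciliary base, so translation
must be removed first.  Drift is estimated between consecutive frames from
the peak of the normalized cross-power spectrum (phase correlation), with
optional subpixel refinement by local upsampled cross-correlation, and
accumulated relative to frame 0.  Only translation is corrected; rotation
and scaling are left untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.registration import phase_cross_correlation

from .stack import ImageStack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DriftTrack:
    """Cumulative per-frame translation relative to the reference frame.

    shifts[t] = (dx, dy) is the displacement of frame t's content relative to
    the reference frame, in pixels; shifts[reference_index] = (0, 0).
    """

    shifts: np.ndarray
    reference_index: int = 0

    def __post_init__(self):
        shifts = np.asarray(self.shifts, dtype=float)
        if shifts.ndim != 2 or shifts.shape[1] != 2:
            raise ValueError(f"shifts must be T x 2, got {shifts.shape}")
        if not np.all(np.isfinite(shifts)):
            raise ValueError("shifts must be finite")
        if not np.allclose(shifts[self.reference_index], 0.0):
            raise ValueError("shift at the reference frame must be (0, 0)")
        object.__setattr__(self, "shifts", shifts)

    def __len__(self) -> int:
        return self.shifts.shape[0]


def estimate_drift(
    stack: ImageStack,
    upsample: int = 10,
    window: bool = False,
    bandpass: tuple[float, float] | None = (4.0, 25.0),
) -> DriftTrack:
    """Estimate cumulative whole-field translation by FFT cross-correlation.

    Registers consecutive frame pairs (robust when the scene deforms slowly,
    e.g. a beating cilium, while drift itself is smooth) and accumulates the
    per-step displacements relative to frame 0.  Subpixel precision is
    1/upsample via upsampled DFT around the integer correlation peak.

    Fluorescence scenes are smooth and noisy, so each frame is band-pass
    filtered (difference of Gaussians with the given (low, high) sigmas, in
    pixels) before correlation: without it the correlation peak of a smooth
    scene is broad and wanders under pixel noise.  The default low cutoff of
    4 px also suppresses the sub-micron-wide cilium itself, so registration
    follows the surrounding tissue rather than the moving filament.  For the
    same robustness reason the peak is taken from the plain cross-power
    spectrum rather than the whitened (pure-phase) one.  An optional
    raised-cosine (Hann) window is available but off by default:
    apodization biases each estimated step toward zero by a fraction of the
    true displacement, which accumulates over the movie, while the
    wrap-around artifacts it guards against are already tamed by the
    zero-mean band-passed input.  Constant frames, for which the correlation
    peak is undefined, inherit the previous step with a warning.
    """
    if stack.n_frames < 2:
        raise ValueError("drift estimation needs at least 2 frames")
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    h, w = stack.frames.shape[1:]
    win = np.outer(np.hanning(h), np.hanning(w)) if window else None

    shifts = np.zeros((stack.n_frames, 2))
    prev_step = np.zeros(2)
    prev = _prep(stack.frames[0], win, bandpass)
    for t in range(1, stack.n_frames):
        cur = _prep(stack.frames[t], win, bandpass)
        if prev.std() == 0 or cur.std() == 0:
            logger.warning("frame %d is constant; reusing previous drift step", t)
            step = prev_step
        else:
            # phase_cross_correlation returns the shift registering the moving
            # image onto the reference, i.e. minus the content displacement
            (dy, dx), _, _ = phase_cross_correlation(
                prev, cur, upsample_factor=upsample, normalization=None
            )
            step = np.array([-dx, -dy])
        shifts[t] = shifts[t - 1] + step
        prev_step = step
        prev = cur
    return DriftTrack(shifts=shifts, reference_index=0)


def apply_correction(stack: ImageStack, drift: DriftTrack) -> ImageStack:
    """Undo the estimated translation: frame t is shifted by -shifts[t].

    Bilinear interpolation; pixels pulled in from outside the field take the
    frame median as a background estimate.
    """
    if len(drift) != stack.n_frames:
        raise ValueError(
            f"drift track length {len(drift)} does not match stack with T={stack.n_frames}"
        )
    out = np.empty_like(stack.frames, dtype=np.float32)
    for t in range(stack.n_frames):
        frame = np.asarray(stack.frames[t], dtype=float)
        dx, dy = drift.shifts[t]
        corrected = ndi.shift(
            frame, (-dy, -dx), order=1, mode="constant", cval=float(np.median(frame))
        )
        out[t] = corrected.astype(np.float32)
    return ImageStack(
        frames=out, pixel_size_um=stack.pixel_size_um, frame_interval_s=stack.frame_interval_s
    )


def _prep(
    frame: np.ndarray, win: np.ndarray | None, bandpass: tuple[float, float] | None
) -> np.ndarray:
    frame = np.asarray(frame, dtype=np.float64)
    if bandpass is not None:
        lo, hi = bandpass
        frame = ndi.gaussian_filter(frame, lo) - ndi.gaussian_filter(frame, hi)
    else:
        frame = frame - frame.mean()
    if win is not None:
        frame = frame * win
    return frame
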