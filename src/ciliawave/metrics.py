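"""Waveform metrics derived from the raw tangent-angle data of a trace.

All statistics are restricted to the middle 80% of the cilium's length
(arc-length band [0.1 L, 0.9 L]), excluding the clamped base and the noisy
tip.  Amplitude is the population standard deviation of theta pooled over
that band and all frames; the beat period comes from the first peak of the
autocorrelation of the band-averaged angle, whose height defines the
periodicity score; maximal curvature is the largest absolute angle change
per unit arc length between adjacent segments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from ._util import circular_mean, wrap_angle
from .tracer import CiliumTrace

__all__ = [
    "WaveformMetrics",
    "PeriodEstimate",
    "compute_amplitude",
    "estimate_period",
    "compute_length_um",
    "compute_max_curvature",
    "summarize",
]

_MIN_PERIOD_FRAMES = 20
_PERIODICITY_FLOOR = 0.2


class PeriodEstimate(NamedTuple):
    period_s: float | None
    periodicity: float
    frequency_hz: float | None
    reliable: bool


@dataclass(frozen=True)
class WaveformMetrics:
    """Per-cilium waveform summary."""

    amplitude_rad: float
    period_s: float | None
    frequency_hz: float | None
    periodicity: float
    length_um: float
    max_curvature_per_um: float
    n_frames_used: int
    flags: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "amplitude_rad": self.amplitude_rad,
            "period_s": self.period_s,
            "frequency_hz": self.frequency_hz,
            "periodicity": self.periodicity,
            "length_um": self.length_um,
            "max_curvature_per_um": self.max_curvature_per_um,
            "n_frames_used": self.n_frames_used,
            "flags": list(self.flags),
        }

    def to_json(self, path) -> str:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        return str(path)


def _middle_segment_mask(n_segments: int, middle_fraction: float = 0.8) -> np.ndarray:
    """Segments whose arc-length midpoint lies within the central band.

    Segment i (0-based) has midpoint (i + 0.5) * ds on a cilium of length
    N * ds; the band is [(1-f)/2, (1+f)/2] in relative arc length.
    """
    if not 0 < middle_fraction <= 1:
        raise ValueError("middle_fraction must be in (0, 1]")
    s_mid = (np.arange(n_segments) + 0.5) / n_segments
    lo = (1.0 - middle_fraction) / 2.0
    hi = 1.0 - lo
    return (s_mid >= lo - 1e-12) & (s_mid <= hi + 1e-12)


def compute_amplitude(trace: CiliumTrace, middle_fraction: float = 0.8) -> float:
    """Beat amplitude: population SD of theta pooled over the middle band
    and all frames.

    Angles are unwrapped about their circular mean before the SD so that a
    cilium oriented near the +/- pi branch cut gets the same answer as one
    along the x-axis.
    """
    mask = _middle_segment_mask(trace.n_segments, middle_fraction)
    pooled = trace.theta[:, mask].ravel()
    if pooled.size < 2:
        raise ValueError("amplitude needs at least 2 pooled angle values")
    mu = circular_mean(pooled)
    dev = wrap_angle(pooled - mu)
    return float(np.std(dev, ddof=0))


def mean_angle_series(trace: CiliumTrace, middle_fraction: float = 0.8) -> np.ndarray:
    """phi(t): mean tangent angle over the middle band, per frame."""
    mask = _middle_segment_mask(trace.n_segments, middle_fraction)
    mu = circular_mean(trace.theta[:, mask].ravel())
    dev = wrap_angle(trace.theta[:, mask] - mu)
    return mu + dev.mean(axis=1)


def estimate_period(
    trace: CiliumTrace,
    frame_interval_s: float | None = None,
    middle_fraction: float = 0.8,
) -> PeriodEstimate:
    """Beat period, periodicity and frequency from the mean-angle series.

    The mean-centered series phi(t) is autocorrelated (biased estimator,
    normalized to 1 at lag 0, searched up to half the record); the period is
    the lag of the first local maximum at lag >= 2 frames whose height
    exceeds 0.2, refined to sub-frame precision by a parabola through the
    three correlations around the peak.  The periodicity score is the
    (clipped) peak height: near 1 for a regular beat, near 0 for aperiodic
    wiggling.  The biased estimator damps the wild long-lag excursions of
    the sample autocorrelation, at the price of shrinking the score by a
    factor (1 - lag/T) — negligible when several beat cycles are recorded.
    If no qualifying peak exists the period is unreliable and reported as
    absent.
    """
    if frame_interval_s is None:
        frame_interval_s = trace.frame_interval_s
    phi = mean_angle_series(trace, middle_fraction)
    t = phi.shape[0]
    if t < _MIN_PERIOD_FRAMES:
        raise ValueError(f"period estimation needs at least {_MIN_PERIOD_FRAMES} frames, got {t}")
    x = phi - phi.mean()
    var = float(np.dot(x, x)) / t
    if var == 0:
        return PeriodEstimate(None, 0.0, None, False)

    max_lag = t // 2
    ac = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        ac[k] = np.dot(x[: t - k], x[k:]) / t / var

    best = None
    for k in range(2, max_lag):
        if ac[k] > ac[k - 1] and ac[k] >= ac[k + 1]:
            if ac[k] > _PERIODICITY_FLOOR:
                best = k
                break
    if best is None:
        return PeriodEstimate(None, float(np.clip(ac[2:].max(initial=0.0), 0.0, 1.0)), None, False)

    # parabolic refinement around the integer-lag peak
    y0, y1, y2 = ac[best - 1], ac[best], ac[best + 1]
    denom = y0 - 2.0 * y1 + y2
    delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    delta = float(np.clip(delta, -0.5, 0.5))
    period = (best + delta) * frame_interval_s
    peak = y1 - 0.25 * (y0 - y2) * delta
    periodicity = float(np.clip(peak, 0.0, 1.0))
    return PeriodEstimate(float(period), periodicity, float(1.0 / period), True)


def compute_length_um(trace: CiliumTrace, pixel_size_um: float | None = None) -> float:
    """Cilium length: N segments of ds pixels at the given scale (constant
    across frames by construction of the trace)."""
    if pixel_size_um is None:
        pixel_size_um = trace.pixel_size_um
    if trace.n_segments < 1:
        raise ValueError("empty trace")
    return float(trace.n_segments * trace.segment_length_px * pixel_size_um)


def compute_max_curvature(
    trace: CiliumTrace,
    pixel_size_um: float | None = None,
    middle_fraction: float = 0.8,
) -> float:
    """Maximal curvature |d theta / d s| over joints in the middle band and
    all frames, in 1/um.

    The discrete curvature at the joint between segments i and i+1 is
    |wrap(theta_{i+1} - theta_i)| / (ds_um).
    """
    if pixel_size_um is None:
        pixel_size_um = trace.pixel_size_um
    n = trace.n_segments
    if n < 2:
        raise ValueError("max curvature needs at least 2 segments")
    ds_um = trace.segment_length_px * pixel_size_um
    s_joint = np.arange(1, n) / n  # joint i/n in relative arc length
    lo = (1.0 - middle_fraction) / 2.0
    mask = (s_joint >= lo - 1e-12) & (s_joint <= 1.0 - lo + 1e-12)
    if not mask.any():
        mask = np.ones_like(mask)
    dtheta = wrap_angle(trace.theta[:, 1:] - trace.theta[:, :-1])[:, mask]
    return float(np.max(np.abs(dtheta)) / ds_um)


def summarize(
    trace: CiliumTrace,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
    middle_fraction: float = 0.8,
) -> WaveformMetrics:
    """Assemble all waveform metrics for one cilium."""
    flags = []
    amplitude = compute_amplitude(trace, middle_fraction)
    length = compute_length_um(trace, pixel_size_um)
    max_curv = compute_max_curvature(trace, pixel_size_um, middle_fraction)
    if trace.n_frames >= _MIN_PERIOD_FRAMES:
        est = estimate_period(trace, frame_interval_s, middle_fraction)
        if not est.reliable:
            flags.append("period_unreliable")
    else:
        est = PeriodEstimate(None, 0.0, None, False)
        flags.append("period_unreliable")
        flags.append("too_few_frames")
    return WaveformMetrics(
        amplitude_rad=amplitude,
        period_s=est.period_s,
        frequency_hz=est.frequency_hz,
        periodicity=est.periodicity,
        length_um=length,
        max_curvature_per_um=max_curv,
        n_frames_used=trace.n_frames,
        flags=tuple(flags),
    )
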