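"""Shared angle and interpolation helpers."""

from __future__ import annotations

import numpy as np


def wrap_angle(theta):
    """Wrap angle differences to the interval (-pi, pi].

    Works elementwise on arrays.  The closed upper end matters only for the
    measure-zero case of an exact half-turn, which is mapped to +pi so that
    wrap(-x) == -wrap(x) except there.
    """
    theta = np.asarray(theta, dtype=float)
    wrapped = np.remainder(theta + np.pi, 2.0 * np.pi) - np.pi
    # remainder puts exact half-turns at -pi; move them to +pi
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


def circular_mean(theta) -> float:
    """Mean direction of a set of angles (radians)."""
    theta = np.asarray(theta, dtype=float)
    return float(np.arctan2(np.mean(np.sin(theta)), np.mean(np.cos(theta))))


def bilinear_sample(frame: np.ndarray, x: np.ndarray, y: np.ndarray, fill: float) -> np.ndarray:
    """Bilinear interpolation of ``frame`` at (x, y) pixel positions.

    x indexes columns, y indexes rows.  Samples outside the image footprint
    (beyond the outermost pixel centers) take ``fill``.
    """
    h, w = frame.shape
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    inside = (x >= 0.0) & (x <= w - 1.0) & (y >= 0.0) & (y <= h - 1.0)
    xc = np.clip(x, 0.0, w - 1.0)
    yc = np.clip(y, 0.0, h - 1.0)
    x0 = np.floor(xc).astype(np.intp)
    y0 = np.floor(yc).astype(np.intp)
    x0 = np.minimum(x0, w - 2) if w > 1 else x0 * 0
    y0 = np.minimum(y0, h - 2) if h > 1 else y0 * 0
    fx = xc - x0
    fy = yc - y0
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    v = (
        frame[y0, x0] * (1 - fx) * (1 - fy)
        + frame[y0, x1] * fx * (1 - fy)
        + frame[y1, x0] * (1 - fx) * fy
        + frame[y1, x1] * fx * fy
    )
    return np.where(inside, v, fill)
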