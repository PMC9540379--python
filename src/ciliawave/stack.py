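"""Calibrated time-lapse image stacks: TIFF I/O and frame-range selection.

A stack is T grayscale frames with an isotropic pixel size (um/pixel) and a
frame interval (s).  Calibration is carried in the TIFF image-description tag
as JSON so that a written stack round-trips without sidecar files; explicit
arguments override embedded metadata (acquisition metadata is frequently
wrong or absent).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

_DESCRIPTION_KEYS = ("pixel_size_um", "frame_interval_s")


@dataclass(frozen=True)
class ImageStack:
    """T ordered frames of scalar intensities with physical calibration.

    frames has shape (T, H, W); pixel (0, 0) is the top-left corner, x is the
    column index and y the row index.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self):
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {frames.shape}")
        if frames.shape[0] < 1:
            raise ValueError("stack must contain at least one frame")
        if not np.all(np.isfinite(frames)):
            raise ValueError("frame intensities must be finite")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        if not self.frame_interval_s > 0:
            raise ValueError(f"frame_interval_s must be positive, got {self.frame_interval_s}")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass(frozen=True)
class FrameRange:
    """Half-open, 0-based frame interval [start, end)."""

    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid frame range [{self.start}, {self.end}): need 0 <= start < end")

    def __len__(self) -> int:
        return self.end - self.start


def read_stack(
    path: str | os.PathLike,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> ImageStack:
    """Read a single-channel multi-page TIFF as an ImageStack.

    The first dimension is time.  Calibration is taken from the image
    description (JSON with keys ``pixel_size_um`` / ``frame_interval_s``)
    unless overridden by the arguments; a disagreement is logged.  RGB /
    multi-channel pages are rejected.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such TIFF: {path}")
    with tifffile.TiffFile(path) as tif:
        page0 = tif.pages[0]
        if page0.samplesperpixel not in (None, 1):
            raise ValueError(
                "expected a single-channel grayscale multi-page TIFF "
                f"(T pages of H x W); got {page0.samplesperpixel} samples per pixel"
            )
        _check_isotropic(page0)
        meta = _parse_description(page0.description)
        data = tif.asarray()
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            "expected a single-channel grayscale multi-page TIFF "
            f"(T pages of H x W); got array of shape {data.shape}"
        )

    px = _resolve_calibration("pixel_size_um", pixel_size_um, meta)
    dt = _resolve_calibration("frame_interval_s", frame_interval_s, meta)
    return ImageStack(frames=data, pixel_size_um=px, frame_interval_s=dt)


def write_stack(stack: ImageStack, path: str | os.PathLike) -> str:
    """Write a multi-page grayscale TIFF with calibration in the description."""
    parent = os.path.dirname(os.fspath(path)) or "."
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"output directory does not exist: {parent}")
    description = json.dumps(
        {"pixel_size_um": stack.pixel_size_um, "frame_interval_s": stack.frame_interval_s}
    )
    tifffile.imwrite(path, stack.frames, description=description, photometric="minisblack")
    return os.fspath(path)


def select_frames(stack: ImageStack, frame_range: FrameRange) -> ImageStack:
    """Return the sub-stack of frames [start, end) with unchanged calibration.

    Selecting a range within one long acquisition supports condition-wise
    comparison (e.g. before/after a treatment) from a single movie.
    """
    if frame_range.end > stack.n_frames:
        raise ValueError(
            f"frame range [{frame_range.start}, {frame_range.end}) out of bounds for T={stack.n_frames}"
        )
    return ImageStack(
        frames=stack.frames[frame_range.start : frame_range.end],
        pixel_size_um=stack.pixel_size_um,
        frame_interval_s=stack.frame_interval_s,
    )


def _parse_description(description: str | None) -> dict:
    if not description:
        return {}
    try:
        meta = json.loads(description)
    except (json.JSONDecodeError, TypeError):
        return {}
    if not isinstance(meta, dict):
        return {}
    return {k: meta[k] for k in _DESCRIPTION_KEYS if k in meta}


def _resolve_calibration(name: str, override: float | None, meta: dict) -> float:
    embedded = meta.get(name)
    if override is not None:
        if embedded is not None and not np.isclose(embedded, override):
            logger.warning(
                "TIFF metadata %s=%s overridden by user value %s", name, embedded, override
            )
        value = override
    elif embedded is not None:
        value = float(embedded)
    else:
        raise ValueError(f"{name} not found in TIFF metadata and not provided")
    if not value > 0:
        raise ValueError(f"{name} must be positive, got {value}")
    return float(value)


def _check_isotropic(page) -> None:
    """Reject anisotropic pixel calibration; downstream geometry assumes
    a single isotropic um/pixel scale."""
    tags = page.tags
    xres = tags.get("XResolution")
    yres = tags.get("YResolution")
    if xres is None or yres is None:
        return
    xv, yv = xres.value, yres.value
    xr = xv[0] / xv[1] if isinstance(xv, tuple) else float(xv)
    yr = yv[0] / yv[1] if isinstance(yv, tuple) else float(yv)
    if xr > 0 and yr > 0 and not np.isclose(xr, yr, rtol=1e-6):
        raise ValueError(
            f"anisotropic pixel calibration (XResolution={xr}, YResolution={yr}) is not supported"
        )
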