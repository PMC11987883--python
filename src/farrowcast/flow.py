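"""Optical-flow activity quantification.

A dense optical-flow field assigns every pixel of a frame pair a 2-D
displacement ``(u, v)`` in pixels/frame.  Sow activity is quantified as the
mean per-pixel displacement magnitude of each field (``A``), summed over the
frames of a 5-minute video segment (``A'``) and min-max rescaled to the
0-100 band (``A''``) before entering any model.

The deep flow estimator itself (RAFT or similar) is an external, pluggable
backend; this module ships only an exhaustive block-matching reference
estimator used for testing, plus the Middlebury ``.flo`` container format
and the two standard flow-accuracy scores (end-point error and Fl-all).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "FlowField",
    "ActivitySeries",
    "mean_displacement",
    "segment_activity",
    "normalize_series",
    "smooth_series",
    "epe",
    "fl_all",
    "estimate_flow",
    "register_backend",
    "read_flo",
    "write_flo",
    "FRAMES_PER_SEGMENT",
]

#: frames entering one 5-minute activity segment at the 2 fps retained rate
FRAMES_PER_SEGMENT = 600

_FLO_MAGIC = 202021.25  # float32 reinterpretation of the ASCII tag "PIEH"


@dataclass
class FlowField:
    """Per-pixel 2-D displacement grid for one frame pair.

    ``u`` is the horizontal and ``v`` the vertical displacement component,
    both in pixels/frame, both of shape ``(height, width)``.
    """

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.u.ndim != 2 or self.u.shape != self.v.shape:
            raise ValueError(
                f"u and v must be 2-D arrays of equal shape, got {self.u.shape} and {self.v.shape}"
            )
        if self.u.size == 0:
            raise ValueError("flow field must contain at least one pixel")
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise ValueError("flow field contains non-finite values")

    @property
    def height(self) -> int:
        return self.u.shape[0]

    @property
    def width(self) -> int:
        return self.u.shape[1]

    def magnitude(self) -> np.ndarray:
        """Per-pixel displacement magnitude sqrt(u**2 + v**2)."""
        return np.hypot(self.u, self.v)


@dataclass
class ActivitySeries:
    """Per-subject activity values at 5-minute resolution, anchored to onset.

    ``minutes_to_onset[i]`` is the remaining time (minutes) at point ``i``;
    it decreases by 5 along the series and reaches 0 at farrowing onset
    (the final point, under the segment-end timestamp convention).
    """

    sow_id: str
    values: np.ndarray
    minutes_to_onset: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.minutes_to_onset = np.asarray(self.minutes_to_onset, dtype=np.int64)
        if self.values.ndim != 1 or self.values.shape != self.minutes_to_onset.shape:
            raise ValueError("values and minutes_to_onset must be 1-D and equally long")
        if len(self.values) == 0:
            raise ValueError("activity series is empty")
        if not np.isfinite(self.values).all():
            raise ValueError("activity series contains non-finite values")
        d = np.diff(self.minutes_to_onset)
        if len(d) and not (d == -5).all():
            raise ValueError("minutes_to_onset must decrease by exactly 5 per point")
        if self.normalized and ((self.values < 0).any() or (self.values > 100).any()):
            raise ValueError("normalized series must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.values)


def mean_displacement(fld: FlowField) -> float:
    """Mean per-pixel displacement magnitude A of one flow field.

    A = (1/N) * sum_i sqrt(u_i**2 + v_i**2) over all N pixels, in
    pixels/frame.  This is the frame-level activity metric.
    """
    return float(fld.magnitude().mean())


def segment_activity(frame_activities: Sequence[float]) -> float:
    """Total segment activity A' = sum of frame-wise activity values.

    For the canonical 5-minute segment sampled at 2 fps this sums
    ``FRAMES_PER_SEGMENT`` (600) values, but any positive count is accepted:
    the extractor may produce 599 pairs from 600 retained frames.
    """
    a = np.asarray(frame_activities, dtype=np.float64)
    if a.size == 0:
        raise ValueError("segment has no frame activities")
    if (a < 0).any():
        raise ValueError("frame activities are magnitudes and cannot be negative")
    return float(a.sum())


def normalize_series(
    raw: Sequence[float],
    ref_min: float,
    ref_max: float,
    *,
    clip: bool = True,
) -> np.ndarray:
    """Min-max rescale raw activity onto [0, 100].

    ``x -> (x - ref_min) / (ref_max - ref_min) * 100``.  The reference range
    is supplied by the caller so that it can be scoped per sow, cohort-wide,
    or frozen from training data; values outside the reference range are
    clipped to [0, 100] unless ``clip=False``.

    A degenerate range (``ref_max == ref_min``) raises unless the data are
    themselves constant and equal to the reference, in which case the series
    maps to all zeros.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if not (np.isfinite(ref_min) and np.isfinite(ref_max)):
        raise ValueError("reference min/max must be finite")
    if ref_max < ref_min:
        raise ValueError(f"ref_max ({ref_max}) must be >= ref_min ({ref_min})")
    if ref_max == ref_min:
        if np.all(raw == ref_min):
            return np.zeros_like(raw)
        raise ValueError("degenerate reference range (ref_max == ref_min) for non-constant data")
    out = (raw - ref_min) / (ref_max - ref_min) * 100.0
    if clip:
        out = np.clip(out, 0.0, 100.0)
    return out


def smooth_series(values: Sequence[float], window: int = 5) -> np.ndarray:
    """Centered moving average with edge shrinkage.

    Near the boundaries the window is truncated to the available points, so
    no padding value is invented; ``window=1`` is the identity.  The window
    must be odd so the average stays centered.
    """
    x = np.asarray(values, dtype=np.float64)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd positive integer, got {window}")
    if window > len(x):
        raise ValueError(f"window ({window}) exceeds series length ({len(x)})")
    if window == 1:
        return x.copy()
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def _check_same_shape(pred: FlowField, truth: FlowField) -> None:
    if pred.u.shape != truth.u.shape:
        raise ValueError(f"flow shapes differ: {pred.u.shape} vs {truth.u.shape}")


def epe(pred: FlowField, truth: FlowField) -> float:
    """Mean end-point error between two flow fields, in pixels.

    The average Euclidean distance between the predicted and ground-truth
    displacement vector at each pixel.
    """
    _check_same_shape(pred, truth)
    return float(np.hypot(pred.u - truth.u, pred.v - truth.v).mean())


def fl_all(pred: FlowField, truth: FlowField, delta: float = 3.0) -> float:
    """Percentage of pixels whose end-point error exceeds ``delta`` pixels."""
    _check_same_shape(pred, truth)
    if delta <= 0:
        raise ValueError("delta must be positive")
    err = np.hypot(pred.u - truth.u, pred.v - truth.v)
    return float(100.0 * np.count_nonzero(err > delta) / err.size)


# --- pluggable flow-estimation backends -----------------------------------

_BACKENDS: dict[str, Callable[..., FlowField]] = {}


def register_backend(name: str, fn: Callable[..., FlowField]) -> None:
    """Register a flow estimator ``fn(frame_a, frame_b, **kw) -> FlowField``."""
    _BACKENDS[name] = fn


def estimate_flow(frame_a: np.ndarray, frame_b: np.ndarray, backend: str = "block_matching", **kwargs) -> FlowField:
    """Estimate dense flow between two same-shape grayscale frames.

    Deep estimators (e.g. RAFT) plug in through :func:`register_backend`;
    the built-in ``block_matching`` backend is an exhaustive SSD search
    intended for testing on small synthetic frames, not production video.
    """
    frame_a = np.asarray(frame_a, dtype=np.float64)
    frame_b = np.asarray(frame_b, dtype=np.float64)
    if frame_a.shape != frame_b.shape or frame_a.ndim != 2:
        raise ValueError("frames must be 2-D arrays of identical shape")
    if backend not in _BACKENDS:
        raise KeyError(
            f"unknown flow backend {backend!r}; registered backends: {sorted(_BACKENDS)}"
        )
    return _BACKENDS[backend](frame_a, frame_b, **kwargs)


def _block_matching(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    block: int = 8,
    search_radius: int = 4,
) -> FlowField:
    """Exhaustive block-matching flow: per block, the integer displacement
    minimizing the sum of squared differences within the search radius."""
    h, w = frame_a.shape
    u = np.zeros((h, w))
    v = np.zeros((h, w))
    for by in range(0, h - block + 1, block):
        for bx in range(0, w - block + 1, block):
            patch = frame_a[by : by + block, bx : bx + block]
            best, best_dx, best_dy = np.inf, 0, 0
            for dy in range(-search_radius, search_radius + 1):
                for dx in range(-search_radius, search_radius + 1):
                    y0, x0 = by + dy, bx + dx
                    if y0 < 0 or x0 < 0 or y0 + block > h or x0 + block > w:
                        continue
                    cand = frame_b[y0 : y0 + block, x0 : x0 + block]
                    ssd = float(((patch - cand) ** 2).sum())
                    if ssd < best:
                        best, best_dx, best_dy = ssd, dx, dy
            u[by : by + block, bx : bx + block] = best_dx
            v[by : by + block, bx : bx + block] = best_dy
    return FlowField(u=u, v=v)


register_backend("block_matching", _block_matching)


# --- Middlebury .flo container ---------------------------------------------


def write_flo(path: str | Path, fld: FlowField) -> None:
    """Write a flow field in Middlebury ``.flo`` format.

    Layout: float32 magic 202021.25 ("PIEH"), int32 width, int32 height,
    then row-major interleaved float32 (u, v) pairs; little-endian.
    """
    path = Path(path)
    data = np.empty((fld.height, fld.width, 2), dtype="<f4")
    data[..., 0] = fld.u
    data[..., 1] = fld.v
    with open(path, "wb") as fh:
        np.array([_FLO_MAGIC], dtype="<f4").tofile(fh)
        np.array([fld.width, fld.height], dtype="<i4").tofile(fh)
        data.tofile(fh)


def read_flo(path: str | Path) -> FlowField:
    """Read a Middlebury ``.flo`` flow field written by :func:`write_flo`."""
    with open(path, "rb") as fh:
        magic = np.fromfile(fh, dtype="<f4", count=1)
        if magic.size != 1 or magic[0] != np.float32(_FLO_MAGIC):
            raise ValueError(f"{path}: not a .flo file (bad magic)")
        w, h = np.fromfile(fh, dtype="<i4", count=2)
        data = np.fromfile(fh, dtype="<f4", count=int(w) * int(h) * 2)
    if data.size != int(w) * int(h) * 2:
        raise ValueError(f"{path}: truncated .flo payload")
    data = data.reshape(int(h), int(w), 2)
    return FlowField(u=data[..., 0].astype(np.float64), v=data[..., 1].astype(np.float64))
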