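"""Preprocessing conventions and sliding-window remaining-time datasets.

Video frames are cropped to a fixed region of interest and temporally
down-sampled to 2 fps by retaining fixed frame positions within each second.
The resulting per-sow activity series are cut into fixed-length sliding
windows; each window's regression label is the remaining time (minutes) to
farrowing onset at the window's final point.  Splits are always at the
subject level — windows from one sow never cross the train/validation/test
boundary — with the 16 non-test sows further partitioned into equal
cross-validation folds.

Coordinate convention: pixel boxes are half-open, 0-based ``[x1, x2) x
[y1, y2)``, so a box from (167, 146) to (2499, 1232) is exactly 2332 pixels
wide and 1086 pixels high.  Timestamp convention: each 5-minute activity
point is stamped by its segment's end, so the final point of a pre-onset
series carries label 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .flow import ActivitySeries

__all__ = [
    "RoiSpec",
    "WindowedSample",
    "SplitPlan",
    "crop_roi",
    "select_frames",
    "make_windows",
    "make_split",
    "write_windows_csv",
    "read_windows_csv",
]


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular region of interest in half-open pixel coordinates."""

    top_left: tuple[int, int]
    bottom_right: tuple[int, int]

    def __post_init__(self) -> None:
        (x1, y1), (x2, y2) = self.top_left, self.bottom_right
        if x2 <= x1 or y2 <= y1:
            raise ValueError(
                f"bottom_right {self.bottom_right} must strictly exceed top_left {self.top_left} in both axes"
            )

    @property
    def width(self) -> int:
        return self.bottom_right[0] - self.top_left[0]

    @property
    def height(self) -> int:
        return self.bottom_right[1] - self.top_left[1]


@dataclass
class WindowedSample:
    """One sliding-window sample with its remaining-time label (minutes)."""

    sow_id: str
    window: np.ndarray
    label: int

    def __post_init__(self) -> None:
        self.window = np.asarray(self.window, dtype=np.float64)
        if self.window.ndim != 1:
            raise ValueError("window must be 1-D")
        if self.label < 0 or self.label % 5:
            raise ValueError(f"label must be a non-negative multiple of 5, got {self.label}")


@dataclass
class SplitPlan:
    """Subject-level split with cross-validation folds over train+val sows."""

    train_sows: list[str]
    val_sows: list[str]
    test_sows: list[str]
    cv_folds: dict[str, int]

    def __post_init__(self) -> None:
        sets = [set(self.train_sows), set(self.val_sows), set(self.test_sows)]
        total = sum(len(s) for s in sets)
        if len(set.union(*sets)) != total:
            raise ValueError("train/val/test sow sets must be pairwise disjoint")
        dev = set(self.train_sows) | set(self.val_sows)
        if set(self.cv_folds) != dev:
            raise ValueError("cv_folds must cover exactly the train+val sows")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "train_sows": self.train_sows,
            "val_sows": self.val_sows,
            "test_sows": self.test_sows,
            "cv_folds": self.cv_folds,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return cls(d["train_sows"], d["val_sows"], d["test_sows"], d["cv_folds"])


def crop_roi(frame: np.ndarray, roi: RoiSpec) -> np.ndarray:
    """Crop a frame array (indexed [y, x, ...]) to the region of interest."""
    frame = np.asarray(frame)
    if frame.ndim < 2:
        raise ValueError("frame must be at least 2-D (height x width)")
    h, w = frame.shape[:2]
    (x1, y1), (x2, y2) = roi.top_left, roi.bottom_right
    if x1 < 0 or y1 < 0 or x2 > w or y2 > h:
        raise ValueError(f"ROI {roi} exceeds frame bounds {(w, h)}")
    return frame[y1:y2, x1:x2]


def select_frames(fps_in: int, indices_per_second: Iterable[int], n_seconds: int) -> np.ndarray:
    """Absolute indices of retained frames under per-second selection.

    ``indices_per_second`` are 1-based positions within each second (for
    25 fps input, retaining the 1st and 13th frames yields a 2 fps stream);
    the output indices are 0-based into the full frame sequence.
    """
    idx = sorted(set(int(i) for i in indices_per_second))
    if not idx:
        raise ValueError("indices_per_second must be non-empty")
    if idx[0] < 1 or idx[-1] > fps_in:
        raise ValueError(f"per-second indices {idx} must lie within [1, fps_in={fps_in}]")
    if n_seconds < 0:
        raise ValueError("n_seconds must be non-negative")
    base = np.asarray(idx, dtype=np.int64) - 1
    return (np.arange(n_seconds, dtype=np.int64)[:, None] * fps_in + base[None, :]).ravel()


def make_windows(series: ActivitySeries, w: int = 72, step: int = 1) -> list[WindowedSample]:
    """Cut one activity series into sliding windows with remaining-time labels.

    Windows of length ``w`` advance by ``step`` points; the label of a window
    is the minutes-to-onset of its final point, so the count is
    ``floor((len - w) / step) + 1`` and consecutive labels differ by
    ``5 * step``.  The last window of a full pre-onset series has label 0.
    """
    n = len(series)
    if w < 1 or w > n:
        raise ValueError(f"window length {w} must be in [1, {n}]")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    out = []
    for start in range(0, n - w + 1, step):
        end = start + w
        out.append(WindowedSample(
            sow_id=series.sow_id,
            window=series.values[start:end].copy(),
            label=int(series.minutes_to_onset[end - 1]),
        ))
    return out


def make_split(
    sow_ids: Sequence[str],
    n_train: int = 12,
    n_val: int = 4,
    n_test: int = 4,
    n_folds: int = 4,
    seed: int = 0,
) -> SplitPlan:
    """Random subject-level split with equal CV folds over train+val.

    The counts must sum to the cohort size and ``n_folds`` must divide the
    number of non-test sows evenly.
    """
    sow_ids = list(sow_ids)
    if len(set(sow_ids)) != len(sow_ids):
        raise ValueError("sow_ids contains duplicates")
    if n_train + n_val + n_test != len(sow_ids):
        raise ValueError(
            f"split sizes {n_train}+{n_val}+{n_test} != cohort size {len(sow_ids)}"
        )
    n_dev = n_train + n_val
    if n_folds < 1 or n_dev % n_folds:
        raise ValueError(f"{n_folds} folds cannot evenly partition {n_dev} train+val sows")
    rng = np.random.default_rng(seed)
    order = [sow_ids[i] for i in rng.permutation(len(sow_ids))]
    train, val, test = order[:n_train], order[n_train:n_dev], order[n_dev:]
    dev = train + val
    folds = {sow: i % n_folds for i, sow in enumerate(dev)}
    return SplitPlan(train_sows=sorted(train), val_sows=sorted(val),
                     test_sows=sorted(test), cv_folds=folds)


def write_windows_csv(path: str | Path, samples: Sequence[WindowedSample]) -> None:
    """Persist windowed samples: sow_id, label, then the w activity columns."""
    if not samples:
        raise ValueError("no samples to write")
    w = len(samples[0].window)
    cols = ["sow_id", "label"] + [f"a{i:03d}" for i in range(w)]
    rows = [[s.sow_id, s.label] + [float(x) for x in s.window] for s in samples]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_windows_csv(path: str | Path) -> list[WindowedSample]:
    """Load windowed samples written by :func:`write_windows_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    acols = [c for c in df.columns if c.startswith("a")]
    return [
        WindowedSample(sow_id=str(r["sow_id"]), window=r[acols].to_numpy(dtype=float),
                       label=int(r["label"]))
        for _, r in df.iterrows()
    ]
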