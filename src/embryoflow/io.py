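"""Image-sequence input and motion-parameter CSV persistence.

Frames are handled as a uniform stream of 2-D grayscale arrays scaled to
[0, 1], regardless of whether the source is a multi-page TIFF, a directory
of numbered still images, or a video container.  The per-transition motion
parameters (rotation angles and centre-of-mass displacement) round-trip
through a small, fixed-dialect CSV so that tracking and downstream
statistics can run as separate steps.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrameSequence",
    "MotionRecord",
    "SequenceError",
    "MotionCsvError",
    "read_sequence",
    "write_motion_csv",
    "read_motion_csv",
]

#: Required leading columns of the motion CSV, in order.
MOTION_CSV_COLUMNS = ("frame", "pos_angle", "neg_angle", "com_rho", "com_theta")

_IMAGE_EXTENSIONS = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}
_VIDEO_EXTENSIONS = {".avi", ".mp4", ".mov", ".mkv"}


class SequenceError(ValueError):
    """Raised for unreadable, inconsistent or too-short image sequences."""


class MotionCsvError(ValueError):
    """Raised for malformed motion CSV files; carries the offending row."""


@dataclass
class FrameSequence:
    """An ordered grayscale image sequence with a known sampling rate.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Intensities in [0, 1], float64.
    fps : float
        Acquisition rate in frames per second; supplied by the caller,
        never trusted from container metadata.
    source_id : str
        Free-text identifier carried through to downstream outputs.
    """

    frames: np.ndarray
    fps: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise SequenceError(
                f"frames must be a (n, h, w) stack, got shape {self.frames.shape}"
            )
        if len(self.frames) < 2:
            raise SequenceError(
                f"a sequence needs at least 2 frames, got {len(self.frames)}"
            )
        if not self.fps > 0:
            raise SequenceError(f"fps must be positive, got {self.fps}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        """Total span of the sequence in seconds (n_frames / fps)."""
        return len(self.frames) / self.fps

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class MotionRecord:
    """Per-transition motion parameters for one individual.

    Four series of equal length N (one sample per frame-to-frame
    transition): mean clockwise rotation ``pos_angle`` and mean
    anti-clockwise rotation magnitude ``neg_angle`` (radians, both >= 0),
    and the centre-of-mass displacement in polar form, magnitude
    ``com_rho`` (pixels, >= 0) and direction ``com_theta`` (radians in
    (-pi, pi]).  Untrackable transitions are stored as zeros, never gaps.
    """

    pos_angle: np.ndarray
    neg_angle: np.ndarray
    com_rho: np.ndarray
    com_theta: np.ndarray
    fps: float
    source_id: str = ""
    com_dx: np.ndarray | None = field(default=None, repr=False)
    com_dy: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for name in ("pos_angle", "neg_angle", "com_rho", "com_theta"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        n = len(self.pos_angle)
        for name in ("neg_angle", "com_rho", "com_theta"):
            if len(getattr(self, name)) != n:
                raise ValueError("all four motion series must have equal length")
        if n < 2:
            raise SequenceError(f"a motion record needs >= 2 samples, got {n}")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        for name in ("pos_angle", "neg_angle", "com_rho", "com_theta"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")
        for name in ("pos_angle", "neg_angle", "com_rho"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")
        if self.com_dx is not None:
            self.com_dx = np.asarray(self.com_dx, dtype=np.float64)
        if self.com_dy is not None:
            self.com_dy = np.asarray(self.com_dy, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.pos_angle)

    @property
    def series(self) -> dict[str, np.ndarray]:
        """The four parameter series keyed by their canonical names."""
        return {
            "pos_angle": self.pos_angle,
            "neg_angle": self.neg_angle,
            "com_rho": self.com_rho,
            "com_theta": self.com_theta,
        }


def _scale_to_unit(img: np.ndarray) -> np.ndarray:
    """Scale integer images by their dtype range; pass floats through clipped."""
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        return img.astype(np.float64) / float(info.max)
    return np.clip(img.astype(np.float64), 0.0, 1.0)


def _to_grayscale(img: np.ndarray) -> np.ndarray:
    # Unweighted channel mean: the acquisition cameras are monochrome, any
    # fixed convention for the odd color input suffices.
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    elif img.ndim != 2:
        raise SequenceError(f"cannot interpret image of shape {img.shape}")
    return img


def _load_frame_file(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    try:
        raw = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with frame name
        raise SequenceError(f"cannot read frame {path}: {exc}") from exc
    return _to_grayscale(_scale_to_unit(np.asarray(raw)))


def _read_tiff_stack(path: Path) -> list[np.ndarray]:
    import tifffile

    try:
        stack = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise SequenceError(f"cannot read TIFF {path}: {exc}") from exc
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    scaled = _scale_to_unit(stack)
    if scaled.ndim == 4:  # pages with color channels
        scaled = scaled[..., :3].mean(axis=-1)
    return list(scaled)


def _read_video(path: Path) -> list[np.ndarray]:
    import imageio.v3 as iio

    try:
        reader = iio.imiter(path)
        return [_to_grayscale(_scale_to_unit(np.asarray(f))) for f in reader]
    except Exception as exc:  # noqa: BLE001
        raise SequenceError(f"cannot read video {path}: {exc}") from exc


def read_sequence(path: str | os.PathLike, fps: float, source_id: str | None = None) -> FrameSequence:
    """Read an image sequence into a :class:`FrameSequence`.

    ``path`` may be a multi-page TIFF, a video file, or a directory of
    lexicographically ordered image files.  ``fps`` must be supplied by the
    caller; frame-rate metadata embedded in containers is not trusted.

    Raises
    ------
    SequenceError
        If frames have mixed dimensions, fewer than 2 frames are found, or
        a file cannot be read (the message names the offending frame).
    """
    path = Path(path)
    if source_id is None:
        source_id = path.stem if path.is_file() else path.name

    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.is_file() and p.suffix.lower() in _IMAGE_EXTENSIONS
        )
        if len(files) < 2:
            raise SequenceError(
                f"directory {path} holds {len(files)} readable frames; need >= 2"
            )
        frames = [_load_frame_file(p) for p in files]
    elif path.suffix.lower() in {".tif", ".tiff"}:
        frames = _read_tiff_stack(path)
    elif path.suffix.lower() in _VIDEO_EXTENSIONS:
        frames = _read_video(path)
    elif path.is_file():
        raise SequenceError(f"unsupported sequence format: {path}")
    else:
        raise SequenceError(f"no such file or directory: {path}")

    if len(frames) < 2:
        raise SequenceError(f"{path}: found {len(frames)} frames; need >= 2")
    shape0 = frames[0].shape
    for i, f in enumerate(frames):
        if f.shape != shape0:
            raise SequenceError(
                f"{path}: frame {i} has shape {f.shape}, expected {shape0}"
            )
    return FrameSequence(frames=np.stack(frames), fps=fps, source_id=source_id)


def write_motion_csv(record: MotionRecord, path: str | os.PathLike) -> None:
    """Write a motion record to CSV (comma-separated, '.' decimal, header row).

    Columns: frame index plus the four parameter series; when the record
    carries cartesian centre-of-mass steps they are appended as
    ``com_dx``/``com_dy`` for inspection.  Values are serialized with 17
    significant digits so the read/write round trip is exact.
    """
    cols: dict[str, np.ndarray] = {"frame": np.arange(len(record))}
    cols.update(record.series)
    if record.com_dx is not None and record.com_dy is not None:
        cols["com_dx"] = record.com_dx
        cols["com_dy"] = record.com_dy
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def read_motion_csv(path: str | os.PathLike, fps: float, source_id: str | None = None) -> MotionRecord:
    """Read a motion CSV written by :func:`write_motion_csv`.

    Raises
    ------
    MotionCsvError
        On a malformed header or a non-numeric cell (message gives the row).
    SequenceError
        If the file has fewer than 2 data rows.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise MotionCsvError(f"{path}: empty file") from exc
    got = tuple(df.columns[: len(MOTION_CSV_COLUMNS)])
    if got != MOTION_CSV_COLUMNS:
        raise MotionCsvError(
            f"{path}: malformed header {list(df.columns)}; "
            f"expected leading columns {list(MOTION_CSV_COLUMNS)}"
        )
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based incl. header
            raise MotionCsvError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at row {row}"
            )
        df[col] = numeric
    if len(df) < 2:
        raise SequenceError(f"{path}: {len(df)} data rows; need >= 2")
    return MotionRecord(
        pos_angle=df["pos_angle"].to_numpy(),
        neg_angle=df["neg_angle"].to_numpy(),
        com_rho=df["com_rho"].to_numpy(),
        com_theta=df["com_theta"].to_numpy(),
        fps=fps,
        source_id=source_id if source_id is not None else path.stem,
        com_dx=df["com_dx"].to_numpy() if "com_dx" in df else None,
        com_dy=df["com_dy"].to_numpy() if "com_dy" in df else None,
    )
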