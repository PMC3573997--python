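"""Ground-truth generators for pipeline validation.

Two kinds of fixtures are produced, both fully deterministic given a seed:

* motion-parameter time series with controlled oscillation periods,
  Poisson-timed rectangular spike bursts (emulating tail flicks) and
  Gaussian noise — these exercise the spectral and statistics stages;
* rendered image sequences of a textured disc ("embryo") spinning and
  drifting inside a static circular capsule ring — these exercise the
  corner tracker, and come with the true per-transition motion record so
  tracking error can be measured directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import FrameSequence, MotionRecord

__all__ = [
    "MotionSpec",
    "VideoSpec",
    "synth_motion_record",
    "synth_embryo_video",
    "synth_cohort",
]

SERIES_KEYS = ("pos", "neg", "rho", "theta")


@dataclass(frozen=True)
class MotionSpec:
    """Recipe for one synthetic motion record.

    ``oscillations`` assigns sinusoids (series key, period_s, amplitude)
    to any of the four series; ``spike_rate_per_min`` adds rectangular
    bursts of ``spike_amplitude`` lasting ``spike_width_frames`` to the
    ``spike_target`` series at Poisson-distributed times.  The default
    duration matches the 10-minute acquisition design the package targets.
    """

    duration_s: float = 600.0
    fps: float = 7.5
    oscillations: tuple[tuple[str, float, float], ...] = ()
    spike_rate_per_min: float = 0.0
    spike_amplitude: float = 0.0
    spike_width_frames: int = 3
    spike_target: str = "pos"
    noise_sd: dict[str, float] | float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration_s and fps must be positive")
        for target, period, amp in self.oscillations:
            if target not in SERIES_KEYS:
                raise ValueError(f"unknown series {target!r}; use one of {SERIES_KEYS}")
            if not 0 < period < self.duration_s:
                raise ValueError(
                    f"oscillation period {period} s must lie in (0, duration)")
            if amp < 0:
                raise ValueError("oscillation amplitude must be >= 0")
        if self.spike_rate_per_min < 0 or self.spike_amplitude < 0:
            raise ValueError("spike rate and amplitude must be >= 0")
        if self.spike_target not in SERIES_KEYS:
            raise ValueError(f"unknown spike target {self.spike_target!r}")
        for sd in self._noise_map().values():
            if sd < 0:
                raise ValueError("noise_sd must be >= 0")

    def _noise_map(self) -> dict[str, float]:
        if isinstance(self.noise_sd, dict):
            return {k: float(self.noise_sd.get(k, 0.0)) for k in SERIES_KEYS}
        return {k: float(self.noise_sd) for k in SERIES_KEYS}


@dataclass(frozen=True)
class VideoSpec:
    """Recipe for one synthetic embryo video.

    A disc of radius ``disc_radius_px`` carrying ``n_texture_blobs``
    Gaussian intensity blobs rotates by ``spin_profile`` (rad/frame,
    positive = clockwise on screen; a scalar is broadcast over all
    transitions) and its centre follows ``drift_path`` (``(n_frames, 2)``
    pixel coordinates; None = stationary at the frame centre), inside a
    static capsule ring.  Per-frame Gaussian sensor noise of sd
    ``background_noise_sd`` is added and intensities clamped to [0, 1].
    """

    n_frames: int = 100
    frame_size: tuple[int, int] = (192, 192)  # (height, width)
    disc_radius_px: float = 60.0
    n_texture_blobs: int = 500
    blob_sigma_px: float = 1.0
    spin_profile: float | np.ndarray = 0.0
    drift_path: np.ndarray | None = None
    capsule_radius_px: float = 88.0
    background_noise_sd: float = 0.005
    fps: float = 7.5
    seed: int = 0

    def validate(self) -> None:
        h, w = self.frame_size
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if not (0 < self.disc_radius_px < self.capsule_radius_px):
            raise ValueError("disc must fit strictly inside the capsule")
        if 2 * self.capsule_radius_px >= min(h, w):
            raise ValueError("capsule must fit inside the frame")
        if self.drift_path is not None:
            path = np.asarray(self.drift_path, dtype=np.float64)
            if path.shape != (self.n_frames, 2):
                raise ValueError("drift_path must have shape (n_frames, 2)")
            margin = self.capsule_radius_px - self.disc_radius_px
            center = np.array([w / 2.0, h / 2.0])
            if np.any(np.hypot(*(path - center).T) > margin):
                raise ValueError("drift_path carries the disc outside the capsule")

    def spin_per_transition(self) -> np.ndarray:
        spin = np.asarray(self.spin_profile, dtype=np.float64)
        if spin.ndim == 0:
            return np.full(self.n_frames - 1, float(spin))
        if len(spin) != self.n_frames - 1:
            raise ValueError("spin_profile must have one entry per transition")
        return spin


def _wrap(a: np.ndarray) -> np.ndarray:
    return -((-a + np.pi) % (2 * np.pi) - np.pi)


def synth_motion_record(spec: MotionSpec) -> tuple[MotionRecord, MotionSpec]:
    """Generate a motion record from a :class:`MotionSpec`.

    Each series is the sum of its assigned sinusoids, plus spikes on the
    spike-target series, plus Gaussian noise; the non-negative series
    (pos, neg, rho) are rectified at 0 and theta is wrapped into
    (-pi, pi].  Returns the record and an echo of the spec (the ground
    truth).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fps))
    t = np.arange(n) / spec.fps
    series = {k: np.zeros(n) for k in SERIES_KEYS}

    for target, period, amp in spec.oscillations:
        phase = rng.uniform(0, 2 * np.pi)
        series[target] += amp * np.sin(2 * np.pi * t / period + phase)

    if spec.spike_rate_per_min > 0 and spec.spike_amplitude > 0:
        expected = spec.spike_rate_per_min * spec.duration_s / 60.0
        n_spikes = rng.poisson(expected)
        starts = rng.integers(0, max(n - spec.spike_width_frames, 1), size=n_spikes)
        for s in starts:
            series[spec.spike_target][s : s + spec.spike_width_frames] += spec.spike_amplitude

    for k, sd in spec._noise_map().items():
        if sd > 0:
            series[k] += rng.normal(0.0, sd, size=n)

    for k in ("pos", "neg", "rho"):
        series[k] = np.maximum(series[k], 0.0)
    series["theta"] = _wrap(series["theta"])

    record = MotionRecord(
        pos_angle=series["pos"], neg_angle=series["neg"],
        com_rho=series["rho"], com_theta=series["theta"],
        fps=spec.fps, source_id=f"synth-{spec.seed}",
    )
    return record, spec


def _render_texture(spec: VideoSpec, rng: np.random.Generator) -> np.ndarray:
    """Static disc-local texture: Gaussian blobs on a soft-edged disc."""
    r = spec.disc_radius_px
    size = int(math.ceil(2 * r)) + 9
    size += size % 2  # odd so the centre is a pixel
    c = size // 2
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dx, dy = xx - c, yy - c
    rad = np.hypot(dx, dy)

    tex = np.full((size, size), 0.45)
    n_blobs = spec.n_texture_blobs
    # blobs kept away from the rim so corner features sit on body texture,
    # not on the (rotationally near-symmetric) disc boundary
    blob_r = r * np.sqrt(rng.uniform(0, 1, size=n_blobs)) * 0.85
    blob_th = rng.uniform(0, 2 * np.pi, size=n_blobs)
    amp = rng.uniform(-0.45, 0.45, size=n_blobs)
    sig = spec.blob_sigma_px * rng.uniform(0.7, 1.5, size=n_blobs)
    bx = blob_r * np.cos(blob_th)
    by = blob_r * np.sin(blob_th)
    for k in range(n_blobs):
        tex += amp[k] * np.exp(-((dx - bx[k]) ** 2 + (dy - by[k]) ** 2) / (2 * sig[k] ** 2))
    # wide soft rim so the boundary itself is not a dominant gradient
    edge = np.clip((r - rad) / 6.0, 0.0, 1.0)
    tex = np.clip(tex, 0.05, 0.95) * edge
    return tex


def synth_embryo_video(spec: VideoSpec) -> tuple[FrameSequence, MotionRecord]:
    """Render a textured spinning/drifting disc inside a capsule ring.

    The disc texture is generated once and resampled per frame with
    bilinear interpolation under the cumulative rotation and drift, so the
    true per-transition motion is known exactly.  Returns the frame
    sequence and the ground-truth motion record (spin split into
    pos/neg by sign; drift step in polar form).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_size
    tex = _render_texture(spec, rng)
    tc = tex.shape[0] // 2

    center_default = np.array([w / 2.0, h / 2.0])
    if spec.drift_path is None:
        path = np.tile(center_default, (spec.n_frames, 1))
    else:
        path = np.asarray(spec.drift_path, dtype=np.float64)

    spin = spec.spin_per_transition()
    cum_angle = np.concatenate([[0.0], np.cumsum(spin)])

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = center_default[1], center_default[0]
    cap_rad = np.hypot(xx - cx, yy - cy)
    ring = 0.35 * np.exp(-((cap_rad - spec.capsule_radius_px) ** 2) / (2 * 1.5**2))
    base = 0.1 + ring

    frames = np.empty((spec.n_frames, h, w))
    for i in range(spec.n_frames):
        ox, oy = path[i]
        phi = cum_angle[i]
        # inverse warp: rotate screen offsets back into texture coordinates.
        # positive phi = clockwise on screen (y down).
        dx = xx - ox
        dy = yy - oy
        u = np.cos(phi) * dx + np.sin(phi) * dy
        v = -np.sin(phi) * dx + np.cos(phi) * dy
        disc = ndimage.map_coordinates(
            tex, [v + tc, u + tc], order=1, mode="constant", cval=0.0
        )
        frame = base + disc
        if spec.background_noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.background_noise_sd, size=frame.shape)
        frames[i] = np.clip(frame, 0.0, 1.0)

    steps = np.diff(path, axis=0)
    rho = np.hypot(steps[:, 0], steps[:, 1])
    theta = np.where(rho > 0, np.arctan2(steps[:, 1], steps[:, 0]), 0.0)
    truth = MotionRecord(
        pos_angle=np.maximum(spin, 0.0),
        neg_angle=np.maximum(-spin, 0.0),
        com_rho=rho,
        com_theta=_wrap(theta),
        fps=spec.fps,
        source_id=f"synthvid-{spec.seed}",
    )
    seq = FrameSequence(frames=frames, fps=spec.fps, source_id=f"synthvid-{spec.seed}")
    return seq, truth


def synth_cohort(group_specs: list[tuple[str, MotionSpec, int]],
                 seed: int = 0) -> list[tuple[str, str, MotionRecord]]:
    """Generate labelled motion records for a multi-group study design.

    Each group is given by (label, spec template, n individuals); every
    individual gets its own seed derived deterministically from the master
    seed, so the whole cohort is reproducible.  Returns a list of
    (group label, individual id, record) mirroring the n-per-treatment
    design used for group comparison.
    """
    root = np.random.SeedSequence(seed)
    out: list[tuple[str, str, MotionRecord]] = []
    children = root.spawn(len(group_specs))
    for (label, template, n), child in zip(group_specs, children):
        if n < 1:
            raise ValueError(f"group {label!r} needs at least 1 individual")
        for j, sub in enumerate(child.spawn(n)):
            indiv_seed = int(sub.generate_state(1)[0] % (2**31 - 1))
            spec = replace(template, seed=indiv_seed)
            record, _ = synth_motion_record(spec)
            indiv_id = f"{label}-{j + 1:02d}"
            record.source_id = indiv_id
            out.append((label, indiv_id, record))
    return out
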