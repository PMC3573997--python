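"""Sparse optic flow: corner tracking and motion-parameter extraction.

The tracker follows the classic sparse pipeline: Shi-Tomasi corner
detection, pyramidal Lucas-Kanade registration of each corner from frame
to frame, rejection of features whose frame-to-frame speed fluctuates too
much to be trusted, and decomposition of the surviving flow field into
four per-transition parameters — mean clockwise and anti-clockwise
rotation about the tracked-feature centroid, and the centroid displacement
in polar form.  Rotation is measured about the feature centroid, not the
image centre, because the embryo drifts freely inside its capsule.

Coordinates are screen coordinates: x right, y down, origin at the
top-left pixel centre.  With y increasing downward, a positive angular
displacement is clockwise as seen on screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import corner_peaks, corner_shi_tomasi

from .io import FrameSequence, MotionRecord

__all__ = [
    "TrackingConfig",
    "FeatureSet",
    "TrackedStep",
    "FlowDecomposition",
    "detect_features",
    "track_step",
    "reject_high_variance",
    "decompose_motion",
    "analyze_sequence",
]

logger = logging.getLogger(__name__)

#: Features closer than this to the centroid are excluded from rotation.
CENTROID_RADIUS_EPS = 1e-6


@dataclass
class TrackingConfig:
    """All tunable tracking parameters, with desk-tested defaults.

    Units: distances in pixels, variances in px^2/frame^2, windows in
    frames or pixels as named.
    """

    max_features: int = 400
    quality: float = 0.01            # relative corner threshold in (0, 1]
    min_distance: int = 5            # px between detected corners
    window: int = 21                 # LK integration window side, px (odd)
    pyramid_levels: int = 3
    max_iterations: int = 20         # LK refinement steps per level
    epsilon: float = 1e-3            # LK convergence threshold, px
    min_eigenvalue: float = 1e-5     # per-pixel gradient-matrix floor
    max_residual: float = 0.15       # mean |I-J| above which a match is lost
    history_window: int = 15         # frames of speed history for rejection
    variance_threshold: float = 4.0  # px^2/frame^2
    redetect_interval: int = 50      # frames between forced re-detections
    min_retained_frac: float = 0.5   # redetect when retained/detected drops below
    roi_center: tuple[float, float] | None = None  # optional circular mask (x, y)
    roi_radius: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrackingConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if cfg.roi_center is not None:
            cfg.roi_center = tuple(cfg.roi_center)  # type: ignore[assignment]
        return cfg


@dataclass
class FeatureSet:
    """Sub-pixel corner positions with stable integer identifiers."""

    positions: np.ndarray  # (n, 2) as (x, y)
    ids: np.ndarray        # (n,) int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 2)
        self.ids = np.asarray(self.ids, dtype=np.int64).reshape(-1)
        if len(self.ids) != len(self.positions):
            raise ValueError("ids and positions must have equal length")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("feature ids must be unique")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class TrackedStep:
    """Result of registering one feature set between consecutive frames."""

    prev_positions: np.ndarray          # (n, 2)
    next_positions: np.ndarray          # (n, 2); NaN where lost
    status: np.ndarray                  # (n,) bool, True = tracked
    ids: np.ndarray                     # (n,) int
    velocity_history: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.prev_positions)
        if not (len(self.next_positions) == len(self.status) == len(self.ids) == n):
            raise ValueError("matched lists must have equal length")

    @property
    def displacements(self) -> np.ndarray:
        """(n, 2) next - prev; NaN rows where the feature was lost."""
        return self.next_positions - self.prev_positions


@dataclass
class FlowDecomposition:
    """The four motion parameters for one frame transition."""

    pos_angle: float
    neg_angle: float
    com_rho: float
    com_theta: float
    n_features_used: int
    com_dx: float = 0.0
    com_dy: float = 0.0


def _apply_roi(coords_rc: np.ndarray, response: np.ndarray,
               center: tuple[float, float], radius: float) -> np.ndarray:
    dx = coords_rc[:, 1] - center[0]
    dy = coords_rc[:, 0] - center[1]
    return coords_rc[dx * dx + dy * dy <= radius * radius]


def detect_features(frame: np.ndarray, max_features: int = 400,
                    quality: float = 0.01, min_distance: int = 5,
                    roi_center: tuple[float, float] | None = None,
                    roi_radius: float | None = None,
                    start_id: int = 0) -> FeatureSet:
    """Detect Shi-Tomasi corners, strongest first.

    Returns at most ``max_features`` corners whose minimum-eigenvalue
    response exceeds ``quality`` times the strongest response, separated
    by at least ``min_distance`` pixels.  A uniform frame yields an empty
    set (not an error).
    """
    frame = np.asarray(frame, dtype=np.float64)
    response = corner_shi_tomasi(frame, sigma=1.5)
    if not np.any(response > 0):
        return FeatureSet(np.empty((0, 2)), np.empty(0, dtype=np.int64))
    coords = corner_peaks(
        response,
        min_distance=int(min_distance),
        threshold_rel=float(quality),
        num_peaks=int(max_features) if roi_center is None else np.inf,
        exclude_border=True,
    )
    if roi_center is not None and roi_radius is not None and len(coords):
        coords = _apply_roi(coords, response, roi_center, roi_radius)
    if len(coords) == 0:
        return FeatureSet(np.empty((0, 2)), np.empty(0, dtype=np.int64))
    order = np.argsort(response[coords[:, 0], coords[:, 1]])[::-1]
    coords = coords[order][: int(max_features)]
    positions = coords[:, ::-1].astype(np.float64)  # (row, col) -> (x, y)
    ids = np.arange(start_id, start_id + len(positions), dtype=np.int64)
    return FeatureSet(positions, ids)


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    # light pre-smoothing suppresses sensor noise before differentiation;
    # sub-pixel accuracy on clean imagery is unaffected at this sigma
    base = ndimage.gaussian_filter(np.asarray(img, dtype=np.float64),
                                   sigma=0.75, mode="nearest")
    pyr = [base]
    for _ in range(1, levels):
        prev = pyr[-1]
        if min(prev.shape) < 8:
            break
        sm = ndimage.gaussian_filter(prev, sigma=1.0, mode="nearest")
        pyr.append(sm[::2, ::2])
    return pyr


def _sample(img: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Bilinear sample of img at (..., 2) xy points; edge-clamped."""
    coords = np.stack([xy[..., 1].ravel(), xy[..., 0].ravel()])
    out = ndimage.map_coordinates(img, coords, order=1, mode="nearest")
    return out.reshape(xy.shape[:-1])


def track_step(prev_frame: np.ndarray, next_frame: np.ndarray,
               features: FeatureSet, window: int = 21,
               pyramid_levels: int = 3, max_iterations: int = 20,
               epsilon: float = 1e-3, min_eigenvalue: float = 1e-5,
               max_residual: float = 0.15) -> TrackedStep:
    """Register features between two frames with pyramidal Lucas-Kanade.

    Each corner is refined coarse-to-fine: at every pyramid level the local
    translation is solved iteratively from the spatial-gradient normal
    equations over a ``window`` x ``window`` patch.  A feature is flagged
    lost when its final position leaves the frame, its gradient matrix is
    near-singular (untrackable aperture), the solution diverges beyond the
    window, or the final photometric residual stays high.

    Raises
    ------
    ValueError
        If ``features`` is empty or frame shapes differ.
    """
    prev_frame = np.asarray(prev_frame, dtype=np.float64)
    next_frame = np.asarray(next_frame, dtype=np.float64)
    if prev_frame.shape != next_frame.shape:
        raise ValueError("prev and next frames must share a shape")
    if len(features) == 0:
        raise ValueError("cannot track an empty FeatureSet")

    n = len(features)
    half = window // 2
    offs = np.arange(-half, half + 1, dtype=np.float64)
    ox, oy = np.meshgrid(offs, offs)
    grid = np.stack([ox.ravel(), oy.ravel()], axis=-1)  # (w*w, 2)
    # Gaussian window weighting centres the estimate on the feature itself,
    # which keeps features near texture boundaries from being dragged toward
    # the interior gradient mass.
    wgt = np.exp(-(ox.ravel() ** 2 + oy.ravel() ** 2) / (2 * (half / 1.5) ** 2))

    prev_pyr = _pyramid(prev_frame, pyramid_levels)
    next_pyr = _pyramid(next_frame, pyramid_levels)
    levels = len(prev_pyr)

    flow = np.zeros((n, 2))
    alive = np.ones(n, dtype=bool)
    residual = np.zeros(n)
    min_eig = np.zeros(n)

    for lvl in range(levels - 1, -1, -1):
        scale = 2.0 ** lvl
        pL, nL = prev_pyr[lvl], next_pyr[lvl]
        gy, gx = np.gradient(pL)
        base = features.positions / scale  # (n, 2)
        pts = base[:, None, :] + grid[None, :, :]  # (n, w*w, 2)

        patch_i = _sample(pL, pts)
        patch_gx = _sample(gx, pts)
        patch_gy = _sample(gy, pts)

        gxx = np.sum(wgt * patch_gx * patch_gx, axis=1)
        gxy = np.sum(wgt * patch_gx * patch_gy, axis=1)
        gyy = np.sum(wgt * patch_gy * patch_gy, axis=1)
        det = gxx * gyy - gxy * gxy
        trace = gxx + gyy
        eig_min = 0.5 * (trace - np.sqrt(np.maximum(trace * trace - 4 * det, 0.0)))
        min_eig = eig_min / (window * window)
        solvable = det > 1e-12

        gl = flow / scale  # carry the coarser level's estimate down
        active = alive & solvable
        for _ in range(max_iterations):
            if not np.any(active):
                break
            pts_j = base[active][:, None, :] + gl[active][:, None, :] + grid[None, :, :]
            patch_j = _sample(nL, pts_j)
            diff = patch_i[active] - patch_j
            bx = np.sum(wgt * diff * patch_gx[active], axis=1)
            by = np.sum(wgt * diff * patch_gy[active], axis=1)
            d = det[active]
            nu_x = (gyy[active] * bx - gxy[active] * by) / d
            nu_y = (gxx[active] * by - gxy[active] * bx) / d
            gl_active = gl[active]
            gl_active[:, 0] += nu_x
            gl_active[:, 1] += nu_y
            gl[active] = gl_active
            step_mag = np.hypot(nu_x, nu_y)
            conv = np.zeros(n, dtype=bool)
            conv[np.flatnonzero(active)] = step_mag < epsilon
            active = active & ~conv
        flow = gl * scale
        # divergence beyond the search window at this level -> lost
        alive &= np.isfinite(flow).all(axis=1)
        alive &= np.hypot(flow[:, 0], flow[:, 1]) <= window * scale

    # final checks at full resolution
    alive &= min_eig >= min_eigenvalue
    next_pos = features.positions + flow
    h, w = prev_frame.shape
    alive &= (next_pos[:, 0] >= 0) & (next_pos[:, 0] <= w - 1)
    alive &= (next_pos[:, 1] >= 0) & (next_pos[:, 1] <= h - 1)
    if np.any(alive):
        idx = np.flatnonzero(alive)
        pts_j = (features.positions[idx] + flow[idx])[:, None, :] + grid[None, :, :]
        patch_j = _sample(next_pyr[0], pts_j)
        pts_i = features.positions[idx][:, None, :] + grid[None, :, :]
        patch_i0 = _sample(prev_pyr[0], pts_i)
        residual[idx] = np.mean(np.abs(patch_i0 - patch_j), axis=1)
        alive[idx] &= residual[idx] <= max_residual

    next_positions = np.where(alive[:, None], next_pos, np.nan)
    return TrackedStep(
        prev_positions=features.positions.copy(),
        next_positions=next_positions,
        status=alive,
        ids=features.ids.copy(),
    )


def reject_high_variance(step: TrackedStep, history_window: int = 15,
                         variance_threshold: float = 4.0) -> TrackedStep:
    """Drop features whose recent speed fluctuates beyond the threshold.

    The variance of each feature's displacement magnitudes over the
    trailing ``history_window`` observations (or however many exist) is
    compared against ``variance_threshold``; a feature is only eligible
    for rejection once it has at least 3 observations.  A wildly varying
    speed indicates the corner is not being tracked accurately.
    """
    if not step.velocity_history:
        return step
    status = step.status.copy()
    for i, hist in enumerate(step.velocity_history):
        if not status[i]:
            continue
        hist = np.asarray(hist, dtype=np.float64)[-history_window:]
        if len(hist) < 3:
            continue
        if np.var(hist) > variance_threshold:
            status[i] = False
    next_positions = np.where(status[:, None], step.next_positions, np.nan)
    return TrackedStep(
        prev_positions=step.prev_positions,
        next_positions=next_positions,
        status=status,
        ids=step.ids,
        velocity_history=step.velocity_history,
    )


def _wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into (-pi, pi]."""
    return -((-np.asarray(a) + np.pi) % (2 * np.pi) - np.pi)


def decompose_motion(step: TrackedStep) -> FlowDecomposition:
    """Decompose a tracked step into the four motion parameters.

    The centroid of the matched features defines the centre of mass; its
    frame-to-frame displacement is reported in polar form (rho, theta).
    Each feature's angular position about its own frame's centroid is
    differenced and wrapped into (-pi, pi]; positive differences (clockwise
    on screen, y down) average into ``pos_angle`` and the magnitudes of
    negative differences into ``neg_angle``.  Features essentially on the
    centroid contribute to the centroid but not to rotation.  With no
    tracked features all four parameters are zero.
    """
    ok = step.status
    if not np.any(ok):
        return FlowDecomposition(0.0, 0.0, 0.0, 0.0, 0)
    p = step.prev_positions[ok]
    q = step.next_positions[ok]
    c_prev = p.mean(axis=0)
    c_next = q.mean(axis=0)
    v = c_next - c_prev
    com_rho = float(np.hypot(v[0], v[1]))
    com_theta = float(np.arctan2(v[1], v[0])) if com_rho > 0 else 0.0
    com_theta = float(_wrap_angle(com_theta))

    rp = p - c_prev
    rq = q - c_next
    rad_p = np.hypot(rp[:, 0], rp[:, 1])
    rad_q = np.hypot(rq[:, 0], rq[:, 1])
    rotatable = (rad_p >= CENTROID_RADIUS_EPS) & (rad_q >= CENTROID_RADIUS_EPS)
    if np.any(rotatable):
        th_p = np.arctan2(rp[rotatable, 1], rp[rotatable, 0])
        th_q = np.arctan2(rq[rotatable, 1], rq[rotatable, 0])
        delta = _wrap_angle(th_q - th_p)
        pos = delta[delta > 0]
        neg = delta[delta < 0]
        pos_angle = float(pos.mean()) if len(pos) else 0.0
        neg_angle = float(-neg.mean()) if len(neg) else 0.0
    else:
        pos_angle = neg_angle = 0.0
    return FlowDecomposition(
        pos_angle=pos_angle,
        neg_angle=neg_angle,
        com_rho=com_rho,
        com_theta=com_theta,
        n_features_used=int(np.sum(ok)),
        com_dx=float(v[0]),
        com_dy=float(v[1]),
    )


def analyze_sequence(seq: FrameSequence, config: TrackingConfig | None = None) -> MotionRecord:
    """Run the full tracking pipeline over an image sequence.

    Corners are detected on the first frame and re-detected whenever the
    retained fraction drops below ``min_retained_frac`` of the count found
    at the last detection epoch, or every ``redetect_interval`` frames.
    Each transition is decomposed using only the features that survive
    tracking and variance rejection.  Transitions with no usable features
    emit zeros so the output stays gap-free for spectral analysis.

    Returns a :class:`MotionRecord` of length ``len(seq) - 1``.
    """
    cfg = config or TrackingConfig()
    frames = seq.frames
    n_trans = len(frames) - 1

    pos_a = np.zeros(n_trans)
    neg_a = np.zeros(n_trans)
    rho = np.zeros(n_trans)
    theta = np.zeros(n_trans)
    dxs = np.zeros(n_trans)
    dys = np.zeros(n_trans)

    features: FeatureSet | None = None
    histories: dict[int, list[float]] = {}
    next_id = 0
    last_detect_frame = -10**9
    epoch_count = 0
    any_features_ever = False

    def _detect(frame_idx: int) -> FeatureSet:
        nonlocal next_id, last_detect_frame, epoch_count
        fs = detect_features(
            frames[frame_idx], cfg.max_features, cfg.quality, cfg.min_distance,
            roi_center=cfg.roi_center, roi_radius=cfg.roi_radius,
            start_id=next_id,
        )
        next_id += len(fs)
        last_detect_frame = frame_idx
        epoch_count += 1
        logger.info(
            "%s: epoch %d at frame %d: detected %d features",
            seq.source_id, epoch_count, frame_idx, len(fs),
        )
        return fs

    epoch_size = 0
    for t in range(n_trans):
        need = (
            features is None
            or len(features) == 0
            or (t - last_detect_frame) >= cfg.redetect_interval
            or (epoch_size > 0 and len(features) < cfg.min_retained_frac * epoch_size)
        )
        if need:
            features = _detect(t)
            epoch_size = len(features)
            histories = {int(i): [] for i in features.ids}
        if len(features) == 0:
            continue  # zeros already in place
        any_features_ever = True

        step = track_step(
            frames[t], frames[t + 1], features,
            window=cfg.window, pyramid_levels=cfg.pyramid_levels,
            max_iterations=cfg.max_iterations, epsilon=cfg.epsilon,
            min_eigenvalue=cfg.min_eigenvalue, max_residual=cfg.max_residual,
        )
        disp = step.displacements
        speeds = np.hypot(disp[:, 0], disp[:, 1])
        for i, fid in enumerate(step.ids):
            if step.status[i]:
                histories[int(fid)].append(float(speeds[i]))
        step.velocity_history = [
            np.asarray(histories.get(int(fid), []), dtype=np.float64)
            for fid in step.ids
        ]
        kept = reject_high_variance(step, cfg.history_window, cfg.variance_threshold)
        dec = decompose_motion(kept)
        pos_a[t] = dec.pos_angle
        neg_a[t] = dec.neg_angle
        rho[t] = dec.com_rho
        theta[t] = dec.com_theta
        dxs[t] = dec.com_dx
        dys[t] = dec.com_dy

        survivors = kept.status
        if np.any(survivors):
            features = FeatureSet(
                positions=kept.next_positions[survivors],
                ids=kept.ids[survivors],
            )
        else:
            features = FeatureSet(np.empty((0, 2)), np.empty(0, dtype=np.int64))

    if not any_features_ever:
        logger.warning("%s: no trackable features in the whole sequence; "
                       "motion record is all zeros", seq.source_id)
    return MotionRecord(
        pos_angle=pos_a, neg_angle=neg_a, com_rho=rho, com_theta=theta,
        fps=seq.fps, source_id=seq.source_id, com_dx=dxs, com_dy=dys,
    )
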