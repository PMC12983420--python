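"""Sparse optical-flow ROI tracking with per-frame rigid pose estimation.

Each annotated ROI is tracked through the cine by the classic sparse
pipeline: Shi-Tomasi corner detection inside the rectangle, pyramidal
Lucas-Kanade flow frame-to-frame with a forward-backward validity check,
and a robust (RANSAC + least-squares) rigid rotation+translation fit that
carries the ROI origin's pose through the loop.  When too many points are
lost, features are re-seeded inside the current ROI pose and tracking
continues with pose continuity preserved.

The pose model is rigid (no scale/shear): the kinematic metrics downstream
are positions and rotations of rigid urethral segments.  Frame-to-frame
(rather than frame-0-to-frame-t) matching is used because speckle
decorrelates over long intervals; drift is bounded empirically against the
simulator's ground truth rather than assumed away.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import corner_peaks, corner_shi_tomasi

from .cine_io import CineLoop, RoiAnnotation, RoiRect
from .errors import (
    ArgumentError,
    DegeneratePoseError,
    LowTextureError,
    TrackingLossError,
)


@dataclass(frozen=True)
class TrackerSettings:
    """Sparse-LK tracker parameters (all exposed in the run config)."""

    max_corners: int = 80
    quality_level: float = 0.01     # Shi-Tomasi response threshold, relative to max
    shi_tomasi_sigma: float = 0.5   # structure-tensor integration scale
    min_corner_distance_px: int = 2
    detect_margin_px: float = 5.0   # keep detections away from the patch seam
    window_px: int = 21             # LK integration window (odd)
    pyramid_levels: int = 3
    max_iterations: int = 20
    convergence_eps_px: float = 0.02
    fb_tol_px: float = 1.0          # forward-backward validity threshold
    min_ncc: float = 0.5            # template/match appearance agreement
    min_points: int = 10
    reseed_fraction: float = 0.5
    ransac_threshold_px: float = 2.0
    ransac_iterations: int = 100
    min_eigenvalue: float = 1e-7    # reject flat gradient structure tensors
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_px < 5 or self.window_px % 2 == 0:
            raise ArgumentError("window_px must be odd and >= 5")
        if self.pyramid_levels < 1:
            raise ArgumentError("pyramid_levels must be >= 1")
        if self.min_points < 3:
            raise ArgumentError("min_points must be >= 3")


@dataclass(frozen=True)
class FeatureSet:
    """Corner features detected inside one ROI at a reference frame."""

    points_px: np.ndarray        # (N, 2) as (x, y)
    quality: np.ndarray          # (N,) Shi-Tomasi response, descending
    valid: np.ndarray            # (N,) bool


@dataclass
class PoseSeries:
    """Per-frame pose of one ROI's origin in image coordinates.

    ``theta_deg`` is the accumulated in-plane rotation in raster-coordinate
    convention (positive = clockwise on screen); the pelvic-frame module
    flips it to the anatomical convention.
    """

    roi: str
    x_px: np.ndarray
    y_px: np.ndarray
    theta_deg: np.ndarray
    n_points_tracked: np.ndarray
    fb_error_px: np.ndarray
    reseeded: np.ndarray

    @property
    def n_frames(self) -> int:
        return int(self.x_px.shape[0])

    @property
    def origin_px(self) -> np.ndarray:
        return np.column_stack([self.x_px, self.y_px])


# ---------------------------------------------------------------------------
# feature detection
# ---------------------------------------------------------------------------

def detect_features(frame: np.ndarray, roi: RoiRect,
                    settings: TrackerSettings = TrackerSettings(),
                    roi_label: str = "roi") -> FeatureSet:
    """Shi-Tomasi corners inside ``roi``, ranked by response.

    Deterministic; raises :class:`LowTextureError` when fewer than
    ``settings.min_points`` corners exist (e.g. a constant-intensity ROI).
    """
    frame = np.asarray(frame, dtype=np.float64)
    h, w = frame.shape
    m = settings.detect_margin_px
    c0 = int(np.ceil(roi.x_px + m))
    c1 = int(np.floor(roi.x_px + roi.width_px - m)) + 1
    r0 = int(np.ceil(roi.y_px - roi.height_px + m))
    r1 = int(np.floor(roi.y_px - m)) + 1
    c0, r0 = max(c0, 0), max(r0, 0)
    c1, r1 = min(c1, w), min(r1, h)
    if c1 - c0 < 8 or r1 - r0 < 8:
        raise LowTextureError(f"ROI '{roi_label}': rectangle too small to detect in")
    crop = frame[r0:r1, c0:c1]
    response = corner_shi_tomasi(crop, sigma=settings.shi_tomasi_sigma)
    if response.max() <= 0:
        raise LowTextureError(f"ROI '{roi_label}': no texture (flat Shi-Tomasi response)")
    peaks = corner_peaks(response, min_distance=settings.min_corner_distance_px,
                         threshold_rel=settings.quality_level, exclude_border=1)
    if peaks.shape[0] < settings.min_points:
        raise LowTextureError(
            f"ROI '{roi_label}': only {peaks.shape[0]} corner(s) found "
            f"(need >= {settings.min_points})"
        )
    scores = response[peaks[:, 0], peaks[:, 1]]
    order = np.argsort(scores)[::-1][: settings.max_corners]
    peaks, scores = peaks[order], scores[order]
    points = np.column_stack([peaks[:, 1] + c0, peaks[:, 0] + r0]).astype(float)
    return FeatureSet(points, scores.astype(float), np.ones(len(points), bool))


# ---------------------------------------------------------------------------
# pyramidal Lucas-Kanade flow
# ---------------------------------------------------------------------------

class _Pyramid:
    """Image pyramid with per-level spatial gradients, built once per frame."""

    __slots__ = ("levels", "grads")

    def __init__(self, image: np.ndarray, n_levels: int):
        image = np.asarray(image, dtype=np.float32)
        self.levels = [image]
        for _ in range(n_levels - 1):
            smoothed = ndimage.gaussian_filter(self.levels[-1], sigma=1.0)
            self.levels.append(np.ascontiguousarray(smoothed[::2, ::2]))
        self.grads = []
        for lvl in self.levels:
            gy, gx = np.gradient(lvl)
            self.grads.append((gx.astype(np.float32), gy.astype(np.float32)))


def _sample(image: np.ndarray, coords_xy: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Bilinear patches around each point; returns (N, window**2).

    Vectorized gather (edge-clamped), much faster than generic resampling for
    the many small windows the tracker reads per frame.
    """
    # coords_xy (N, 2); offsets (window**2, 2) in (dx, dy)
    h, w = image.shape
    xs = coords_xy[:, 0, None] + offsets[None, :, 0]
    ys = coords_xy[:, 1, None] + offsets[None, :, 1]
    np.clip(xs, 0.0, w - 1.0, out=xs)
    np.clip(ys, 0.0, h - 1.0, out=ys)
    x0 = xs.astype(np.intp)
    y0 = ys.astype(np.intp)
    np.minimum(x0, w - 2, out=x0)
    np.minimum(y0, h - 2, out=y0)
    fx = xs - x0
    fy = ys - y0
    flat = image.ravel()
    base = y0 * w + x0
    v00 = flat[base]
    v01 = flat[base + 1]
    v10 = flat[base + w]
    v11 = flat[base + w + 1]
    top = v00 + fx * (v01 - v00)
    bot = v10 + fx * (v11 - v10)
    return top + fy * (bot - top)


def _lk_pyramidal(pyr_a: _Pyramid, pyr_b: _Pyramid, points: np.ndarray,
                  settings: TrackerSettings,
                  init_flow: np.ndarray | None = None,
                  top_level: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Track ``points`` from pyramid A to pyramid B; returns (moved, ok).

    ``init_flow`` seeds the displacement estimate (e.g. the negated forward
    flow for the backward validation pass), in which case coarse pyramid
    levels can be skipped via ``top_level``.
    """
    n = points.shape[0]
    half = settings.window_px // 2
    grid = np.arange(-half, half + 1, dtype=float)
    ox, oy = np.meshgrid(grid, grid)
    offsets = np.column_stack([ox.ravel(), oy.ravel()])
    # Gaussian window weighting: periphery pixels (which may straddle the
    # moving-patch boundary) contribute little to the normal equations
    wgt = np.exp(-(offsets ** 2).sum(axis=1)
                 / (2.0 * (half / 2.0) ** 2)).astype(np.float32)

    if top_level is None:
        top_level = len(pyr_a.levels) - 1
    if init_flow is None:
        g = np.zeros((n, 2))
    else:
        g = np.asarray(init_flow, dtype=float) / (2.0 ** top_level)
    ok = np.ones(n, dtype=bool)
    for level in range(top_level, -1, -1):
        A = pyr_a.levels[level]
        B = pyr_b.levels[level]
        gx_img, gy_img = pyr_a.grads[level]
        p = points / (2.0 ** level)
        T = _sample(A, p, offsets)
        Gx = _sample(gx_img, p, offsets)
        Gy = _sample(gy_img, p, offsets)
        Gxw = Gx * wgt
        Gyw = Gy * wgt
        gxx = np.einsum("ij,ij->i", Gxw, Gx)
        gxy = np.einsum("ij,ij->i", Gxw, Gy)
        gyy = np.einsum("ij,ij->i", Gyw, Gy)
        det = gxx * gyy - gxy * gxy
        trace = gxx + gyy
        # smaller eigenvalue of the structure tensor, per pixel count
        lam_min = 0.5 * (trace - np.sqrt(np.maximum(trace * trace - 4 * det, 0.0)))
        flat = lam_min / offsets.shape[0] < settings.min_eigenvalue
        ok &= ~flat
        det = np.where(np.abs(det) < 1e-12, np.inf, det)
        d = np.zeros((n, 2))
        active = ok.copy()
        for _ in range(settings.max_iterations):
            if not active.any():
                break
            q = p + g + d
            I = _sample(B, q[active], offsets)
            e = T[active] - I
            bx = np.einsum("ij,ij->i", Gxw[active], e)
            by = np.einsum("ij,ij->i", Gyw[active], e)
            inv_det = 1.0 / det[active]
            dx = (gyy[active] * bx - gxy[active] * by) * inv_det
            dy = (gxx[active] * by - gxy[active] * bx) * inv_det
            d[active, 0] += dx
            d[active, 1] += dy
            step = np.hypot(dx, dy)
            still = np.zeros(n, dtype=bool)
            still[np.flatnonzero(active)[step >= settings.convergence_eps_px]] = True
            active = still
        g = (g + d) * (2.0 if level > 0 else 1.0)
    moved = points + g
    h, w = pyr_a.levels[0].shape
    inb = ((moved[:, 0] >= 0) & (moved[:, 0] <= w - 1)
           & (moved[:, 1] >= 0) & (moved[:, 1] <= h - 1))
    ok &= inb
    return moved, ok


def flow_step(frame_a: np.ndarray, frame_b: np.ndarray, points: np.ndarray,
              settings: TrackerSettings = TrackerSettings(),
              pyr_a: _Pyramid | None = None, pyr_b: _Pyramid | None = None,
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One sparse pyramidal LK step a -> b with forward-backward validation.

    Returns ``(moved_points, valid, fb_error_px)``.  A point is valid iff its
    backward-tracked position lands within ``settings.fb_tol_px`` of where it
    started.  Raises :class:`TrackingLossError` if no point survives.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 1:
        raise ArgumentError("flow_step needs at least one point")
    frame_a = np.asarray(frame_a, dtype=np.float64)
    frame_b = np.asarray(frame_b, dtype=np.float64)
    if frame_a.shape != frame_b.shape:
        raise ArgumentError("frames must have identical shapes")
    if pyr_a is None:
        pyr_a = _Pyramid(frame_a, settings.pyramid_levels)
    if pyr_b is None:
        pyr_b = _Pyramid(frame_b, settings.pyramid_levels)
    moved, ok_f = _lk_pyramidal(pyr_a, pyr_b, points, settings)
    # backward pass starts from the negated forward flow, so it needs no
    # coarse-to-fine search of its own
    back, ok_b = _lk_pyramidal(pyr_b, pyr_a, moved, settings,
                               init_flow=points - moved, top_level=0)
    fb_err = np.linalg.norm(back - points, axis=1)
    # appearance agreement: a geometrically self-consistent but wrong match
    # (decorrelated speckle, occlusion) shows low template correlation
    half = settings.window_px // 2
    grid = np.arange(-half, half + 1, dtype=float)
    ox, oy = np.meshgrid(grid, grid)
    offsets = np.column_stack([ox.ravel(), oy.ravel()])
    Ta = _sample(pyr_a.levels[0], points, offsets)
    Tb = _sample(pyr_b.levels[0], moved, offsets)
    Ta = Ta - Ta.mean(axis=1, keepdims=True)
    Tb = Tb - Tb.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.einsum("ij,ij->i", Ta, Ta) * np.einsum("ij,ij->i", Tb, Tb))
    ncc = np.einsum("ij,ij->i", Ta, Tb) / np.where(denom < 1e-12, np.inf, denom)
    valid = ok_f & ok_b & (fb_err <= settings.fb_tol_px) & (ncc >= settings.min_ncc)
    if not valid.any():
        raise TrackingLossError("optical flow lost every point between frames")
    return moved, valid, fb_err


# ---------------------------------------------------------------------------
# rigid pose estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoseEstimate:
    """Rigid fit ``p' = R p + t`` with the translation also reported about a
    reference center (``tx_px, ty_px`` = displacement of that center)."""

    tx_px: float
    ty_px: float
    dtheta_deg: float
    inliers: np.ndarray
    rms_px: float
    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation.T + self.translation


def _kabsch_2d(ref: np.ndarray, cur: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cr = ref.mean(axis=0)
    cc = cur.mean(axis=0)
    a = ref - cr
    b = cur - cc
    num = float(np.sum(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]))
    den = float(np.sum(a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]))
    theta = np.arctan2(num, den)
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    t = cc - R @ cr
    return R, t


def estimate_rigid_pose(points_ref: np.ndarray, points_cur: np.ndarray,
                        validity: np.ndarray | None = None,
                        center: np.ndarray | None = None,
                        settings: TrackerSettings = TrackerSettings(),
                        ) -> PoseEstimate:
    """Robust least-squares rotation+translation from point correspondences.

    RANSAC on 2-point minimal samples selects an inlier consensus
    (threshold ``settings.ransac_threshold_px``), followed by a closed-form
    Kabsch refit on the inliers.  ``tx_px, ty_px`` report the displacement of
    ``center`` (default: the centroid of the valid reference points), so that
    a rotation about that center contributes no translation.
    """
    ref = np.atleast_2d(np.asarray(points_ref, dtype=float))
    cur = np.atleast_2d(np.asarray(points_cur, dtype=float))
    if ref.shape != cur.shape:
        raise ArgumentError("points_ref and points_cur must have the same shape")
    if validity is None:
        validity = np.ones(ref.shape[0], dtype=bool)
    validity = np.asarray(validity, dtype=bool)
    idx = np.flatnonzero(validity)
    if idx.size < settings.min_points:
        raise DegeneratePoseError(
            f"only {idx.size} valid correspondence(s); need >= {settings.min_points}"
        )
    ref_v, cur_v = ref[idx], cur[idx]
    if center is None:
        center = ref_v.mean(axis=0)
    center = np.asarray(center, dtype=float)

    rng = np.random.default_rng(settings.seed)
    best_inliers: np.ndarray | None = None
    thr = settings.ransac_threshold_px
    n = idx.size
    for _ in range(settings.ransac_iterations):
        i, j = rng.choice(n, size=2, replace=False)
        if np.linalg.norm(ref_v[i] - ref_v[j]) < 1e-9:
            continue
        R, t = _kabsch_2d(ref_v[[i, j]], cur_v[[i, j]])
        resid = np.linalg.norm(ref_v @ R.T + t - cur_v, axis=1)
        inl = resid < thr
        if best_inliers is None or inl.sum() > best_inliers.sum():
            best_inliers = inl
            if inl.all():
                break
    if best_inliers is None or best_inliers.sum() < settings.min_points:
        raise DegeneratePoseError("RANSAC found no rigid-consistent point subset")
    # refit on inliers, then re-harvest inliers once for stability
    for _ in range(2):
        R, t = _kabsch_2d(ref_v[best_inliers], cur_v[best_inliers])
        resid = np.linalg.norm(ref_v @ R.T + t - cur_v, axis=1)
        new_inliers = resid < thr
        if new_inliers.sum() < settings.min_points:
            break
        best_inliers = new_inliers
    rms = float(np.sqrt(np.mean(resid[best_inliers] ** 2)))
    theta = float(np.degrees(np.arctan2(R[1, 0], R[0, 0])))
    moved_center = R @ center + t
    inlier_mask = np.zeros(ref.shape[0], dtype=bool)
    inlier_mask[idx[best_inliers]] = True
    return PoseEstimate(float(moved_center[0] - center[0]),
                        float(moved_center[1] - center[1]),
                        theta, inlier_mask, rms, R, t)


# ---------------------------------------------------------------------------
# full-loop tracking
# ---------------------------------------------------------------------------

def _transformed_rect_corners(rect: RoiRect, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return rect.corners @ R.T + t


class _RoiTracker:
    """Tracking state for one ROI while stepping through the loop."""

    def __init__(self, cine: CineLoop, rect: RoiRect, label: str,
                 settings: TrackerSettings):
        self.cine = cine
        self.rect = rect
        self.label = label
        self.settings = settings
        features = detect_features(cine.frames[0], rect, settings, label)
        self.points = features.points_px
        self.n_seed = len(self.points)
        self.R = np.eye(2)
        self.t = np.zeros(2)
        self.theta = 0.0
        T = cine.n_frames
        origin = rect.origin
        self.series = PoseSeries(
            roi=label,
            x_px=np.full(T, origin[0]), y_px=np.full(T, origin[1]),
            theta_deg=np.zeros(T), n_points_tracked=np.zeros(T, dtype=int),
            fb_error_px=np.zeros(T), reseeded=np.zeros(T, dtype=bool),
        )
        self.series.n_points_tracked[0] = self.n_seed

    def _check_bounds(self, frame_index: int) -> None:
        h, w = self.cine.frame_shape
        corners = _transformed_rect_corners(self.rect, self.R, self.t)
        if (corners[:, 0].min() < 0 or corners[:, 1].min() < 0
                or corners[:, 0].max() > w - 1 or corners[:, 1].max() > h - 1):
            raise TrackingLossError(
                f"ROI '{self.label}' left the frame at frame {frame_index}"
            )

    def _reseed(self, frame: np.ndarray, frame_index: int) -> bool:
        """Re-detect features inside the current ROI pose; True on success."""
        corners = _transformed_rect_corners(self.rect, self.R, self.t)
        x0, y1 = corners[:, 0].min(), corners[:, 1].max()
        bbox = RoiRect(x0, y1, corners[:, 0].max() - x0, y1 - corners[:, 1].min())
        try:
            features = detect_features(frame, bbox, self.settings, self.label)
        except LowTextureError:
            return False
        # keep only points truly inside the transformed rectangle
        local = (features.points_px - self.t) @ self.R  # inverse rotation
        inside = self.rect.contains(local)
        pts = features.points_px[inside]
        if len(pts) < self.settings.min_points:
            return False
        self.points = pts
        self.n_seed = len(pts)
        self.series.reseeded[frame_index] = True
        return True

    def step(self, pyr_prev: _Pyramid, pyr_cur: _Pyramid, frame_index: int) -> None:
        s = self.settings
        try:
            moved, valid, fb_err = flow_step(
                pyr_prev.levels[0], pyr_cur.levels[0], self.points, s,
                pyr_a=pyr_prev, pyr_b=pyr_cur)
            est = estimate_rigid_pose(self.points, moved, valid, settings=s)
        except (TrackingLossError, DegeneratePoseError):
            # try a fresh seeding in the previous frame, then one more step
            if not self._reseed(pyr_prev.levels[0], frame_index):
                raise TrackingLossError(
                    f"unrecoverable tracking loss for ROI '{self.label}' "
                    f"at frame {frame_index}"
                )
            moved, valid, fb_err = flow_step(
                pyr_prev.levels[0], pyr_cur.levels[0], self.points, s,
                pyr_a=pyr_prev, pyr_b=pyr_cur)
            est = estimate_rigid_pose(self.points, moved, valid, settings=s)
        self.R = est.rotation @ self.R
        self.t = est.rotation @ self.t + est.translation
        self.theta += est.dtheta_deg
        origin = self.R @ self.rect.origin + self.t
        ser = self.series
        ser.x_px[frame_index] = origin[0]
        ser.y_px[frame_index] = origin[1]
        ser.theta_deg[frame_index] = self.theta
        keep = est.inliers
        ser.n_points_tracked[frame_index] = int(keep.sum())
        ser.fb_error_px[frame_index] = float(fb_err[keep].mean()) if keep.any() else np.nan
        self._check_bounds(frame_index)
        self.points = moved[keep]
        if len(self.points) < s.reseed_fraction * self.n_seed:
            if not self._reseed(pyr_cur.levels[0], frame_index):
                if len(self.points) < s.min_points:
                    raise TrackingLossError(
                        f"unrecoverable tracking loss for ROI '{self.label}' "
                        f"at frame {frame_index}"
                    )


def track_rois(cine: CineLoop, rois: dict[str, RoiRect],
               settings: TrackerSettings = TrackerSettings(),
               ) -> dict[str, PoseSeries]:
    """Track several ROIs through the loop sharing per-frame pyramids."""
    trackers = {lab: _RoiTracker(cine, rect, lab, settings)
                for lab, rect in rois.items()}
    pyr_prev = _Pyramid(cine.frames[0], settings.pyramid_levels)
    for t in range(1, cine.n_frames):
        pyr_cur = _Pyramid(cine.frames[t], settings.pyramid_levels)
        for tracker in trackers.values():
            tracker.step(pyr_prev, pyr_cur, t)
        pyr_prev = pyr_cur
    return {lab: tr.series for lab, tr in trackers.items()}


def track_roi(cine: CineLoop, roi: RoiRect,
              settings: TrackerSettings = TrackerSettings(),
              roi_label: str = "roi") -> PoseSeries:
    """Track a single ROI through the full cine loop.

    Frame-0 pose equals the annotated pose with theta = 0; the returned
    series has an entry for every frame (no gaps).
    """
    return track_rois(cine, {roi_label: roi}, settings)[roi_label]


def track_annotation(cine: CineLoop, annotation: RoiAnnotation,
                     settings: TrackerSettings = TrackerSettings(),
                     labels: Sequence[str] | None = None) -> dict[str, PoseSeries]:
    """Track the annotated ROIs (all four by default)."""
    annotation.validate_bounds(cine.frame_shape)
    labels = tuple(labels) if labels is not None else tuple(annotation.rois)
    return track_rois(cine, {lab: annotation.rois[lab] for lab in labels}, settings)
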