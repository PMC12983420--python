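"""Tracker contracts: detection, sparse flow, rigid pose, full-loop tracking."""

import numpy as np
import pytest
from scipy import ndimage

import urethrakin as uk
from urethrakin.cine_io import RoiRect
from urethrakin.errors import DegeneratePoseError, LowTextureError, TrackingLossError
from urethrakin.roi_tracking import (
    TrackerSettings,
    detect_features,
    estimate_rigid_pose,
    flow_step,
    track_roi,
    track_rois,
)

from conftest import ROIS


def _procrustes_oracle(ref, cur):
    """Closed-form 2D rigid fit via SVD — independent of the tracker's path."""
    cr, cc = ref.mean(axis=0), cur.mean(axis=0)
    H = (ref - cr).T @ (cur - cc)
    U, _s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, d]) @ U.T
    t = cc - R @ cr
    return R, t


class TestDetectFeatures:
    def test_uniform_roi_has_no_corners(self):
        frame = np.full((100, 100), 0.5)
        with pytest.raises(LowTextureError):
            detect_features(frame, RoiRect(20, 60, 40, 40))

    def test_speckle_roi_yields_enough_points(self, texture, annotation):
        features = detect_features(texture, annotation.rois["proximal"])
        assert len(features.points_px) >= 10
        assert annotation.rois["proximal"].contains(features.points_px).all()

    def test_deterministic(self, texture, annotation):
        a = detect_features(texture, annotation.rois["mid"])
        b = detect_features(texture, annotation.rois["mid"])
        assert np.array_equal(a.points_px, b.points_px)


class TestFlowStep:
    def test_identity_motion(self, texture, annotation):
        pts = detect_features(texture, annotation.rois["proximal"]).points_px
        moved, valid, fb = flow_step(texture, texture, pts)
        assert valid.all()
        assert np.abs(moved - pts).max() < 0.1

    def test_integer_translation_recovered(self, texture, annotation):
        pts = detect_features(texture, annotation.rois["proximal"]).points_px
        shifted = np.roll(texture, 3, axis=1)  # +3 px in x
        moved, valid, _ = flow_step(texture, shifted, pts)
        mean_shift = (moved - pts)[valid].mean(axis=0)
        assert np.abs(mean_shift - [3.0, 0.0]).max() < 0.2

    def test_unrelated_noise_is_untrackable(self, texture, annotation):
        pts = detect_features(texture, annotation.rois["proximal"]).points_px
        noise = np.random.default_rng(0).uniform(0, 1, texture.shape)
        with pytest.raises(TrackingLossError):
            flow_step(texture, noise, pts)


class TestEstimateRigidPose:
    def _points(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        return rng.uniform(0, 40, (n, 2)) + [100, 100]

    def test_identity(self):
        pts = self._points()
        est = estimate_rigid_pose(pts, pts)
        assert (est.tx_px, est.ty_px, est.dtheta_deg) == pytest.approx((0, 0, 0))

    def test_rotation_about_center_plus_translation(self):
        pts = self._points()
        center = np.array([120.0, 120.0])
        th = np.deg2rad(10.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        cur = (pts - center) @ R.T + center + [2.0, -1.0]
        est = estimate_rigid_pose(pts, cur, center=center)
        assert est.tx_px == pytest.approx(2.0, abs=1e-6)
        assert est.ty_px == pytest.approx(-1.0, abs=1e-6)
        assert est.dtheta_deg == pytest.approx(10.0, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_procrustes_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = self._points(40, seed)
        th = rng.uniform(-0.3, 0.3)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        t = rng.uniform(-5, 5, 2)
        cur = pts @ R.T + t
        est = estimate_rigid_pose(pts, cur)
        R_o, t_o = _procrustes_oracle(pts, cur)
        assert np.allclose(est.rotation, R_o, atol=1e-9)
        assert np.allclose(est.translation, t_o, atol=1e-6)
        assert est.rms_px < 1e-9

    def test_robust_to_gross_outliers(self):
        pts = self._points(30, 3)
        cur = pts + [2.0, -1.0]
        bad = np.arange(6)  # 20 % corrupted
        cur[bad] += 50.0
        est = estimate_rigid_pose(pts, cur)
        assert not est.inliers[bad].any()
        assert est.tx_px == pytest.approx(2.0, abs=0.1)
        assert est.ty_px == pytest.approx(-1.0, abs=0.1)
        assert est.dtheta_deg == pytest.approx(0.0, abs=0.1)

    def test_too_few_valid_points(self):
        pts = self._points(8)
        with pytest.raises(DegeneratePoseError):
            estimate_rigid_pose(pts, pts)


class TestTrackRoi:
    def test_static_cine_yields_constant_pose(self, static_cine, annotation):
        cine, _ = static_cine
        for roi in ("pubis",) + ROIS:
            series = track_roi(cine, annotation.rois[roi], roi_label=roi)
            origin = annotation.rois[roi].origin
            assert np.abs(series.origin_px - origin).max() < 0.2
            assert np.abs(series.theta_deg).max() < 0.2

    def test_tracks_known_trajectory_within_contract(self, cough_scene,
                                                     cough_poses):
        """Accuracy contract vs. ground truth: <= 0.5 px and <= 1.0 deg RMS."""
        _cine, gt, _ = cough_scene
        for roi in ROIS:
            truth = gt.image_pose(roi)
            pos_err = np.linalg.norm(cough_poses[roi].origin_px - truth[:, :2],
                                     axis=1)
            ang_err = cough_poses[roi].theta_deg - truth[:, 2]
            assert np.sqrt((pos_err ** 2).mean()) <= 0.5
            assert np.sqrt((ang_err ** 2).mean()) <= 1.0

    def test_frame0_pose_matches_annotation(self, cough_poses, annotation):
        for roi in ("pubis",) + ROIS:
            assert np.allclose(cough_poses[roi].origin_px[0],
                               annotation.rois[roi].origin)
            assert cough_poses[roi].theta_deg[0] == 0.0

    def test_integer_translation_equivariance(self, texture, annotation):
        frames = np.stack([np.roll(texture, (2 * k, k), axis=(1, 0))
                           for k in range(4)])
        cine = uk.CineLoop(frames, 30.0, 0.2)
        series = track_roi(cine, annotation.rois["mid"], roi_label="mid")
        expected = annotation.rois["mid"].origin + np.outer(np.arange(4), [2.0, 1.0])
        assert np.abs(series.origin_px - expected).max() < 0.2

    @pytest.mark.parametrize("alpha", [5.0, 15.0])
    def test_rigid_rotation_recovered(self, texture, annotation, alpha):
        """A cine rotated rigidly by alpha about a fixed point yields
        dtheta = alpha within 0.5 deg (alpha reached over a few frames, as
        in a real loop)."""
        rect = annotation.rois["mid"]
        center = rect.origin + [rect.width_px / 2, -rect.height_px / 2]
        rows, cols = np.mgrid[0:384, 0:384].astype(float)
        frames = []
        for th_deg in np.linspace(0.0, alpha, 4):
            th = np.deg2rad(th_deg)
            # inverse map for a rotation by +theta (raster) about center
            qx = (np.cos(th) * (cols - center[0])
                  + np.sin(th) * (rows - center[1]) + center[0])
            qy = (-np.sin(th) * (cols - center[0])
                  + np.cos(th) * (rows - center[1]) + center[1])
            frames.append(ndimage.map_coordinates(texture, [qy, qx], order=3,
                                                  mode="mirror"))
        cine = uk.CineLoop(np.stack(frames), 30.0, 0.2)
        series = track_roi(cine, rect, roi_label="mid")
        assert series.theta_deg[-1] == pytest.approx(alpha, abs=0.5)

    def test_roi_leaving_frame_raises_with_context(self, texture):
        frames = np.stack([np.roll(texture, 12 * k, axis=1) for k in range(12)])
        cine = uk.CineLoop(frames, 30.0, 0.2)
        rect = RoiRect(320.0, 200.0, 40.0, 40.0)  # near the right edge
        with pytest.raises(TrackingLossError, match="edge_roi"):
            track_roi(cine, rect, roi_label="edge_roi")

    def test_shared_pyramid_matches_individual_tracking(self, static_cine,
                                                        annotation):
        cine, _ = static_cine
        multi = track_rois(cine, {r: annotation.rois[r] for r in ("mid", "pubis")})
        single = track_roi(cine, annotation.rois["mid"], roi_label="mid")
        assert np.allclose(multi["mid"].origin_px, single.origin_px)
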