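"""Simulator contracts: determinism, waveform shapes, render geometry."""

import numpy as np
import pytest

import urethrakin as uk
from urethrakin.errors import ArgumentError
from urethrakin.roi_tracking import TrackerSettings, detect_features
from urethrakin.cine_io import RoiRect

from conftest import COUGH_AMPS, ROIS, ROTS, probe_series


class TestSpeckleField:
    def test_deterministic_and_seed_sensitive(self):
        a = uk.generate_speckle_field(256, 256, 3, seed=7)
        b = uk.generate_speckle_field(256, 256, 3, seed=7)
        c = uk.generate_speckle_field(256, 256, 3, seed=8)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        assert a.min() >= 0.0 and a.max() <= 1.0

    def test_corner_density_supports_tracking(self):
        """Any 40x40 window must offer >= 50 corners to the module's detector."""
        tex = uk.generate_speckle_field(256, 256, 3, seed=7)
        settings = TrackerSettings(max_corners=500, detect_margin_px=0.0)
        window = RoiRect(108.0, 148.0, 40.0, 40.0)  # central 40x40
        features = detect_features(tex, window, settings)
        assert len(features.points_px) >= 50

    @pytest.mark.parametrize("shape", [(32, 256), (256, 32)])
    def test_rejects_tiny_dimensions(self, shape):
        with pytest.raises(ArgumentError):
            uk.generate_speckle_field(*shape, 3, seed=0)


class TestManeuverTrajectories:
    def test_zero_amplitudes_give_null_motion(self):
        template = uk.template_for("cough", {r: (0.0, 0.0) for r in ROIS},
                                   prelift_mm=0.0)
        for roi in ROIS:
            assert np.all(uk.maneuver_trajectory(template, roi) == 0.0)

    def test_cough_peak_magnitude_and_timing(self):
        template = uk.template_for("cough", {"proximal": (2.0, -6.0)})
        traj = uk.maneuver_trajectory(template, "proximal")
        dmag = np.hypot(traj[:, 0], traj[:, 1])
        expected = np.hypot(2.0, 6.0)  # 6.324...
        assert abs(dmag.max() - expected) <= 0.01 * expected
        peak_t = template.times_s[int(np.argmax(dmag))]
        assert template.onset_s <= peak_t <= template.onset_s + 1.5 * template.rise_s
        # spike-and-rebound: back at rest by the final frame
        assert dmag[-1] <= 0.02 * expected
        assert np.all(traj[0] == 0.0)

    def test_cough_prelift_is_superior_before_main_descent(self):
        template = uk.template_for("cough", {"proximal": (0.0, -6.0)})
        traj = uk.maneuver_trajectory(template, "proximal")
        onset_idx = int(template.onset_s * template.frame_rate_hz)
        assert traj[:onset_idx, 1].max() > 0.2  # anticipatory upward bump
        assert traj[:, 1].min() < -5.0          # then the main inferior spike

    def test_valsalva_sustains_a_plateau(self):
        template = uk.template_for("valsalva", {"proximal": (3.0, -9.0)})
        traj = uk.maneuver_trajectory(template, "proximal")
        dmag = np.hypot(traj[:, 0], traj[:, 1])
        frac_above_half = np.mean(dmag >= 0.5 * dmag.max())
        assert frac_above_half >= 0.25

    def test_pmc_x_reversal_crosses_zero_once(self):
        template = uk.template_for("pmc", {"proximal": (-1.5, 3.5)})
        traj = uk.maneuver_trajectory(template, "proximal")
        dx = traj[:, 0][traj[:, 0] != 0.0]
        signs = np.sign(dx)
        assert signs[0] > 0 and signs[-1] < 0
        assert int(np.sum(np.diff(signs) != 0)) == 1
        dmag_end = np.hypot(traj[-1, 0], traj[-1, 1])
        assert dmag_end <= 0.02 * np.hypot(1.5, 3.5)

    @pytest.mark.parametrize("scale", [0.5, 2.0, 3.0])
    def test_amplitude_linearity(self, scale):
        base = uk.template_for("valsalva", {"proximal": (2.0, -5.0)})
        scaled = uk.template_for("valsalva", {"proximal": (2.0 * scale, -5.0 * scale)})
        a = uk.maneuver_trajectory(base, "proximal")
        b = uk.maneuver_trajectory(scaled, "proximal")
        assert np.allclose(b[:, :2], scale * a[:, :2])

    def test_frame_count_and_bad_inputs(self):
        template = uk.template_for("cough", {}, duration_s=1.5, frame_rate_hz=30)
        assert uk.maneuver_trajectory(template, "mid").shape == (45, 3)
        with pytest.raises(ArgumentError):
            uk.maneuver_trajectory(template, "urethra")
        with pytest.raises(ArgumentError):
            uk.template_for("cough", {}, duration_s=-1.0)
        with pytest.raises(ArgumentError):
            uk.template_for("jump", {})


class TestRenderCine:
    def test_static_scene_is_constant(self, static_cine):
        cine, _gt = static_cine
        assert np.array_equal(cine.frames, np.broadcast_to(
            cine.frames[0], cine.frames.shape))

    def test_probe_motion_absent_from_ground_truth(self, texture, annotation):
        """The probe confounder lives in image space only."""
        T = 20
        trajs = {roi: np.zeros((T, 3)) for roi in ROIS}
        probe = np.zeros((T, 3))
        probe[:, 0] = 5.0
        probe[0] = 0.0
        _cine, gt = uk.render_cine(texture, annotation, trajs, probe, noise_sd=0.0)
        for roi in ROIS:
            assert np.allclose(gt.displacement_mm(roi), 0.0)
        # ...but it does move the scene
        assert np.any(gt.image_pose("proximal")[1] != gt.image_pose("proximal")[0])

    def test_render_deterministic(self, texture, annotation):
        template = uk.template_for("cough", COUGH_AMPS, ROTS)
        trajs = {roi: uk.maneuver_trajectory(template, roi) for roi in ROIS}
        probe = probe_series(template.times_s)
        a, _ = uk.render_cine(texture, annotation, trajs, probe, 0.02, seed=5)
        b, _ = uk.render_cine(texture, annotation, trajs, probe, 0.02, seed=5)
        assert np.array_equal(a.frames, b.frames)

    def test_roi_leaving_frame_is_reported(self, texture, annotation):
        T = 10
        trajs = {roi: np.zeros((T, 3)) for roi in ROIS}
        trajs["distal"][:, 1] = np.linspace(0, -40, T)  # 200 px inferior
        with pytest.raises(ArgumentError, match="distal.*frame [0-9]"):
            uk.render_cine(texture, annotation, trajs, None, noise_sd=0.0)

    def test_ground_truth_starts_at_annotated_rest(self, cough_scene, annotation):
        _cine, gt, _ = cough_scene
        ipp = np.asarray(annotation.ipp_px)
        for roi in ROIS:
            origin = annotation.rois[roi].origin
            rest_x = (origin[0] - ipp[0]) * gt.pixel_spacing_mm
            rest_y = -(origin[1] - ipp[1]) * gt.pixel_spacing_mm
            assert np.allclose(gt.positions_mm[roi][0], [rest_x, rest_y])


class TestMakeCohort:
    def test_degenerate_sd_gives_identical_amplitudes(self):
        params = {(g, "cough", r): (4.0, 0.0, -80.0)
                  for g in ("control", "sui") for r in ROIS}
        spec = uk.CohortSpec(n_control=2, n_sui=2, seed=0, maneuvers=("cough",),
                             amplitude_params=params,
                             template_overrides={"cough": {"duration_s": 0.2}})
        subjects = uk.make_cohort(spec)
        mags = [s.amplitudes_mm["proximal"] for s in subjects]
        assert np.allclose(mags, 4.0)

    def test_seed_sensitivity_and_determinism(self):
        kwargs = dict(n_control=2, n_sui=2, maneuvers=("cough",),
                      template_overrides={"cough": {"duration_s": 0.2}})
        a = uk.make_cohort(uk.CohortSpec(seed=1, **kwargs))
        b = uk.make_cohort(uk.CohortSpec(seed=1, **kwargs))
        c = uk.make_cohort(uk.CohortSpec(seed=2, **kwargs))
        for x, y in zip(a, b):
            assert np.array_equal(x.cine.frames, y.cine.frames)
            assert x.amplitudes_mm == y.amplitudes_mm
        assert any(x.amplitudes_mm != z.amplitudes_mm for x, z in zip(a, c))

    def test_group_sizes_validated(self):
        with pytest.raises(ArgumentError):
            uk.CohortSpec(n_control=1, n_sui=5)
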