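"""Shared fixtures: one rendered synthetic scene reused across the suite.

Rendering and tracking are the expensive stages, so the canonical cough cine
(with probe motion and sensor noise at default levels) and its tracked poses
are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

import urethrakin as uk
from urethrakin.roi_tracking import TrackerSettings, track_rois

ROIS = ("proximal", "mid", "distal")
COUGH_AMPS = {"proximal": (2.0, -6.0), "mid": (1.0, -4.0), "distal": (0.5, -3.0)}
ROTS = {"proximal": 3.0, "mid": 2.0, "distal": 1.0}


def probe_series(times_s: np.ndarray, amp_px: float = 3.0,
                 rot_deg: float = 1.0) -> np.ndarray:
    """Smooth sinusoidal probe motion, zero at frame 0."""
    w = 2 * np.pi * 0.7
    ramp = np.clip(times_s / 0.3, 0, 1) ** 2
    probe = np.column_stack([
        amp_px * np.sin(w * times_s) * ramp,
        0.7 * amp_px * np.sin(w * times_s + 1.0) * ramp,
        rot_deg * np.sin(w * times_s + 2.0) * ramp,
    ])
    probe[0] = 0.0
    return probe


@pytest.fixture(scope="session")
def texture():
    return uk.generate_speckle_field(384, 384, 3.0, seed=7)


@pytest.fixture(scope="session")
def annotation():
    return uk.default_annotation()


@pytest.fixture(scope="session")
def cough_scene(texture, annotation):
    """Cough cine with probe motion + noise, plus its ground truth."""
    template = uk.template_for("cough", COUGH_AMPS, ROTS)
    trajs = {roi: uk.maneuver_trajectory(template, roi) for roi in ROIS}
    probe = probe_series(template.times_s)
    cine, gt = uk.render_cine(texture, annotation, trajs, probe,
                              noise_sd=0.02, seed=3)
    return cine, gt, trajs


@pytest.fixture(scope="session")
def cough_poses(cough_scene, annotation):
    cine, _gt, _trajs = cough_scene
    labels = ("pubis",) + ROIS
    return track_rois(cine, {lab: annotation.rois[lab] for lab in labels},
                      TrackerSettings())


@pytest.fixture(scope="session")
def probe_invariance_pelvic(texture, annotation):
    """Pelvic-frame trajectories of the same scene with probe motion on/off."""
    from urethrakin.pelvic_frame import construct_frame, to_pelvic

    template = uk.template_for("cough", COUGH_AMPS, ROTS)
    trajs = {roi: uk.maneuver_trajectory(template, roi) for roi in ROIS}
    probe = probe_series(template.times_s)
    labels = ("pubis",) + ROIS
    rects = {lab: annotation.rois[lab] for lab in labels}
    results = {}
    for name, pm in (("off", None), ("on", probe)):
        cine, _gt = uk.render_cine(texture, annotation, trajs, pm,
                                   noise_sd=0.02, seed=3)
        poses = track_rois(cine, rects, TrackerSettings())
        frame = construct_frame(poses["pubis"], annotation,
                                cine.pixel_spacing_mm)
        results[name] = {roi: to_pelvic(poses[roi], frame)[:, :2]
                         for roi in ROIS}
    return results


@pytest.fixture(scope="session")
def static_cine(texture, annotation):
    """No motion, no probe, no noise: every frame equals frame 0."""
    template = uk.template_for("cough", {roi: (0.0, 0.0) for roi in ROIS},
                               prelift_mm=0.0, duration_s=0.5)
    trajs = {roi: uk.maneuver_trajectory(template, roi) for roi in ROIS}
    cine, gt = uk.render_cine(texture, annotation, trajs, None, noise_sd=0.0)
    return cine, gt
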