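"""Synthetic speckle cine loops with known ground-truth urethral motion.

The generator emulates what the tracker sees in a mid-sagittal
transperineal-ultrasound cine: a speckled B-mode-like texture, three
urethral regions of interest (proximal / mid / distal) that move rigidly
with maneuver-specific waveforms, a trackable pubis, superimposed global
probe motion, and additive sensor noise.  Every loop comes with an exact
:class:`GroundTruth` — per-frame pelvic-frame positions and orientations
free of probe motion — so tracking accuracy and the probe-motion correction
can be verified quantitatively.

Maneuver waveforms (displacement envelopes, all starting from rest):

* ``cough`` — a raised-cosine spike-and-rebound (fast rise, slower rebound),
  optionally preceded by a small superior "pre-lift" bump emulating the
  anticipatory pelvic-floor contraction.
* ``valsalva`` — a smoothstep ramp to a sustained plateau followed by a slow
  release, emulating creep under prolonged straining.
* ``pmc`` — a superior lift with a characteristic anterior-posterior
  signature: a small posterior (+x) pulse first, then a reversal into a
  sustained anterior (-x) drift.

Amplitudes are specified per ROI in mm in the pelvic frame (+x posterior,
+y superior); rotations in degrees (positive = posterior-to-superior sweep).
Cohort generation draws per-subject amplitudes from group-level normal
distributions truncated at zero, calibrated by default to the reference
cohort statistics in :mod:`urethrakin.reference_cohort`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .cine_io import (
    ROI_LABELS,
    URETHRAL_LABELS,
    CineLoop,
    RoiAnnotation,
    RoiRect,
)
from .errors import ArgumentError
from . import reference_cohort as ref

DEFAULT_FRAME_SHAPE = (384, 384)
DEFAULT_PIXEL_SPACING_MM = 0.2
DEFAULT_FRAME_RATE_HZ = 30.0
DEFAULT_NOISE_SD = 0.02
DEFAULT_GRAIN_SCALE_PX = 3.0
BLEND_MARGIN_PX = 8.0

_REST_TOL_FRAC = 0.02  # cough/pmc must end within 2% of amplitude from rest


# ---------------------------------------------------------------------------
# waveform primitives
# ---------------------------------------------------------------------------

def _smoothstep(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    u = np.clip((t - t0) / max(t1 - t0, 1e-12), 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _bump(t: np.ndarray, center: float, halfwidth: float) -> np.ndarray:
    """Raised-cosine bump, 1 at `center`, 0 outside +/- halfwidth."""
    u = (t - center) / max(halfwidth, 1e-12)
    out = 0.5 * (1.0 + np.cos(np.pi * np.clip(u, -1.0, 1.0)))
    return np.where(np.abs(u) < 1.0, out, 0.0)


@dataclass(frozen=True)
class MotionTemplate:
    """Per-maneuver motion prescription for the three urethral ROIs.

    ``amplitudes_mm`` maps ROI label -> (dx_mm, dy_mm) peak displacement in
    the pelvic frame; ``rotation_deg`` maps ROI label -> peak rotation.
    Timing parameters are in seconds; their defaults depend on the maneuver
    (see :func:`template_for`).
    """

    maneuver: str
    duration_s: float
    frame_rate_hz: float
    amplitudes_mm: Mapping[str, tuple[float, float]]
    rotation_deg: Mapping[str, float] = field(default_factory=dict)
    onset_s: float = 0.3
    rise_s: float = 0.15
    hold_s: float = 0.0
    rebound_s: float = 0.35
    prelift_mm: float = 0.0
    prelift_lead_s: float = 0.2
    pmc_reversal_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.maneuver not in ("cough", "valsalva", "pmc"):
            raise ArgumentError(f"unknown maneuver '{self.maneuver}'")
        if not (self.duration_s > 0):
            raise ArgumentError("duration_s must be > 0")
        if not (self.frame_rate_hz > 0):
            raise ArgumentError("frame_rate_hz must be > 0")
        for name in ("onset_s", "rise_s", "hold_s", "rebound_s", "prelift_lead_s"):
            if getattr(self, name) < 0:
                raise ArgumentError(f"{name} must be >= 0")
        for lab in self.amplitudes_mm:
            if lab not in URETHRAL_LABELS:
                raise ArgumentError(f"unknown ROI label '{lab}' in amplitudes_mm")
        object.__setattr__(self, "amplitudes_mm", dict(self.amplitudes_mm))
        object.__setattr__(self, "rotation_deg", dict(self.rotation_deg))

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


_TEMPLATE_DEFAULTS = {
    # onset, rise, hold, rebound, duration
    "cough": dict(onset_s=0.5, rise_s=0.15, hold_s=0.0, rebound_s=0.35,
                  duration_s=1.5, prelift_mm=0.5, prelift_lead_s=0.2),
    "valsalva": dict(onset_s=0.2, rise_s=1.5, hold_s=2.0, rebound_s=1.0,
                     duration_s=5.0),
    "pmc": dict(onset_s=0.2, rise_s=0.5, hold_s=1.3, rebound_s=0.8,
                duration_s=3.0, pmc_reversal_mm=0.5),
}


def template_for(maneuver: str,
                 amplitudes_mm: Mapping[str, tuple[float, float]],
                 rotation_deg: Mapping[str, float] | None = None,
                 frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
                 **overrides) -> MotionTemplate:
    """Build a :class:`MotionTemplate` with maneuver-appropriate timing defaults."""
    if maneuver not in _TEMPLATE_DEFAULTS:
        raise ArgumentError(f"unknown maneuver '{maneuver}'")
    kwargs = dict(_TEMPLATE_DEFAULTS[maneuver])
    kwargs.update(overrides)
    return MotionTemplate(maneuver=maneuver, frame_rate_hz=frame_rate_hz,
                          amplitudes_mm=amplitudes_mm,
                          rotation_deg=rotation_deg or {}, **kwargs)


def _envelope_main(template: MotionTemplate, t: np.ndarray) -> np.ndarray:
    """Unit displacement envelope shared by dx, dy and rotation."""
    t0, rise, hold, reb = (template.onset_s, template.rise_s,
                           template.hold_s, template.rebound_s)
    if template.maneuver == "cough":
        up = _bump(t, t0 + rise, rise)
        down = _bump(t, t0 + rise, reb)
        return np.where(t <= t0 + rise, up, down)
    # valsalva and pmc main component: ramp + hold + release
    env = _smoothstep(t, t0, t0 + rise)
    env = env * (1.0 - _smoothstep(t, t0 + rise + hold, t0 + rise + hold + reb))
    return env


def maneuver_trajectory(template: MotionTemplate, roi_label: str) -> np.ndarray:
    """Per-frame ``(dx_mm, dy_mm, dtheta_deg)`` series for one urethral ROI.

    Frame 0 is exactly at rest; cough and PMC return to within 2 % of the
    amplitude of rest by the final frame; the peak displacement magnitude
    equals the template's amplitude vector magnitude to within 1 %.
    """
    if roi_label not in URETHRAL_LABELS:
        raise ArgumentError(f"unknown roi_label '{roi_label}'")
    t = template.times_s
    ax, ay = template.amplitudes_mm.get(roi_label, (0.0, 0.0))
    rot = template.rotation_deg.get(roi_label, 0.0)
    env = _envelope_main(template, t)
    dx = ax * env
    dy = ay * env
    dtheta = rot * env

    if template.maneuver == "cough" and template.prelift_mm != 0.0:
        lead = template.prelift_lead_s
        dy = dy + template.prelift_mm * _bump(t, template.onset_s - lead, lead)
    if template.maneuver == "pmc" and template.pmc_reversal_mm != 0.0:
        # posterior pulse then reversal: the -x drift follows a delayed envelope
        t0, rise, hold, reb = (template.onset_s, template.rise_s,
                               template.hold_s, template.rebound_s)
        pulse_hw = rise * 0.7
        pulse = _bump(t, t0 + 0.5 * rise, pulse_hw)
        delay = 0.5 * rise
        drift = _smoothstep(t, t0 + rise, t0 + rise + rise + delay)
        drift = drift * (1.0 - _smoothstep(t, t0 + rise + hold + delay,
                                           template.duration_s))
        dx = template.pmc_reversal_mm * pulse + ax * drift
    out = np.column_stack([dx, dy, dtheta])
    out[0] = 0.0  # exact rest at frame 0 (envelopes are 0 there anyway)
    return out


# ---------------------------------------------------------------------------
# speckle texture and default scene layout
# ---------------------------------------------------------------------------

def generate_speckle_field(height_px: int, width_px: int,
                           grain_scale_px: float = DEFAULT_GRAIN_SCALE_PX,
                           seed: int = 0) -> np.ndarray:
    """Deterministic speckle-like texture in [0, 1].

    Low-pass-filtered white noise with autocorrelation length of roughly
    ``grain_scale_px`` — corner-rich enough that the tracker finds dozens of
    features in any 40x40 px window.
    """
    if height_px < 64 or width_px < 64:
        raise ArgumentError("texture dimensions must be >= 64 px")
    if grain_scale_px < 1:
        raise ArgumentError("grain_scale_px must be >= 1")
    rng = np.random.default_rng(seed)
    shape = (int(height_px), int(width_px))
    # a Gaussian blur of sigma s yields an autocorrelation length of ~3 s
    fine = ndimage.gaussian_filter(rng.standard_normal(shape),
                                   sigma=grain_scale_px / 3.0)
    # coarse tissue-like intensity variation: real B-mode has anatomy behind
    # the speckle, and coarse structure is what pyramidal tracking locks onto
    # for motions larger than the speckle grain
    coarse = ndimage.gaussian_filter(rng.standard_normal(shape),
                                     sigma=max(3.0 * grain_scale_px, 6.0))
    img = fine / fine.std() + 0.6 * coarse / coarse.std()
    img -= img.min()
    peak = img.max()
    return (img / peak if peak > 0 else img).astype(np.float64)


_BASE_LAYOUT = {
    # base geometry on a 384 x 384 frame; scaled to the requested shape.
    # Urethral ROIs are spaced 75 px (15 mm at 0.2 mm/px) apart so that even
    # large differential segment displacements keep the patches disjoint.
    "ipp": (150.0, 150.0),
    "tangent": (190.0, 150.0),
    "pubis": (105.0, 175.0, 60.0, 50.0),
    "proximal": (210.0, 150.0, 40.0, 40.0),
    "mid": (205.0, 225.0, 40.0, 40.0),
    "distal": (200.0, 300.0, 40.0, 40.0),
}


def default_annotation(frame_shape: tuple[int, int] = DEFAULT_FRAME_SHAPE) -> RoiAnnotation:
    """Canonical synthetic-scene annotation: pubis anterior, urethra posterior
    running superior (proximal) to inferior (distal), tangent pointing posteriorly."""
    sy = frame_shape[0] / 384.0
    sx = frame_shape[1] / 384.0
    rois = {}
    for lab in ROI_LABELS:
        x, y, w, h = _BASE_LAYOUT[lab]
        rois[lab] = RoiRect(x * sx, y * sy, w * sx, h * sy)
    ipp = (_BASE_LAYOUT["ipp"][0] * sx, _BASE_LAYOUT["ipp"][1] * sy)
    tan = (_BASE_LAYOUT["tangent"][0] * sx, _BASE_LAYOUT["tangent"][1] * sy)
    return RoiAnnotation(rois, ipp, tan)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _anatomical_axes(annotation: RoiAnnotation) -> tuple[np.ndarray, np.ndarray]:
    ipp = np.asarray(annotation.ipp_px, dtype=float)
    tan = np.asarray(annotation.tangent_px, dtype=float)
    xhat = tan - ipp
    xhat = xhat / np.linalg.norm(xhat)
    yhat = np.array([xhat[1], -xhat[0]])  # +90 deg toward superior (up in raster)
    return xhat, yhat


def _rot2(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class GroundTruth:
    """Exact probe-motion-free trajectories for a rendered cine.

    ``positions_mm[roi]`` is the (T, 2) absolute pelvic-frame position of the
    ROI origin; ``theta_deg[roi]`` its orientation relative to rest.  The
    probe confounder lives only in image space and is recorded separately.
    """

    positions_mm: Mapping[str, np.ndarray]
    theta_deg: Mapping[str, np.ndarray]
    probe_motion_px: np.ndarray
    pixel_spacing_mm: float
    frame_rate_hz: float
    annotation: RoiAnnotation

    @property
    def n_frames(self) -> int:
        return int(self.probe_motion_px.shape[0])

    def displacement_mm(self, roi: str) -> np.ndarray:
        pos = self.positions_mm[roi]
        return pos - pos[0]

    def image_pose(self, roi: str) -> np.ndarray:
        """(T, 3) image-space origin position (px) and orientation (deg),
        i.e. the motion the tracker should recover *including* probe motion."""
        ann = self.annotation
        xhat, yhat = _anatomical_axes(ann)
        origin = ann.rois[roi].origin
        disp = self.displacement_mm(roi)
        d_img = (np.outer(disp[:, 0], xhat) + np.outer(disp[:, 1], yhat)) \
            / self.pixel_spacing_mm
        pts = origin[None, :] + d_img
        out = np.empty((self.n_frames, 3))
        ctr = self._image_center
        for tview in range(self.n_frames):
            tx, ty, rot = self.probe_motion_px[tview]
            R = _rot2(np.deg2rad(rot))
            out[tview, :2] = R @ (pts[tview] - ctr) + ctr + np.array([tx, ty])
            out[tview, 2] = -self.theta_deg[roi][tview] + rot
        return out

    @property
    def _image_center(self) -> np.ndarray:
        # rendering rotates probe motion about the annotated IPP's frame center
        return np.asarray(self._center)

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions_mm",
                           {k: np.asarray(v, float) for k, v in self.positions_mm.items()})
        object.__setattr__(self, "theta_deg",
                           {k: np.asarray(v, float) for k, v in self.theta_deg.items()})
        object.__setattr__(self, "probe_motion_px",
                           np.asarray(self.probe_motion_px, float))


def render_cine(texture: np.ndarray,
                annotation: RoiAnnotation,
                trajectories: Mapping[str, np.ndarray],
                probe_motion: np.ndarray | None = None,
                noise_sd: float = DEFAULT_NOISE_SD,
                seed: int = 0,
                pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM,
                frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
                ) -> tuple[CineLoop, GroundTruth]:
    """Render a cine in which each urethral ROI patch moves rigidly along its
    trajectory (composed with global probe motion) over a probe-moving
    background; the pubis moves with the probe only.

    ``trajectories`` maps each urethral ROI label to a (T, 3) array of
    (dx_mm, dy_mm, dtheta_deg) pelvic-frame displacements; ``probe_motion``
    is a (T, 3) array of (tx_px, ty_px, rot_deg) global rigid motion, or None.
    """
    texture = np.asarray(texture, dtype=np.float64)
    H, W = texture.shape
    annotation.validate_bounds((H, W))
    missing = [lab for lab in URETHRAL_LABELS if lab not in trajectories]
    if missing:
        raise ArgumentError(f"trajectories missing ROI(s): {', '.join(missing)}")
    trajs = {lab: np.asarray(trajectories[lab], dtype=float)
             for lab in URETHRAL_LABELS}
    T = next(iter(trajs.values())).shape[0]
    for lab, tr in trajs.items():
        if tr.shape != (T, 3):
            raise ArgumentError(f"trajectory for '{lab}' must be (T, 3), got {tr.shape}")
    if probe_motion is None:
        probe = np.zeros((T, 3))
    else:
        probe = np.asarray(probe_motion, dtype=float)
        if probe.shape != (T, 3):
            raise ArgumentError(f"probe_motion must be (T, 3), got {probe.shape}")

    xhat, yhat = _anatomical_axes(annotation)
    ctr = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
    margin = BLEND_MARGIN_PX
    coeffs = ndimage.spline_filter(texture, order=3, mode="mirror")
    rows, cols = np.mgrid[0:H, 0:W].astype(float)

    frames = np.empty((T, H, W), dtype=np.float32)
    static_probe = not np.any(probe)
    for t in range(T):
        tx, ty, rot = probe[t]
        Rp = _rot2(np.deg2rad(rot))
        RpT = Rp.T
        if static_probe or (tx == 0 and ty == 0 and rot == 0):
            bg = texture.copy()
        else:
            # inverse probe map applied to the output grid
            qx = RpT[0, 0] * (cols - ctr[0] - tx) + RpT[0, 1] * (rows - ctr[1] - ty) + ctr[0]
            qy = RpT[1, 0] * (cols - ctr[0] - tx) + RpT[1, 1] * (rows - ctr[1] - ty) + ctr[1]
            bg = ndimage.map_coordinates(coeffs, [qy, qx], order=3,
                                         prefilter=False, mode="mirror")
        for lab in URETHRAL_LABELS:
            rect = annotation.rois[lab]
            o = rect.origin
            dx_mm, dy_mm, dth = trajs[lab][t]
            d_img = (dx_mm * xhat + dy_mm * yhat) / pixel_spacing_mm
            Rm = _rot2(np.deg2rad(-dth))
            # forward map: y = Rp((Rm(q - o) + o + d_img) - ctr) + ctr + tp
            ext = np.array([[rect.x_px - margin, rect.y_px + margin],
                            [rect.x_px + rect.width_px + margin, rect.y_px + margin],
                            [rect.x_px + rect.width_px + margin, rect.y_px - rect.height_px - margin],
                            [rect.x_px - margin, rect.y_px - rect.height_px - margin]])
            moved_core = (rect.corners - o) @ Rm.T + o + d_img
            moved_core = (moved_core - ctr) @ Rp.T + ctr + np.array([tx, ty])
            if (moved_core[:, 0].min() < 0 or moved_core[:, 1].min() < 0
                    or moved_core[:, 0].max() > W - 1 or moved_core[:, 1].max() > H - 1):
                raise ArgumentError(f"ROI '{lab}' exits frame bounds at frame {t}")
            moved_ext = (ext - o) @ Rm.T + o + d_img
            moved_ext = (moved_ext - ctr) @ Rp.T + ctr + np.array([tx, ty])
            c0 = max(int(np.floor(moved_ext[:, 0].min())) - 1, 0)
            c1 = min(int(np.ceil(moved_ext[:, 0].max())) + 2, W)
            r0 = max(int(np.floor(moved_ext[:, 1].min())) - 1, 0)
            r1 = min(int(np.ceil(moved_ext[:, 1].max())) + 2, H)
            sub_c = cols[r0:r1, c0:c1]
            sub_r = rows[r0:r1, c0:c1]
            # invert probe, then the ROI motion, to find the rest-frame source
            px = RpT[0, 0] * (sub_c - ctr[0] - tx) + RpT[0, 1] * (sub_r - ctr[1] - ty) + ctr[0]
            py = RpT[1, 0] * (sub_c - ctr[0] - tx) + RpT[1, 1] * (sub_r - ctr[1] - ty) + ctr[1]
            RmT = Rm.T
            qx = RmT[0, 0] * (px - o[0] - d_img[0]) + RmT[0, 1] * (py - o[1] - d_img[1]) + o[0]
            qy = RmT[1, 0] * (px - o[0] - d_img[0]) + RmT[1, 1] * (py - o[1] - d_img[1]) + o[1]
            patch = ndimage.map_coordinates(coeffs, [qy, qx], order=3,
                                            prefilter=False, mode="mirror")
            # cosine taper on the Chebyshev distance outside the rest rectangle
            d_out_x = np.maximum(np.maximum(rect.x_px - qx,
                                            qx - (rect.x_px + rect.width_px)), 0.0)
            d_out_y = np.maximum(np.maximum((rect.y_px - rect.height_px) - qy,
                                            qy - rect.y_px), 0.0)
            d_out = np.hypot(d_out_x, d_out_y)
            w = np.where(d_out >= margin, 0.0,
                         0.5 * (1.0 + np.cos(np.pi * d_out / margin)))
            bg[r0:r1, c0:c1] = bg[r0:r1, c0:c1] * (1.0 - w) + patch * w
        frames[t] = bg
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sd, frames.shape).astype(np.float32)
    frames = np.clip(frames, 0.0, 1.0)

    # ground truth in the pelvic frame (probe-free by construction)
    ipp = np.asarray(annotation.ipp_px)
    positions, thetas = {}, {}
    for lab in URETHRAL_LABELS:
        o = annotation.rois[lab].origin
        rest = np.array([np.dot(o - ipp, xhat), np.dot(o - ipp, yhat)]) * pixel_spacing_mm
        positions[lab] = rest[None, :] + trajs[lab][:, :2]
        thetas[lab] = trajs[lab][:, 2].copy()
    o_pub = annotation.rois["pubis"].origin
    rest_pub = np.array([np.dot(o_pub - ipp, xhat),
                         np.dot(o_pub - ipp, yhat)]) * pixel_spacing_mm
    positions["pubis"] = np.tile(rest_pub, (T, 1))
    thetas["pubis"] = np.zeros(T)

    gt = GroundTruth(positions, thetas, probe, pixel_spacing_mm, frame_rate_hz,
                     annotation)
    object.__setattr__(gt, "_center", ctr)
    cine = CineLoop(frames, frame_rate_hz, pixel_spacing_mm, "synthetic")
    return cine, gt


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic two-group cohort.

    ``amplitude_params[(group, maneuver, roi)]`` gives the group-level
    (mean |d| mm, SD mm, direction deg) from which per-subject displacement
    amplitudes are drawn (normal, truncated at zero).  Defaults are
    calibrated to the reference cohort statistics.
    """

    n_control: int = ref.N_CONTROL
    n_sui: int = ref.N_SUI
    seed: int = 0
    maneuvers: Sequence[str] = ref.MANEUVERS
    amplitude_params: Mapping[tuple[str, str, str], tuple[float, float, float]] | None = None
    rotation_deg_per_mm: float = 0.4
    frame_shape: tuple[int, int] = DEFAULT_FRAME_SHAPE
    grain_scale_px: float = DEFAULT_GRAIN_SCALE_PX
    noise_sd: float = DEFAULT_NOISE_SD
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    probe_amp_px: float = 3.0
    probe_rot_deg: float = 1.0
    probe_freq_hz: float = 0.7
    template_overrides: Mapping[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_sui < 2:
            raise ArgumentError("need n >= 2 subjects per group")
        params = self.amplitude_params
        if params is None:
            params = {
                (g, m, r): (ref.MAGNITUDE_MM[(m, r, g)][0],
                            ref.MAGNITUDE_MM[(m, r, g)][1],
                            ref.DIRECTION_DEG[(m, r, g)][0])
                for m in self.maneuvers for r in ref.SEGMENTS for g in ref.GROUPS
            }
        for key, (mu, sd, _phi) in params.items():
            if sd < 0:
                raise ArgumentError(f"negative SD for {key}")
        object.__setattr__(self, "amplitude_params", dict(params))
        object.__setattr__(self, "maneuvers", tuple(self.maneuvers))


@dataclass(frozen=True)
class SyntheticSubject:
    """One rendered subject-maneuver cine with its ground truth."""

    subject_id: str
    group: str
    maneuver: str
    cine: CineLoop
    annotation: RoiAnnotation
    ground_truth: GroundTruth
    amplitudes_mm: Mapping[str, float]


def _draw_magnitudes(rng: np.random.Generator,
                     params: Mapping[str, tuple[float, float, float]]) -> dict[str, float]:
    """Draw one subject-maneuver's per-ROI displacement magnitudes.

    A single standard-normal severity factor is shared along the urethral
    chain (each segment's magnitude = its group mean + z x its group SD,
    truncated at 0): segments of one urethra move coherently, while the
    marginal distribution of each segment still matches the group spec.
    """
    z = rng.standard_normal()
    return {roi: max(mu + z * sd, 0.0) for roi, (mu, sd, _phi) in params.items()}


def make_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Render a full synthetic cohort: one cine per subject per maneuver.

    Deterministic for a fixed ``spec.seed``: subject amplitudes, textures,
    probe-motion phases and sensor noise all derive from it.
    """
    rng = np.random.default_rng(spec.seed)
    annotation = default_annotation(spec.frame_shape)
    out: list[SyntheticSubject] = []
    groups = [("control", spec.n_control), ("sui", spec.n_sui)]
    for group, n in groups:
        for i in range(n):
            sid = f"{group}_{i:02d}"
            texture_seed = int(rng.integers(0, 2**31 - 1))
            noise_seed = int(rng.integers(0, 2**31 - 1))
            phases = rng.uniform(0, 2 * np.pi, size=3)
            texture = generate_speckle_field(*spec.frame_shape,
                                             spec.grain_scale_px, texture_seed)
            for maneuver in spec.maneuvers:
                params = {roi: spec.amplitude_params[(group, maneuver, roi)]
                          for roi in ref.SEGMENTS}
                mags = _draw_magnitudes(rng, params)
                amps: dict[str, tuple[float, float]] = {}
                rots: dict[str, float] = {}
                for roi in ref.SEGMENTS:
                    phi_r = np.deg2rad(params[roi][2])
                    amps[roi] = (mags[roi] * np.cos(phi_r), mags[roi] * np.sin(phi_r))
                    rots[roi] = spec.rotation_deg_per_mm * mags[roi]
                overrides = dict(spec.template_overrides.get(maneuver, {}))
                template = template_for(maneuver, amps, rots,
                                        spec.frame_rate_hz, **overrides)
                trajs = {roi: maneuver_trajectory(template, roi)
                         for roi in ref.SEGMENTS}
                t = template.times_s
                w = 2 * np.pi * spec.probe_freq_hz
                probe = np.column_stack([
                    spec.probe_amp_px * np.sin(w * t + phases[0]) * _smoothstep(t, 0, 0.3),
                    spec.probe_amp_px * np.sin(w * t + phases[1]) * _smoothstep(t, 0, 0.3),
                    spec.probe_rot_deg * np.sin(w * t + phases[2]) * _smoothstep(t, 0, 0.3),
                ])
                probe[0] = 0.0
                cine, gt = render_cine(texture, annotation, trajs, probe,
                                       spec.noise_sd, noise_seed,
                                       spec.pixel_spacing_mm, spec.frame_rate_hz)
                out.append(SyntheticSubject(sid, group, maneuver, cine,
                                            annotation, gt, mags))
    return out
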