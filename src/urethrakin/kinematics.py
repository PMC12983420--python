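"""Segmental kinematic metrics from pelvic-frame pose series.

For each urethral segment the per-frame displacement relative to the rest
frame is reported as components (dx posterior-positive, dy
superior-positive), rotation dtheta, displacement-vector magnitude
``|d| = sqrt(dx^2 + dy^2)`` and direction ``phi = atan2(dy, dx)`` in
degrees on (-180, 180].  Directions computed from sub-resolution motion
(|d| < 0.1 mm) are flagged unreliable and excluded from direction averages.

Chain-level quantities: the signed kink angle between the proximal-to-mid
and mid-to-distal segment vectors (positive = the mid segment is convex
toward anterior), and the relative mobility of adjacent segments — the
difference of their displacement magnitudes normalized by the rest-frame
inter-segment distance along the superior-inferior axis (mm/mm; negative
means the more proximal segment moves more).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ArgumentError, DegenerateGeometryError

PHI_MIN_DISPLACEMENT_MM = 0.1


def _wrap_angle_deg(angle: np.ndarray | float):
    """Wrap to (-180, 180]."""
    wrapped = (np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0
    wrapped = np.where(np.isclose(wrapped, -180.0), 180.0, wrapped)
    return wrapped if wrapped.ndim else float(wrapped)


@dataclass(frozen=True)
class KinematicRecord:
    """Per-frame displacement kinematics for one ROI."""

    roi: str
    dx_mm: np.ndarray
    dy_mm: np.ndarray
    dtheta_deg: np.ndarray
    dmag_mm: np.ndarray
    phi_deg: np.ndarray
    phi_reliable: np.ndarray
    rest_frame: int

    @property
    def n_frames(self) -> int:
        return int(self.dx_mm.shape[0])


def displacement_series(pelvic_pose: np.ndarray, roi: str = "roi",
                        rest_frame: int = 0) -> KinematicRecord:
    """Displacement kinematics of one ROI relative to its rest-frame pose.

    ``pelvic_pose`` is the (T, 3) array of (x_mm, y_mm, theta_deg) from
    :func:`urethrakin.pelvic_frame.to_pelvic`.
    """
    pose = np.atleast_2d(np.asarray(pelvic_pose, dtype=float))
    if pose.size == 0:
        raise ArgumentError("empty pose series")
    if pose.shape[1] != 3:
        raise ArgumentError(f"pelvic pose must be (T, 3), got {pose.shape}")
    if not (0 <= rest_frame < pose.shape[0]):
        raise ArgumentError(f"rest_frame {rest_frame} out of range")
    delta = pose - pose[rest_frame]
    dx, dy, dtheta = delta[:, 0], delta[:, 1], _wrap_angle_deg(delta[:, 2])
    dmag = np.hypot(dx, dy)
    phi = _wrap_angle_deg(np.degrees(np.arctan2(dy, dx)))
    reliable = dmag >= PHI_MIN_DISPLACEMENT_MM
    return KinematicRecord(roi, dx, dy, np.asarray(dtheta), dmag,
                           np.asarray(phi), reliable, rest_frame)


def kink_angle(prox_xy, mid_xy, dist_xy) -> float:
    """Signed kink angle (degrees) of the proximal-mid-distal chain.

    Magnitude: angle between the (mid - prox) and (dist - mid) vectors.
    Sign: the 2D cross product of those vectors — positive when the chain
    bends so the mid segment is convex toward anterior.  Zero for collinear
    origins; invariant under global rotation/translation; the sign flips
    under mirror reflection.
    """
    p = np.asarray(prox_xy, dtype=float)
    m = np.asarray(mid_xy, dtype=float)
    d = np.asarray(dist_xy, dtype=float)
    u = m - p
    v = d - m
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise DegenerateGeometryError("adjacent segment origins coincide")
    cross = u[0] * v[1] - u[1] * v[0]
    dot = u[0] * v[0] + u[1] * v[1]
    return float(_wrap_angle_deg(np.degrees(np.arctan2(cross, dot))))


def relative_mobility(dmag_upper_mm: float, dmag_lower_mm: float,
                      rest_distance_y_mm: float) -> float:
    """Relative mobility of an adjacent segment pair, in mm/mm.

    ``(lower - upper) / rest_distance_y``: negative values mean the more
    proximal (upper) segment moves more.  The normalizing distance is the
    rest-frame separation along the superior-inferior axis.
    """
    if not (rest_distance_y_mm > 0):
        raise DegenerateGeometryError(
            "rest-frame inter-segment y-distance must be > 0"
        )
    return float((dmag_lower_mm - dmag_upper_mm) / rest_distance_y_mm)


def max_excursion(record: KinematicRecord) -> tuple[int, float]:
    """Frame of greatest displacement magnitude (ties -> earliest frame)."""
    if record.n_frames == 0:
        raise ArgumentError("empty record")
    frame = int(np.argmax(record.dmag_mm))
    return frame, float(record.dmag_mm[frame])


@dataclass(frozen=True)
class ManeuverResult:
    """Summary kinematics of one subject-maneuver cine.

    Values are taken at the maximum-excursion frame of the selection ROI
    (the proximal segment by default — bladder-neck descent).
    """

    maneuver: str
    max_frame: int
    selection_roi: str
    peak_dmag_mm: float
    per_roi: Mapping[str, dict]          # dx, dy, dtheta, dmag, phi at max frame
    kink_rest_deg: float | None
    kink_max_deg: float | None
    rel_mobility_prox_mid: float | None  # mm/mm at max excursion
    rel_mobility_mid_dist: float | None
    trial_index: int = 0


def compute_maneuver_result(records: Mapping[str, KinematicRecord],
                            positions_mm: Mapping[str, np.ndarray],
                            maneuver: str,
                            selection_roi: str = "proximal",
                            trial_index: int = 0) -> ManeuverResult:
    """Assemble per-maneuver metrics from per-ROI kinematic records.

    ``positions_mm[roi]`` are the absolute pelvic-frame (T, 2) positions used
    for the kink-angle chain geometry.  Chain metrics are reported only when
    all three urethral segments are present.
    """
    if selection_roi not in records:
        raise ArgumentError(f"selection ROI '{selection_roi}' not in records")
    sel = records[selection_roi]
    max_frame, peak = max_excursion(sel)
    per_roi = {}
    for lab, rec in records.items():
        per_roi[lab] = {
            "dx_mm": float(rec.dx_mm[max_frame]),
            "dy_mm": float(rec.dy_mm[max_frame]),
            "dtheta_deg": float(rec.dtheta_deg[max_frame]),
            "dmag_mm": float(rec.dmag_mm[max_frame]),
            "phi_deg": float(rec.phi_deg[max_frame]),
            "phi_reliable": bool(rec.phi_reliable[max_frame]),
        }
    chain = all(lab in records for lab in ("proximal", "mid", "distal"))
    kink_rest = kink_max = r_pm = r_md = None
    if chain:
        rest = {lab: positions_mm[lab][records[lab].rest_frame] for lab in
                ("proximal", "mid", "distal")}
        at_max = {lab: positions_mm[lab][max_frame] for lab in
                  ("proximal", "mid", "distal")}
        kink_rest = kink_angle(rest["proximal"], rest["mid"], rest["distal"])
        kink_max = kink_angle(at_max["proximal"], at_max["mid"], at_max["distal"])
        dist_pm = abs(rest["proximal"][1] - rest["mid"][1])
        dist_md = abs(rest["mid"][1] - rest["distal"][1])
        r_pm = relative_mobility(records["proximal"].dmag_mm[max_frame],
                                 records["mid"].dmag_mm[max_frame], dist_pm)
        r_md = relative_mobility(records["mid"].dmag_mm[max_frame],
                                 records["distal"].dmag_mm[max_frame], dist_md)
    return ManeuverResult(maneuver, max_frame, selection_roi, peak, per_roi,
                          kink_rest, kink_max, r_pm, r_md, trial_index)


def select_trial(results: Sequence[ManeuverResult]) -> ManeuverResult:
    """Pick the repetition with the greatest excursion (ties -> lowest index)."""
    if len(results) == 0:
        raise ArgumentError("no trials to select from")
    peaks = np.array([r.peak_dmag_mm for r in results])
    return results[int(np.argmax(peaks))]
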