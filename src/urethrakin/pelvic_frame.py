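"""The pubis-anchored pelvic coordinate system.

The analysis frame is anchored at the inferior pubic point (IPP): the +x
axis is tangent to the inferior pubic margin and points posteriorly (from
the IPP toward the annotated tangent point), the +y axis is perpendicular
and points superiorly.  The frame is rigidly attached to the tracked pubis
ROI, so probe-pubis motion — translation or rotation of the transducer
relative to the bony pelvis — cancels out of every ROI trajectory expressed
in it.  This is the method's central correction: pelvic-frame trajectories
are (within tracking tolerance) identical whether or not the probe moved.

Because image rows grow downward while the anatomical +y is superior, one
sign flip happens here — and nowhere else in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cine_io import RoiAnnotation
from .errors import ArgumentError, DegenerateGeometryError
from .roi_tracking import PoseSeries


@dataclass(frozen=True)
class PelvicFrame:
    """Per-frame origin and orthonormal axes of the IPP-anchored frame,
    in image coordinates, plus the pubis rotation carried by the frame."""

    origin_px: np.ndarray   # (T, 2) IPP position each frame
    xhat: np.ndarray        # (T, 2) unit tangent, posterior
    yhat: np.ndarray        # (T, 2) unit normal, superior
    pubis_theta_deg: np.ndarray  # (T,) raster-convention pubis rotation
    pixel_spacing_mm: float

    @property
    def n_frames(self) -> int:
        return int(self.origin_px.shape[0])


def construct_frame(pubis_pose: PoseSeries, annotation: RoiAnnotation,
                    pixel_spacing_mm: float) -> PelvicFrame:
    """Build the per-frame pelvic frame from the tracked pubis pose.

    Frame-0 axes derive from the annotated IPP and tangent point; each later
    frame's origin and axes are the frame-0 ones carried by the pubis ROI's
    rigid pose (the pubis is bone — it moves only with the probe).
    """
    ipp = np.asarray(annotation.ipp_px, dtype=float)
    tangent = np.asarray(annotation.tangent_px, dtype=float)
    direction = tangent - ipp
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        raise DegenerateGeometryError("IPP and tangent point coincide")
    xhat0 = direction / norm
    yhat0 = np.array([xhat0[1], -xhat0[0]])  # superior: -row direction

    T = pubis_pose.n_frames
    pubis_origin0 = annotation.rois["pubis"].origin
    theta = np.deg2rad(pubis_pose.theta_deg)
    c, s = np.cos(theta), np.sin(theta)
    # R_t carries frame-0 pubis geometry to frame t:  p_t = R_t (p_0 - o_0) + o_t
    rel = ipp - pubis_origin0
    origin = np.column_stack([
        pubis_pose.x_px + c * rel[0] - s * rel[1],
        pubis_pose.y_px + s * rel[0] + c * rel[1],
    ])
    xhat = np.column_stack([c * xhat0[0] - s * xhat0[1], s * xhat0[0] + c * xhat0[1]])
    yhat = np.column_stack([c * yhat0[0] - s * yhat0[1], s * yhat0[0] + c * yhat0[1]])
    return PelvicFrame(origin, xhat, yhat, pubis_pose.theta_deg.copy(),
                       pixel_spacing_mm)


def to_pelvic(pose: PoseSeries, frame: PelvicFrame) -> np.ndarray:
    """Express an ROI pose series in pelvic coordinates.

    Returns a (T, 3) array of (x_mm, y_mm, theta_deg): the projection of
    (ROI origin - IPP) onto the frame axes scaled by the pixel spacing, and
    the ROI rotation relative to the pubis in the anatomical convention
    (positive = posterior-axis-to-superior-axis, i.e. counterclockwise in
    anatomical display — the sign flip from raster coordinates).
    """
    if pose.n_frames != frame.n_frames:
        raise ArgumentError(
            f"pose series has {pose.n_frames} frames but the pelvic frame "
            f"has {frame.n_frames}"
        )
    rel = pose.origin_px - frame.origin_px
    x_mm = np.einsum("ij,ij->i", rel, frame.xhat) * frame.pixel_spacing_mm
    y_mm = np.einsum("ij,ij->i", rel, frame.yhat) * frame.pixel_spacing_mm
    theta = -(pose.theta_deg - frame.pubis_theta_deg)
    return np.column_stack([x_mm, y_mm, theta])
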