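"""Cine-loop, annotation and trajectory I/O.

Containers
----------
:class:`CineLoop`
    An ordered stack of grayscale frames (``T x H x W`` floats in ``[0, 1]``)
    with frame rate (Hz) and isotropic pixel spacing (mm/px).
:class:`RoiAnnotation`
    The one-time operator input: four rectangles (proximal / mid / distal
    urethra and pubis), the inferior pubic point (IPP) and a second point
    defining the pubic tangent direction, all in frame-0 image coordinates.

Coordinate convention
---------------------
Image coordinates are raster: ``x`` = column (rightward), ``y`` = row
(downward).  A rectangle is stored by its *origin* — the bottom-left corner
in anatomical display orientation, i.e. the corner with the smallest column
and the **largest** row — plus width and height, so the rectangle spans
columns ``[x, x + w]`` and rows ``[y - h, y]``.  The tangent point must be
annotated posterior to the IPP.  Conversion to the right-handed,
superior-positive pelvic frame happens once, in :mod:`urethrakin.pelvic_frame`.

Supported cine formats: multiframe DICOM, PNG/TIFF stacks with a sidecar
metadata JSON, and (where an imageio plugin exists) grayscale video
containers.  Readers reject malformed input; nothing is silently repaired.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ArgumentError, CalibrationError, ParseError, SchemaError

ROI_LABELS = ("proximal", "mid", "distal", "pubis")
URETHRAL_LABELS = ("proximal", "mid", "distal")

COORDINATE_CONVENTION = (
    "raster image coordinates: x = column (rightward), y = row (downward); "
    "rectangle origin = bottom-left corner in anatomical display orientation "
    "(smallest column, largest row); tangent point posterior to the IPP"
)

_TRAJ_COLUMNS = [
    "subject", "maneuver", "roi", "frame", "t_s", "x_mm", "y_mm",
    "theta_deg", "dx_mm", "dy_mm", "dmag_mm", "phi_deg", "n_points_tracked",
]


@dataclass(frozen=True)
class CineLoop:
    """A grayscale cine: frames ``(T, H, W)`` in [0, 1] plus calibration."""

    frames: np.ndarray
    frame_rate_hz: float
    pixel_spacing_mm: float
    source: str = "memory"

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float32)
        if frames.ndim != 3:
            raise ArgumentError(f"frames must be T x H x W, got shape {frames.shape}")
        if frames.shape[0] < 2:
            raise ArgumentError("a cine loop needs at least 2 frames")
        if not (self.frame_rate_hz > 0):
            raise ArgumentError("frame_rate_hz must be > 0")
        if not (self.pixel_spacing_mm > 0):
            raise ArgumentError("pixel_spacing_mm must be > 0")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return int(self.frames.shape[1]), int(self.frames.shape[2])

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass(frozen=True)
class RoiRect:
    """Axis-aligned rectangle; origin = bottom-left corner (see module docs)."""

    x_px: float
    y_px: float
    width_px: float
    height_px: float

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise SchemaError("rectangle width/height must be positive")

    @property
    def origin(self) -> np.ndarray:
        return np.array([self.x_px, self.y_px], dtype=float)

    @property
    def corners(self) -> np.ndarray:
        """(4, 2) corner coordinates, origin first."""
        x, y, w, h = self.x_px, self.y_px, self.width_px, self.height_px
        return np.array([[x, y], [x + w, y], [x + w, y - h], [x, y - h]], dtype=float)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return (
            (p[:, 0] >= self.x_px)
            & (p[:, 0] <= self.x_px + self.width_px)
            & (p[:, 1] >= self.y_px - self.height_px)
            & (p[:, 1] <= self.y_px)
        )

    def within_bounds(self, frame_shape: tuple[int, int]) -> bool:
        h, w = frame_shape
        return (
            self.x_px >= 0
            and self.y_px - self.height_px >= 0
            and self.x_px + self.width_px <= w - 1
            and self.y_px <= h - 1
        )


@dataclass(frozen=True)
class RoiAnnotation:
    """Operator annotation at a reference frame (default frame 0)."""

    rois: Mapping[str, RoiRect]
    ipp_px: tuple[float, float]
    tangent_px: tuple[float, float]
    frame_index: int = 0

    def __post_init__(self) -> None:
        missing = [lab for lab in ROI_LABELS if lab not in self.rois]
        if missing:
            raise SchemaError(f"annotation missing ROI label(s): {', '.join(missing)}")
        if tuple(self.ipp_px) == tuple(self.tangent_px):
            raise SchemaError("ipp_px and tangent_px must differ (degenerate tangent)")
        rects = [self.rois[lab] for lab in URETHRAL_LABELS]
        for i in range(len(rects)):
            for j in range(i + 1, len(rects)):
                if rects[i] == rects[j]:
                    raise SchemaError(
                        f"urethral ROIs '{URETHRAL_LABELS[i]}' and "
                        f"'{URETHRAL_LABELS[j]}' are identical"
                    )
        object.__setattr__(self, "rois", dict(self.rois))
        object.__setattr__(self, "ipp_px", tuple(float(v) for v in self.ipp_px))
        object.__setattr__(self, "tangent_px", tuple(float(v) for v in self.tangent_px))

    def validate_bounds(self, frame_shape: tuple[int, int]) -> None:
        for lab, rect in self.rois.items():
            if not rect.within_bounds(frame_shape):
                raise SchemaError(
                    f"ROI '{lab}' rectangle exceeds frame bounds {frame_shape}"
                )


# ---------------------------------------------------------------------------
# cine reading / writing
# ---------------------------------------------------------------------------

def _normalize_frames(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames)
    if frames.ndim == 4:  # RGB(A) -> luma
        frames = frames[..., :3].mean(axis=-1)
    frames = frames.astype(np.float32)
    if np.issubdtype(np.asarray(frames).dtype, np.floating):
        peak = float(frames.max()) if frames.size else 1.0
        if peak > 1.0:
            frames = frames / peak
    lo = float(frames.min())
    if lo < 0:
        frames = frames - lo
        frames = frames / max(float(frames.max()), 1e-12)
    return np.clip(frames, 0.0, 1.0)


def _load_dicom(path: Path, frame_rate_hz, pixel_spacing_mm) -> CineLoop:
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array
    if arr.ndim == 2 or (arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] > 8):
        raise ArgumentError(f"{path}: single-frame DICOM; a cine needs >= 2 frames")
    frames = arr.astype(np.float32)
    if frames.max() > 0:
        frames = frames / float(frames.max())
    if frame_rate_hz is None:
        if "CineRate" in ds:
            frame_rate_hz = float(ds.CineRate)
        elif "FrameTime" in ds and float(ds.FrameTime) > 0:
            frame_rate_hz = 1000.0 / float(ds.FrameTime)
        else:
            raise CalibrationError(
                f"{path}: no CineRate/FrameTime tag; pass frame_rate_hz explicitly"
            )
    if pixel_spacing_mm is None:
        spacing = getattr(ds, "PixelSpacing", None)
        if spacing is None:
            raise CalibrationError(
                f"{path}: no PixelSpacing tag; pass pixel_spacing_mm explicitly"
            )
        sy, sx = float(spacing[0]), float(spacing[1])
        if abs(sy - sx) > 1e-6 * max(sy, sx):
            raise CalibrationError(
                f"{path}: anisotropic PixelSpacing {sy} x {sx} mm not supported"
            )
        pixel_spacing_mm = sx
    return CineLoop(_normalize_frames(frames), frame_rate_hz, pixel_spacing_mm, str(path))


def _load_stack_dir(path: Path, frame_rate_hz, pixel_spacing_mm) -> CineLoop:
    meta_path = path / "metadata.json"
    meta = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    if frame_rate_hz is None:
        frame_rate_hz = meta.get("frame_rate_hz")
    if pixel_spacing_mm is None:
        pixel_spacing_mm = meta.get("pixel_spacing_mm")
    if frame_rate_hz is None or pixel_spacing_mm is None:
        raise CalibrationError(
            f"{path}: frame rate / pixel spacing not in metadata.json; "
            "pass them explicitly or add them to the sidecar JSON"
        )
    files = sorted(
        p for p in path.iterdir()
        if p.suffix.lower() in (".png", ".tif", ".tiff") and re.search(r"\d+", p.stem)
    )
    if len(files) < 2:
        raise ArgumentError(f"{path}: found {len(files)} frame images; need >= 2")
    frames = np.stack([np.asarray(iio.imread(f), dtype=np.float64) for f in files])
    # PNG stacks are quantized; undo the integer scaling
    if frames.max() > 1.0:
        frames = frames / (65535.0 if frames.max() > 255 else 255.0)
    return CineLoop(_normalize_frames(frames), float(frame_rate_hz),
                    float(pixel_spacing_mm), str(path))


def load_cine(path, *, frame_rate_hz: float | None = None,
              pixel_spacing_mm: float | None = None) -> CineLoop:
    """Load a cine loop from DICOM, an image-stack directory, or a video file.

    ``frame_rate_hz`` / ``pixel_spacing_mm`` override (or supply, when the
    container lacks them) the calibration; a missing calibration raises
    :class:`~urethrakin.errors.CalibrationError` rather than guessing.
    """
    path = Path(path)
    if not path.exists():
        raise ArgumentError(f"no such cine source: {path}")
    if path.is_dir():
        return _load_stack_dir(path, frame_rate_hz, pixel_spacing_mm)
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom", ""):
        return _load_dicom(path, frame_rate_hz, pixel_spacing_mm)
    if suffix in (".tif", ".tiff"):
        frames = np.asarray(iio.imread(path))
        if frames.ndim == 2:
            raise ArgumentError(f"{path}: single-frame TIFF; a cine needs >= 2 frames")
        if frame_rate_hz is None or pixel_spacing_mm is None:
            raise CalibrationError(
                f"{path}: supply frame_rate_hz and pixel_spacing_mm for TIFF stacks"
            )
        return CineLoop(_normalize_frames(frames), frame_rate_hz, pixel_spacing_mm, str(path))
    if suffix in (".avi", ".mp4", ".mov", ".mkv"):
        if frame_rate_hz is None or pixel_spacing_mm is None:
            raise CalibrationError(
                f"{path}: video containers carry no spacing; supply frame_rate_hz "
                "and pixel_spacing_mm"
            )
        try:
            frames = np.asarray(iio.imread(path))
        except Exception as exc:  # no ffmpeg plugin in minimal installs
            raise ArgumentError(f"cannot read video {path}: {exc}") from exc
        return CineLoop(_normalize_frames(frames), frame_rate_hz, pixel_spacing_mm, str(path))
    raise ArgumentError(f"unrecognized cine format: {path}")


def save_cine(cine: CineLoop, out_dir) -> Path:
    """Write a cine as a 16-bit PNG stack plus ``metadata.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(cine.frames):
        q = np.round(np.clip(frame, 0, 1) * 65535).astype(np.uint16)
        iio.imwrite(out_dir / f"frame_{i:04d}.png", q)
    (out_dir / "metadata.json").write_text(json.dumps({
        "frame_rate_hz": cine.frame_rate_hz,
        "pixel_spacing_mm": cine.pixel_spacing_mm,
        "n_frames": cine.n_frames,
        "frame_shape": list(cine.frame_shape),
    }, indent=2))
    return out_dir


# ---------------------------------------------------------------------------
# annotation JSON
# ---------------------------------------------------------------------------

def write_annotation(annotation: RoiAnnotation, path) -> Path:
    path = Path(path)
    payload = {
        "coordinate_convention": COORDINATE_CONVENTION,
        "frame_index": annotation.frame_index,
        "rois": {
            lab: {"x_px": r.x_px, "y_px": r.y_px,
                  "width_px": r.width_px, "height_px": r.height_px}
            for lab, r in annotation.rois.items()
        },
        "ipp_px": list(annotation.ipp_px),
        "tangent_px": list(annotation.tangent_px),
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_annotation(path, frame_shape: tuple[int, int] | None = None) -> RoiAnnotation:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("rois", "ipp_px", "tangent_px"):
        if key not in payload:
            raise SchemaError(f"{path}: missing field '{key}'")
    rois = {}
    for lab in ROI_LABELS:
        if lab not in payload["rois"]:
            raise SchemaError(f"{path}: rois missing label '{lab}'")
        spec = payload["rois"][lab]
        try:
            rois[lab] = RoiRect(float(spec["x_px"]), float(spec["y_px"]),
                                float(spec["width_px"]), float(spec["height_px"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: malformed rectangle for '{lab}': {exc}") from exc
    ann = RoiAnnotation(rois, tuple(payload["ipp_px"]), tuple(payload["tangent_px"]),
                        int(payload.get("frame_index", 0)))
    if frame_shape is not None:
        ann.validate_bounds(frame_shape)
    return ann


# ---------------------------------------------------------------------------
# trajectory CSV
# ---------------------------------------------------------------------------

def write_trajectories(records: pd.DataFrame | list[dict], path) -> Path:
    """Write a long-format trajectory table (one row per subject/maneuver/roi/frame)."""
    path = Path(path)
    df = pd.DataFrame(records, columns=_TRAJ_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_trajectories(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    numeric = [c for c in _TRAJ_COLUMNS if c not in ("subject", "maneuver", "roi")]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header line, one for 0-based indexing
            line = int(bad.idxmax()) + 2
            raise ParseError(f"{path}: non-numeric value in column '{col}' at line {line}")
        df[col] = coerced
    return df
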