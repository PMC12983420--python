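"""End-to-end orchestration: simulate -> track -> kinematics -> statistics.

``run_subject`` turns one cine + annotation into pelvic-frame trajectories
and per-maneuver metric rows; ``run_cohort`` batches subjects into the tidy
cohort table and emits group summaries, per-ROI mixed ANOVAs and the
pairwise contrast report.  One subject's tracking failure never aborts a
cohort run — it is logged and skipped — but the run aborts if fewer than two
subjects per group survive.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats as cs
from .cine_io import CineLoop, RoiAnnotation, URETHRAL_LABELS
from .errors import ArgumentError, SchemaError, UrethrakinError
from .kinematics import (
    KinematicRecord,
    ManeuverResult,
    compute_maneuver_result,
    displacement_series,
)
from .pelvic_frame import construct_frame, to_pelvic
from .roi_tracking import TrackerSettings, track_annotation
from .synthetic_cine import CohortSpec, SyntheticSubject, make_cohort

logger = logging.getLogger("urethrakin")


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs besides the data itself."""

    tracker: TrackerSettings = field(default_factory=TrackerSettings)
    rois: Sequence[str] = URETHRAL_LABELS
    selection_roi: str = "proximal"   # segment whose excursion defines "maximum"
    rest_frame: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        rois = tuple(self.rois)
        bad = [r for r in rois if r not in URETHRAL_LABELS]
        if bad:
            raise ArgumentError(f"unknown ROI label(s) in config: {bad}")
        if self.selection_roi not in rois:
            raise ArgumentError(
                f"selection_roi '{self.selection_roi}' is not among rois {rois}"
            )
        object.__setattr__(self, "rois", rois)

    def to_yaml(self, path) -> Path:
        payload = dataclasses.asdict(self)
        payload["rois"] = list(payload["rois"])
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
        return Path(path)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict):
            raise SchemaError(f"{path}: config must be a mapping")
        tracker = TrackerSettings(**payload.pop("tracker", {}) or {})
        try:
            return cls(tracker=tracker, **payload)
        except TypeError as exc:
            raise SchemaError(f"{path}: {exc}") from exc


@dataclass(frozen=True)
class SubjectResult:
    subject: str
    maneuver: str
    trajectories: pd.DataFrame
    metric_rows: list[dict]
    maneuver_result: ManeuverResult
    log: dict


def run_subject(cine: CineLoop, annotation: RoiAnnotation, config: RunConfig,
                subject: str = "subject", maneuver: str = "maneuver",
                group: str | None = None) -> SubjectResult:
    """Track one cine, express poses in the pelvic frame, compute metrics.

    Deterministic for fixed inputs and ``config.seed``.
    """
    annotation.validate_bounds(cine.frame_shape)
    settings = dataclasses.replace(config.tracker, seed=config.seed)
    labels = ("pubis",) + tuple(config.rois)
    poses = track_annotation(cine, annotation, settings, labels=labels)
    frame = construct_frame(poses["pubis"], annotation, cine.pixel_spacing_mm)

    records: dict[str, KinematicRecord] = {}
    positions: dict[str, np.ndarray] = {}
    traj_rows = []
    times = cine.times_s
    for roi in config.rois:
        pel = to_pelvic(poses[roi], frame)
        rec = displacement_series(pel, roi, config.rest_frame)
        records[roi] = rec
        positions[roi] = pel[:, :2]
        for f in range(cine.n_frames):
            traj_rows.append({
                "subject": subject, "maneuver": maneuver, "roi": roi,
                "frame": f, "t_s": times[f],
                "x_mm": pel[f, 0], "y_mm": pel[f, 1], "theta_deg": pel[f, 2],
                "dx_mm": rec.dx_mm[f], "dy_mm": rec.dy_mm[f],
                "dmag_mm": rec.dmag_mm[f], "phi_deg": rec.phi_deg[f],
                "n_points_tracked": int(poses[roi].n_points_tracked[f]),
            })
    result = compute_maneuver_result(records, positions, maneuver,
                                     config.selection_roi)
    metric_rows = metric_rows_from_result(result, subject, group)
    log = {
        "subject": subject, "maneuver": maneuver,
        "reseed_events": {lab: int(poses[lab].reseeded.sum()) for lab in labels},
        "mean_fb_error_px": {
            lab: float(np.nanmean(poses[lab].fb_error_px[1:])) for lab in labels
        },
        "min_points_tracked": {
            lab: int(poses[lab].n_points_tracked[1:].min()) for lab in labels
        },
    }
    logger.debug(json.dumps(log))
    return SubjectResult(subject, maneuver, pd.DataFrame(traj_rows),
                         metric_rows, result, log)


def metric_rows_from_result(result: ManeuverResult, subject: str,
                            group: str | None) -> list[dict]:
    """Flatten a :class:`ManeuverResult` into tidy cohort-table rows."""
    rows = []

    def _row(roi, metric, value):
        rows.append({"subject": subject, "group": group,
                     "maneuver": result.maneuver, "roi": roi,
                     "metric": metric, "value": value})

    for roi, vals in result.per_roi.items():
        for metric in ("dx_mm", "dy_mm", "dtheta_deg", "dmag_mm", "phi_deg"):
            _row(roi, metric, vals[metric])
    if result.kink_rest_deg is not None:
        _row("chain", "kink_rest_deg", result.kink_rest_deg)
        _row("chain", "kink_max_deg", result.kink_max_deg)
        # signed (negative = proximal-dominant) and magnitude-only variants
        _row("proximal_mid", "rel_mobility_mm_per_mm", result.rel_mobility_prox_mid)
        _row("mid_distal", "rel_mobility_mm_per_mm", result.rel_mobility_mid_dist)
        _row("proximal_mid", "abs_rel_mobility_mm_per_mm",
             abs(result.rel_mobility_prox_mid))
        _row("mid_distal", "abs_rel_mobility_mm_per_mm",
             abs(result.rel_mobility_mid_dist))
    _row(result.selection_roi, "max_frame", float(result.max_frame))
    return rows


@dataclass(frozen=True)
class CohortResult:
    table: pd.DataFrame          # tidy cohort table
    summary: pd.DataFrame        # per-cell descriptive statistics
    anova: Mapping[str, pd.DataFrame]     # per-ROI mixed ANOVA (dmag)
    contrasts: pd.DataFrame      # pairwise tests with Bonferroni adjustment
    failures: list[dict]
    trajectories: pd.DataFrame


def run_cohort(subjects: Sequence[SyntheticSubject] | CohortSpec,
               config: RunConfig = RunConfig()) -> CohortResult:
    """Run the full analysis over a cohort of subject-maneuver cines.

    ``subjects`` is either a :class:`CohortSpec` (rendered here) or an
    iterable of :class:`SyntheticSubject`.  Per-subject failures are recorded
    and skipped; the run aborts only when fewer than two subjects per group
    survive.
    """
    if isinstance(subjects, CohortSpec):
        subjects = make_cohort(subjects)
    rows: list[dict] = []
    traj_frames = []
    failures: list[dict] = []
    survivors: dict[str, set] = {}
    for subj in subjects:
        try:
            res = run_subject(subj.cine, subj.annotation, config,
                              subject=subj.subject_id, maneuver=subj.maneuver,
                              group=subj.group)
        except UrethrakinError as exc:
            failures.append({"subject": subj.subject_id,
                             "maneuver": subj.maneuver, "error": str(exc)})
            logger.warning("subject %s/%s failed: %s", subj.subject_id,
                           subj.maneuver, exc)
            continue
        rows.extend(res.metric_rows)
        traj_frames.append(res.trajectories)
        survivors.setdefault(subj.group, set()).add(subj.subject_id)
    for group, members in survivors.items():
        if len(members) < 2:
            raise ArgumentError(
                f"fewer than 2 surviving subjects in group '{group}'"
            )
    if not rows:
        raise ArgumentError("no subject produced any metrics")
    table = pd.DataFrame(rows, columns=cs.COHORT_COLUMNS)
    summary = cs.summarize_cohort(table)
    maneuvers = sorted(table["maneuver"].unique())
    anova = {}
    contrast_rows = []
    have_all_three = set(maneuvers) >= {"cough", "valsalva", "pmc"}
    for roi in config.rois:
        if have_all_three:
            try:
                anova[roi] = cs.rm_anova_2x3(table, roi, "dmag_mm")
            except UrethrakinError as exc:
                logger.warning("ANOVA skipped for %s: %s", roi, exc)
        if have_all_three:
            family = cs.default_contrast_family(roi, "dmag_mm")
        else:
            family = [cs.Contrast("independent", roi, "dmag_mm", maneuver=m)
                      for m in maneuvers]
        try:
            contrast_rows.append(cs.pairwise_compare(table, family))
        except UrethrakinError as exc:
            logger.warning("contrasts skipped for %s: %s", roi, exc)
    contrasts = (pd.concat(contrast_rows, ignore_index=True)
                 if contrast_rows else pd.DataFrame())
    trajectories = (pd.concat(traj_frames, ignore_index=True)
                    if traj_frames else pd.DataFrame())
    return CohortResult(table, summary, anova, contrasts, failures, trajectories)


def metrics_from_trajectories(traj: pd.DataFrame, config: RunConfig = RunConfig(),
                              group_map: Mapping[str, str] | None = None
                              ) -> pd.DataFrame:
    """Recompute per-maneuver metric rows from a saved trajectory table."""
    rows = []
    for (subject, maneuver), sub in traj.groupby(["subject", "maneuver"]):
        records, positions = {}, {}
        for roi, roi_df in sub.groupby("roi"):
            roi_df = roi_df.sort_values("frame")
            pel = roi_df[["x_mm", "y_mm", "theta_deg"]].to_numpy(float)
            records[roi] = displacement_series(pel, roi, config.rest_frame)
            positions[roi] = pel[:, :2]
        sel = config.selection_roi if config.selection_roi in records \
            else next(iter(records))
        result = compute_maneuver_result(records, positions, maneuver, sel)
        group = group_map.get(subject) if group_map else None
        rows.extend(metric_rows_from_result(result, subject, group))
    return pd.DataFrame(rows, columns=cs.COHORT_COLUMNS)
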