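"""Condition-specific behavioral variables and unit conversions.

One variable per condition:

* novel object — mean distance of the head tag from the object over the
  trial ('mean dist. to object', pixels);
* open field — max minus min distance of the head tag from the arena center
  ('roaming range', pixels);
* shelter — seconds with one tag (partial concealment) or no tag (full
  concealment) detected ('shelter usage').

Frames with a missing head tag are excluded from the two distance-based
metrics; shelter usage is defined purely by tag detectability, with no
geometric shelter mask, and must be computed on an uninterpolated track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ArenaGeometry, ObjectTrack, TagTrack, TrialMeta, ValidationError
from .motion_analysis import MotionParams, MovementSummary, analyze_track

__all__ = [
    "ConditionMetrics",
    "UndefinedMetricError",
    "mean_distance_to_object",
    "roaming_range",
    "shelter_usage",
    "pixels_to_mm",
    "delta_scores",
    "compute_condition_metrics",
    "metrics_table",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value (e.g. head never detected)."""


@dataclass
class ConditionMetrics:
    """Per-trial behavioral variables; exactly the metric matching the
    trial's condition is set, the other two are NaN."""

    meta: TrialMeta
    mean_dist_to_object_px: float
    roaming_range_px: float
    shelter_usage_s: float
    total_walking_px: float
    total_head_movement_px: float


def _head_distances(track: TagTrack, ref_xy: np.ndarray) -> np.ndarray:
    det = track.head_detected
    if not det.any():
        raise UndefinedMetricError("head tag never detected in trial")
    d = track.head[det] - ref_xy[det] if ref_xy.ndim == 2 else track.head[det] - ref_xy
    return np.hypot(d[:, 0], d[:, 1])


def mean_distance_to_object(track: TagTrack, object_track: ObjectTrack) -> float:
    """Mean head-to-object distance (px) over frames with a detected head."""
    if object_track.n_frames != track.n_frames:
        raise ValidationError("object track and tag track must be aligned")
    return float(_head_distances(track, object_track.object_xy).mean())


def roaming_range(track: TagTrack, center_xy) -> float:
    """Max minus min head-to-center distance (px) over detected frames."""
    d = _head_distances(track, np.asarray(center_xy, dtype=float))
    return float(d.max() - d.min())


def shelter_usage(track: TagTrack, fps: float) -> float:
    """Seconds with at most one tag detected (partial or full concealment)."""
    if track.has_interpolated:
        raise ValidationError(
            "shelter usage requires an uninterpolated track: imputation masks "
            "concealment"
        )
    n_det = track.head_detected.astype(int) + track.tail_detected.astype(int)
    return float(np.count_nonzero(n_det <= 1)) / fps


def pixels_to_mm(d_px: float, geometry: ArenaGeometry) -> float:
    """Convert a pixel distance to millimetres via the calibration constant."""
    if d_px < 0:
        raise ValidationError("distance must be non-negative")
    return d_px * geometry.mm_per_pixel


def delta_scores(phase1: pd.Series, phase2: pd.Series) -> pd.Series:
    """Per-subject phase-1 minus phase-2 values (direction of change).

    A subject that e.g. moved closer to the object in phase 2 (smaller
    distance) gets a positive delta.
    """
    p1 = pd.Series(phase1)
    p2 = pd.Series(phase2)
    if set(p1.index) != set(p2.index):
        raise ValidationError("phase 1 and phase 2 must cover the same subjects")
    return p1 - p2.reindex(p1.index)


def compute_condition_metrics(
    track: TagTrack,
    meta: TrialMeta,
    geometry: ArenaGeometry,
    object_track: ObjectTrack | None = None,
    params: MotionParams = MotionParams(),
    summary: MovementSummary | None = None,
) -> ConditionMetrics:
    """Movement totals plus the single metric matching the trial condition."""
    if summary is None:
        summary = analyze_track(track, params)
    mdo = rr = su = float("nan")
    if meta.condition == "novel_object":
        if object_track is None:
            object_track = ObjectTrack.constant(track.n_frames, geometry.center_xy)
        mdo = mean_distance_to_object(track, object_track)
    elif meta.condition == "open_field":
        rr = roaming_range(track, geometry.center_xy)
    else:
        su = shelter_usage(track, geometry.fps)
    return ConditionMetrics(
        meta=meta,
        mean_dist_to_object_px=mdo,
        roaming_range_px=rr,
        shelter_usage_s=su,
        total_walking_px=summary.total_walking_px,
        total_head_movement_px=summary.total_head_movement_px,
    )


def metrics_table(rows: list[ConditionMetrics]) -> pd.DataFrame:
    """Long-format trial table (one row per trial) feeding the statistics."""
    recs = []
    for m in rows:
        recs.append(
            {
                "subject_id": m.meta.subject_id,
                "species": m.meta.species,
                "phase": m.meta.phase,
                "condition": m.meta.condition,
                "testing_time": m.meta.testing_time,
                "incubation_group": m.meta.incubation_group,
                "mean_dist_to_object_px": m.mean_dist_to_object_px,
                "roaming_range_px": m.roaming_range_px,
                "shelter_usage_s": m.shelter_usage_s,
                "total_walking_px": m.total_walking_px,
                "total_head_movement_px": m.total_head_movement_px,
            }
        )
    df = pd.DataFrame(recs)
    if len(df) and df.duplicated(["subject_id", "phase", "condition"]).any():
        raise ValidationError("duplicate (subject, phase, condition) rows")
    return df
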