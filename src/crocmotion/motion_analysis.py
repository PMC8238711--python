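"""Event-based classification of locomotion vs. head movement.

The classifier compares each frame ``i`` with the frame half a second earlier
(``i - lag``, 30 frames at 60 f/s). The "head line" (HL) joins the head-tag
position at the two frames; only when its length reaches the event threshold
(5 px, ~6.39 mm) is a movement event recorded, and the recorded distance is
measured from the previously recorded position (the anchor), which then jumps
to the current head position. The "tail-base line" (TbL) is the same
construction for the tail-base tag. Events are labeled by comparing the
compass angles of HL and TbL (right = 0 deg, screen-up = +90 deg): headings
agreeing to within 45 deg mean the whole body translated — walking distance —
while disagreement, or a stationary tail-base, means the head swung from a
stable body — head movement without walking. Crocodilians hold the head rigid
during terrestrial locomotion, so the two categories are mutually exclusive.

Anchor semantics: the anchor starts at the first detected head position,
moves only when an event is recorded, and survives frames where a tag is
missing (so shelter entries/exits are not counted as locomotion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import TagTrack, ValidationError

__all__ = [
    "MotionParams",
    "MovementEvent",
    "MovementSummary",
    "heading_angle",
    "angle_difference",
    "analyze_track",
    "events_to_dataframe",
]

WALKING = "walking"
HEAD_MOVEMENT = "head_movement"


@dataclass(frozen=True)
class MotionParams:
    """Thresholds of the event classifier.

    lag_frames: comparison lag (30 frames = 0.5 s at 60 f/s).
    min_displacement_px: minimum HL length for an event (5 px ~ 6.39 mm).
    angle_threshold_deg: heading-agreement bound splitting walking from head
        movement (45 deg; exactly 45 counts as head movement).
    """

    lag_frames: int = 30
    min_displacement_px: float = 5.0
    angle_threshold_deg: float = 45.0

    def __post_init__(self) -> None:
        if self.lag_frames < 1:
            raise ValidationError("lag_frames must be >= 1")
        if not self.min_displacement_px > 0:
            raise ValidationError("min_displacement_px must be > 0")
        if not 0 < self.angle_threshold_deg < 180:
            raise ValidationError("angle_threshold_deg must be in (0, 180)")


@dataclass
class MovementEvent:
    """One recorded movement: frame index, line lengths, angles, distance."""

    frame_index: int
    head_line_length_px: float
    tail_line_length_px: float | None
    ahl_deg: float | None
    atbl_deg: float | None
    angle_diff_deg: float | None
    recorded_distance_px: float
    label: str


@dataclass
class MovementSummary:
    """Per-trial totals; every event contributes to exactly one total."""

    total_walking_px: float
    total_head_movement_px: float
    events: list[MovementEvent] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.events)


def heading_angle(
    from_xy: tuple[float, float], to_xy: tuple[float, float]
) -> float | None:
    """Compass angle of the displacement from_xy -> to_xy, in degrees.

    Image y grows downward, so y is negated: right = 0, screen-up = +90,
    screen-down = -90; range (-180, 180]. Returns None for a zero vector.
    """
    dx = float(to_xy[0]) - float(from_xy[0])
    dy = float(to_xy[1]) - float(from_xy[1])
    if dx == 0.0 and dy == 0.0:
        return None
    ang = math.degrees(math.atan2(-dy, dx))
    if ang <= -180.0:
        ang = 180.0
    return ang


def angle_difference(a: float, b: float) -> float:
    """Minimal absolute circular difference between two angles, in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def analyze_track(track: TagTrack, params: MotionParams = MotionParams()) -> MovementSummary:
    """Run the event classifier over a track and accumulate the two totals.

    Frames where the head tag is missing at ``i`` or ``i - lag`` produce no
    event and leave the anchor in place. An event is labeled head movement
    when the tail-base is missing at either frame or its displacement is
    below the event threshold (a head turn from a stable position); otherwise
    the HL/TbL heading difference decides.
    """
    lag = params.lag_frames
    n = track.n_frames
    if n < lag + 1:
        raise ValidationError(
            f"track has {n} frames; need at least lag_frames+1 = {lag + 1}"
        )
    head = track.head
    tail = track.tail
    hd = track.head_detected
    td = track.tail_detected

    det_idx = np.flatnonzero(hd)
    anchor = head[det_idx[0]].copy() if det_idx.size else None

    hl_vec = head[lag:] - head[:-lag]
    hl_len = np.hypot(hl_vec[:, 0], hl_vec[:, 1])
    valid = hd[lag:] & hd[:-lag]
    cand = np.flatnonzero(valid & (hl_len >= params.min_displacement_px)) + lag

    events: list[MovementEvent] = []
    tot_walk = 0.0
    tot_head = 0.0
    thr = params.min_displacement_px
    for i in cand:
        hl = float(hl_len[i - lag])
        rec = float(np.hypot(*(head[i] - anchor))) if anchor is not None else 0.0
        tbl = ahl = atbl = diff = None
        if td[i] and td[i - lag]:
            tv = tail[i] - tail[i - lag]
            tbl = float(np.hypot(tv[0], tv[1]))
        if tbl is None or tbl < thr:
            label = HEAD_MOVEMENT
        else:
            ahl = heading_angle(head[i - lag], head[i])
            atbl = heading_angle(tail[i - lag], tail[i])
            diff = angle_difference(ahl, atbl)
            label = WALKING if diff < params.angle_threshold_deg else HEAD_MOVEMENT
        if label == WALKING:
            tot_walk += rec
        else:
            tot_head += rec
        events.append(
            MovementEvent(
                frame_index=int(i),
                head_line_length_px=hl,
                tail_line_length_px=tbl,
                ahl_deg=ahl,
                atbl_deg=atbl,
                angle_diff_deg=diff,
                recorded_distance_px=rec,
                label=label,
            )
        )
        anchor = head[i].copy()
    return MovementSummary(tot_walk, tot_head, events)


def events_to_dataframe(summary: MovementSummary) -> pd.DataFrame:
    """Event log as a DataFrame (one row per event), for the per-trial CSV."""
    return pd.DataFrame(
        [
            {
                "frame": e.frame_index,
                "head_line_length_px": e.head_line_length_px,
                "tail_line_length_px": e.tail_line_length_px,
                "ahl_deg": e.ahl_deg,
                "atbl_deg": e.atbl_deg,
                "angle_diff_deg": e.angle_diff_deg,
                "recorded_distance_px": e.recorded_distance_px,
                "label": e.label,
            }
            for e in summary.events
        ],
        columns=[
            "frame",
            "head_line_length_px",
            "tail_line_length_px",
            "ahl_deg",
            "atbl_deg",
            "angle_diff_deg",
            "recorded_distance_px",
            "label",
        ],
    )
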