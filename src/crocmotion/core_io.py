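"""Shared data model and trajectory/correction I/O.

The central container is :class:`TagTrack`: per-frame pixel coordinates of the
two color stickers (head tag, tail-base tag) together with per-frame detection
flags. Absence of a tag is first-class — the shelter condition is scored by
counting frames with missing tags, so a missing tag is a flag plus NaN
coordinates, never a sentinel coordinate.

Conventions: pixel units, origin at the top-left corner of the frame, x grows
rightward, y grows downward, frames are 0-based and contiguous.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArenaGeometry",
    "TrialMeta",
    "TagTrack",
    "Correction",
    "CorrectionSet",
    "ObjectTrack",
    "TrackFormatError",
    "ValidationError",
    "read_track_csv",
    "write_track_csv",
    "read_corrections_csv",
    "apply_corrections",
]

SPECIES = ("alligator", "caiman")
CONDITIONS = ("novel_object", "open_field", "shelter")
TESTING_TIMES = ("morning", "evening")
INCUBATION_GROUPS = ("presumed_male", "presumed_female")


class TrackFormatError(ValueError):
    """Raised when a track file does not have the expected layout."""


class ValidationError(ValueError):
    """Raised when data violates a documented invariant."""


@dataclass(frozen=True)
class ArenaGeometry:
    """Frame and arena calibration.

    ``mm_per_pixel`` is the physical edge length of one pixel at the arena
    floor (default 1.278 mm at 960x540 with the camera 37 cm above the floor);
    ``center_xy`` is the arena center, which is also the default novel-object
    location.
    """

    width_px: int = 960
    height_px: int = 540
    center_xy: tuple[float, float] = (480.0, 270.0)
    mm_per_pixel: float = 1.278
    fps: float = 60.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValidationError("frame dimensions must be positive")
        if self.fps <= 0 or self.mm_per_pixel <= 0:
            raise ValidationError("fps and mm_per_pixel must be positive")
        cx, cy = self.center_xy
        if not (0 <= cx < self.width_px and 0 <= cy < self.height_px):
            raise ValidationError("center_xy must lie within the frame")


@dataclass(frozen=True)
class TrialMeta:
    """Identity and design factors of one 10-minute trial."""

    subject_id: str
    species: str
    phase: int
    condition: str
    testing_time: str = "morning"
    incubation_group: str = "presumed_male"

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(f"species must be one of {SPECIES}")
        if self.phase not in (1, 2):
            raise ValidationError("phase must be 1 or 2")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"condition must be one of {CONDITIONS}")
        if self.testing_time not in TESTING_TIMES:
            raise ValidationError(f"testing_time must be one of {TESTING_TIMES}")
        if self.incubation_group not in INCUBATION_GROUPS:
            raise ValidationError(
                f"incubation_group must be one of {INCUBATION_GROUPS}"
            )


@dataclass
class TagTrack:
    """Per-frame head and tail-base tag positions with detection flags.

    Coordinates are ``(n_frames, 2)`` float arrays holding ``(x, y)``; frames
    where the tag was not detected hold NaN and have the corresponding
    ``*_detected`` flag False. ``*_interpolated`` marks coordinates filled by
    :func:`crocmotion.tag_detection.interpolate_gaps` rather than detected.
    """

    head: np.ndarray
    tail: np.ndarray
    head_detected: np.ndarray
    tail_detected: np.ndarray
    head_interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]
    tail_interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.head = np.asarray(self.head, dtype=float).reshape(-1, 2)
        self.tail = np.asarray(self.tail, dtype=float).reshape(-1, 2)
        n = self.head.shape[0]
        self.head_detected = np.asarray(self.head_detected, dtype=bool).reshape(n)
        self.tail_detected = np.asarray(self.tail_detected, dtype=bool).reshape(n)
        if self.tail.shape[0] != n:
            raise ValidationError("head and tail arrays must have equal length")
        if self.head_interpolated is None:
            self.head_interpolated = np.zeros(n, dtype=bool)
        if self.tail_interpolated is None:
            self.tail_interpolated = np.zeros(n, dtype=bool)
        self.head_interpolated = np.asarray(self.head_interpolated, bool).reshape(n)
        self.tail_interpolated = np.asarray(self.tail_interpolated, bool).reshape(n)
        for xy, det, name in (
            (self.head, self.head_detected, "head"),
            (self.tail, self.tail_detected, "tail"),
        ):
            finite = np.isfinite(xy).all(axis=1)
            if not np.array_equal(finite, det):
                raise ValidationError(
                    f"{name}_detected flags must match coordinate presence"
                )

    @property
    def n_frames(self) -> int:
        return self.head.shape[0]

    @property
    def has_interpolated(self) -> bool:
        return bool(self.head_interpolated.any() or self.tail_interpolated.any())

    @classmethod
    def empty(cls, n_frames: int) -> "TagTrack":
        nan = np.full((n_frames, 2), np.nan)
        false = np.zeros(n_frames, dtype=bool)
        return cls(nan.copy(), nan.copy(), false.copy(), false.copy())

    def copy(self) -> "TagTrack":
        return TagTrack(
            self.head.copy(),
            self.tail.copy(),
            self.head_detected.copy(),
            self.tail_detected.copy(),
            self.head_interpolated.copy(),
            self.tail_interpolated.copy(),
        )

    def validate_bounds(self, geometry: ArenaGeometry) -> None:
        """Check that every present coordinate lies within the frame."""
        for xy in (self.head, self.tail):
            present = np.isfinite(xy).all(axis=1)
            p = xy[present]
            if p.size and (
                (p[:, 0] < 0).any()
                or (p[:, 0] >= geometry.width_px).any()
                or (p[:, 1] < 0).any()
                or (p[:, 1] >= geometry.height_px).any()
            ):
                raise ValidationError("tag coordinates outside frame bounds")

    def equals(self, other: "TagTrack") -> bool:
        return (
            np.array_equal(self.head, other.head, equal_nan=True)
            and np.array_equal(self.tail, other.tail, equal_nan=True)
            and np.array_equal(self.head_detected, other.head_detected)
            and np.array_equal(self.tail_detected, other.tail_detected)
            and np.array_equal(self.head_interpolated, other.head_interpolated)
            and np.array_equal(self.tail_interpolated, other.tail_interpolated)
        )


@dataclass(frozen=True)
class Correction:
    """One manual fix: place a tag (or the object) at (x, y) from a frame on."""

    frame_index: int
    tag: str  # head | tail | object
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.tag not in ("head", "tail", "object"):
            raise ValidationError("tag must be head, tail or object")


@dataclass
class CorrectionSet:
    corrections: list[Correction] = field(default_factory=list)

    def __iter__(self):
        return iter(self.corrections)

    def __len__(self) -> int:
        return len(self.corrections)


@dataclass
class ObjectTrack:
    """Piecewise-constant per-frame object position.

    Starts at the arena center and jumps to each corrected position from that
    correction's frame onward (when the animal pushes the object, the corrected
    position becomes the new reference center).
    """

    object_xy: np.ndarray  # (n_frames, 2)

    def __post_init__(self) -> None:
        self.object_xy = np.asarray(self.object_xy, dtype=float).reshape(-1, 2)

    @property
    def n_frames(self) -> int:
        return self.object_xy.shape[0]

    @classmethod
    def constant(cls, n_frames: int, xy: Sequence[float]) -> "ObjectTrack":
        return cls(np.tile(np.asarray(xy, dtype=float), (n_frames, 1)))


_TRACK_COLUMNS = [
    "frame",
    "head_x",
    "head_y",
    "head_detected",
    "tail_x",
    "tail_y",
    "tail_detected",
]


def read_track_csv(path: str | Path) -> TagTrack:
    """Read a tag track from CSV.

    Required columns: frame, head_x, head_y, head_detected, tail_x, tail_y,
    tail_detected; optional head_interpolated / tail_interpolated. Frame
    indices must run 0, 1, 2, ... without gaps.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise TrackFormatError(f"empty track file: {path}") from exc
    missing = [c for c in _TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"track file missing columns: {missing}")
    n = len(df)
    if n and not np.array_equal(df["frame"].to_numpy(), np.arange(n)):
        raise ValidationError("frame index must be contiguous from 0")
    head = df[["head_x", "head_y"]].to_numpy(dtype=float)
    tail = df[["tail_x", "tail_y"]].to_numpy(dtype=float)
    head_det = df["head_detected"].to_numpy().astype(bool)
    tail_det = df["tail_detected"].to_numpy().astype(bool)
    # a cleared flag wins over any stale coordinate
    head[~head_det] = np.nan
    tail[~tail_det] = np.nan
    if np.isnan(head[head_det]).any() or np.isnan(tail[tail_det]).any():
        raise ValidationError("detected flag set but coordinate missing")
    kwargs = {}
    for col in ("head_interpolated", "tail_interpolated"):
        if col in df.columns:
            kwargs[col] = df[col].to_numpy().astype(bool)
    return TagTrack(head, tail, head_det, tail_det, **kwargs)


def write_track_csv(track: TagTrack, path: str | Path) -> None:
    """Write a track to CSV; missing tags become empty fields with flag 0.

    Coordinates are serialized at full precision (round-trips bit-exactly).
    """
    df = pd.DataFrame(
        {
            "frame": np.arange(track.n_frames),
            "head_x": track.head[:, 0],
            "head_y": track.head[:, 1],
            "head_detected": track.head_detected.astype(int),
            "tail_x": track.tail[:, 0],
            "tail_y": track.tail[:, 1],
            "tail_detected": track.tail_detected.astype(int),
            "head_interpolated": track.head_interpolated.astype(int),
            "tail_interpolated": track.tail_interpolated.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g", na_rep="")


def read_corrections_csv(path: str | Path) -> CorrectionSet:
    """Read a correction CSV with columns frame, tag, x, y."""
    df = pd.read_csv(path)
    missing = [c for c in ("frame", "tag", "x", "y") if c not in df.columns]
    if missing:
        raise TrackFormatError(f"correction file missing columns: {missing}")
    return CorrectionSet(
        [
            Correction(int(r.frame), str(r.tag), float(r.x), float(r.y))
            for r in df.itertuples()
        ]
    )


def apply_corrections(
    track: TagTrack,
    corrections: CorrectionSet | Iterable[Correction],
    center_xy: Sequence[float] = (480.0, 270.0),
) -> tuple[TagTrack, ObjectTrack]:
    """Apply manual tag corrections and build the object-position timeline.

    Head/tail corrections overwrite the tag position at that single frame and
    mark it detected. Object corrections do not touch the track: they move the
    object reference from the correction frame onward (piecewise constant,
    initialized at ``center_xy``). Later corrections to the same (frame, tag)
    win. Idempotent for a fixed correction set.
    """
    out = track.copy()
    n = track.n_frames
    obj = ObjectTrack.constant(n, center_xy)
    for c in corrections:
        if not (0 <= c.frame_index < n):
            raise ValidationError(
                f"correction frame {c.frame_index} outside [0, {n})"
            )
        if c.tag == "object":
            obj.object_xy[c.frame_index :] = (c.x, c.y)
        elif c.tag == "head":
            out.head[c.frame_index] = (c.x, c.y)
            out.head_detected[c.frame_index] = True
            out.head_interpolated[c.frame_index] = False
        else:
            out.tail[c.frame_index] = (c.x, c.y)
            out.tail_detected[c.frame_index] = True
            out.tail_interpolated[c.frame_index] = False
    return out, obj


def meta_to_dict(meta: TrialMeta) -> dict:
    return dataclasses.asdict(meta)


def read_meta_csv(path: str | Path) -> list[TrialMeta]:
    """Read trial metadata rows (subject_id, species, phase, condition, ...)."""
    df = pd.read_csv(path)
    metas = []
    for r in df.itertuples():
        metas.append(
            TrialMeta(
                subject_id=str(r.subject_id),
                species=str(r.species),
                phase=int(r.phase),
                condition=str(r.condition),
                testing_time=str(getattr(r, "testing_time", "morning")),
                incubation_group=str(
                    getattr(r, "incubation_group", "presumed_male")
                ),
            )
        )
    return metas


def geometry_to_dict(g: ArenaGeometry) -> dict:
    d = dataclasses.asdict(g)
    d["center_xy"] = list(d["center_xy"])
    return d


def geometry_from_dict(d: dict) -> ArenaGeometry:
    d = dict(d)
    d["center_xy"] = tuple(d.get("center_xy", (480.0, 270.0)))
    return ArenaGeometry(**d)


def dump_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")
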