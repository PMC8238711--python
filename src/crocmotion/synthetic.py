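"""Ground-truthed synthetic trials.

A :class:`BehaviorScript` is an ordered list of bouts — rest, walk, head
turn, shelter — for a hatchling carrying a head tag and a tail-base tag in a
960x540 arena filmed at 60 f/s. :func:`simulate_trajectory` turns a script
into exact per-frame tag positions plus per-bout summaries (true walked path
length, true hidden seconds); :func:`render_frames` draws the corresponding
frames (textured cardboard background, anti-aliased colored discs, discs
omitted while hidden). Together they close the loop: every stage of the
pipeline can be validated against scripted ground truth without any video.

Kinematics: a walk bout translates head and tail rigidly along a smoothly
jittering heading (jitter well inside the 45-degree classification bound, so
scripted walking is classifiable as walking); a head-turn bout rotates the
head about the fixed tail-base (a head turn is performed from a stable
position); rest holds both tags with sub-threshold Gaussian jitter; a shelter
bout hides the tags. Walls reflect the heading, so the animal stays inside
the arena.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .core_io import ArenaGeometry, ValidationError
from .tag_detection import ColorSpec, DEFAULT_COLOR_SPECS

__all__ = [
    "Bout",
    "BehaviorScript",
    "GroundTruth",
    "simulate_trajectory",
    "render_frames",
    "write_frames",
    "make_background",
    "make_correlated_pair",
    "random_script",
]

BOUT_KINDS = ("rest", "walk", "head_turn", "shelter")

#: Disc radius of the rendered 1-cm sticker, px (1 cm at 1.278 mm/px ~ 8 px
#: diameter).
TAG_RADIUS_PX = 4.0

_TAG_RGB = {
    "red": (204, 31, 31),
    "green": (41, 191, 61),
    "blue": (41, 82, 214),
}
_CARDBOARD_RGB = (181.0, 156.0, 127.0)
_WALL_MARGIN_PX = 20.0


@dataclass(frozen=True)
class Bout:
    kind: str
    duration_frames: int
    speed_px_per_frame: float = 0.0  # walk
    turn_deg_per_frame: float = 0.0  # head_turn

    def __post_init__(self) -> None:
        if self.kind not in BOUT_KINDS:
            raise ValidationError(f"bout kind must be one of {BOUT_KINDS}")
        if self.duration_frames < 1:
            raise ValidationError("bout duration must be >= 1 frame")


@dataclass
class BehaviorScript:
    """Scripted bout sequence plus the animal's starting pose."""

    bouts: list[Bout]
    start_head_xy: tuple[float, float] = (520.0, 270.0)
    start_tail_xy: tuple[float, float] = (480.0, 270.0)
    body_length_px: float = 40.0

    def __post_init__(self) -> None:
        if not self.bouts:
            raise ValidationError("script needs at least one bout")
        if self.body_length_px <= 0:
            raise ValidationError("body_length_px must be > 0")

    @property
    def n_frames(self) -> int:
        return sum(b.duration_frames for b in self.bouts)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "start_head_xy": list(self.start_head_xy),
            "start_tail_xy": list(self.start_tail_xy),
            "body_length_px": self.body_length_px,
            "bouts": [
                {
                    "kind": b.kind,
                    "duration_frames": b.duration_frames,
                    "speed_px_per_frame": b.speed_px_per_frame,
                    "turn_deg_per_frame": b.turn_deg_per_frame,
                }
                for b in self.bouts
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "BehaviorScript":
        doc = json.loads(Path(path).read_text())
        return cls(
            bouts=[Bout(**b) for b in doc["bouts"]],
            start_head_xy=tuple(doc.get("start_head_xy", (520.0, 270.0))),
            start_tail_xy=tuple(doc.get("start_tail_xy", (480.0, 270.0))),
            body_length_px=float(doc.get("body_length_px", 40.0)),
        )


@dataclass
class BoutSummary:
    kind: str
    start_frame: int
    duration_frames: int
    path_length_px: float  # head path length during walk bouts, else 0
    hidden_s: float  # seconds hidden during shelter bouts, else 0


@dataclass
class GroundTruth:
    """Scripted per-frame tag positions and the per-bout oracle log."""

    head: np.ndarray  # (n, 2)
    tail: np.ndarray  # (n, 2)
    hidden: np.ndarray  # (n,) bool — both tags concealed
    bouts: list[BoutSummary] = field(default_factory=list)
    fps: float = 60.0

    @property
    def n_frames(self) -> int:
        return self.head.shape[0]

    @property
    def total_walk_path_px(self) -> float:
        return sum(b.path_length_px for b in self.bouts if b.kind == "walk")

    @property
    def total_hidden_s(self) -> float:
        return sum(b.hidden_s for b in self.bouts)


def _reflect_heading(pos: np.ndarray, heading: float, step: float,
                     lo: np.ndarray, hi: np.ndarray) -> float:
    """Flip heading components that would carry ``pos`` out of [lo, hi]."""
    dx = step * math.cos(heading)
    dy = step * math.sin(heading)
    nxt = pos + (dx, dy)
    if nxt[0] < lo[0] or nxt[0] > hi[0]:
        heading = math.pi - heading
    nxt_y = pos[1] + step * math.sin(heading)
    if nxt_y < lo[1] or nxt_y > hi[1]:
        heading = -heading
    return heading


def simulate_trajectory(
    script: BehaviorScript,
    geometry: ArenaGeometry = ArenaGeometry(),
    seed: int = 0,
) -> GroundTruth:
    """Execute a behavior script into exact per-frame tag positions.

    Deterministic for a fixed (script, geometry, seed). Wall handling is
    reflective with a safety margin so both tags stay strictly inside the
    frame; a script whose starting pose already violates the margin raises.
    """
    rng = np.random.default_rng(seed)
    head = np.asarray(script.start_head_xy, dtype=float).copy()
    tail = np.asarray(script.start_tail_xy, dtype=float).copy()
    lo = np.array([_WALL_MARGIN_PX, _WALL_MARGIN_PX])
    hi = np.array(
        [geometry.width_px - _WALL_MARGIN_PX, geometry.height_px - _WALL_MARGIN_PX]
    )
    for p, name in ((head, "head"), (tail, "tail")):
        if (p < lo).any() or (p > hi).any():
            raise ValidationError(f"start_{name}_xy outside arena margin")

    n = script.n_frames
    heads = np.empty((n, 2))
    tails = np.empty((n, 2))
    hidden = np.zeros(n, dtype=bool)
    bouts: list[BoutSummary] = []
    heading = math.atan2(head[1] - tail[1], head[0] - tail[0])

    f = 0
    for bout in script.bouts:
        path = 0.0
        hid_frames = 0
        for _ in range(bout.duration_frames):
            if bout.kind == "walk":
                heading += math.radians(rng.normal(0.0, 0.5))
                heading = _reflect_heading(head, heading, bout.speed_px_per_frame,
                                           lo, hi)
                heading = _reflect_heading(tail, heading, bout.speed_px_per_frame,
                                           lo, hi)
                step = bout.speed_px_per_frame * np.array(
                    [math.cos(heading), math.sin(heading)]
                )
                head += step
                tail += step
                path += bout.speed_px_per_frame
            elif bout.kind == "head_turn":
                rel = head - tail
                ang = math.radians(bout.turn_deg_per_frame)
                ca, sa = math.cos(ang), math.sin(ang)
                rel = np.array([ca * rel[0] - sa * rel[1],
                                sa * rel[0] + ca * rel[1]])
                # clamp the swung head inside the margin by shrinking the arm
                cand = tail + rel
                if (cand < lo).any() or (cand > hi).any():
                    rel *= 0.95
                    cand = tail + rel
                head = np.clip(cand, lo, hi)
            elif bout.kind == "rest":
                head = np.clip(head + rng.normal(0.0, 0.2, size=2), lo, hi)
                tail = np.clip(tail + rng.normal(0.0, 0.2, size=2), lo, hi)
            else:  # shelter
                hidden[f] = True
                hid_frames += 1
            heads[f] = head
            tails[f] = tail
            f += 1
        bouts.append(
            BoutSummary(
                kind=bout.kind,
                start_frame=f - bout.duration_frames,
                duration_frames=bout.duration_frames,
                path_length_px=path,
                hidden_s=hid_frames / geometry.fps,
            )
        )
    return GroundTruth(heads, tails, hidden, bouts, fps=geometry.fps)


def make_background(
    geometry: ArenaGeometry, rng: np.random.Generator, noise_amp: float = 8.0
) -> np.ndarray:
    """Textured cardboard-tone background, uint8 (H, W, 3).

    Low-amplitude pixel noise around a matte cardboard color: enough texture
    to exercise the segmentation, but saturation stays far below the tag
    thresholds.
    """
    base = np.array(_CARDBOARD_RGB)
    noise = rng.uniform(-noise_amp, noise_amp, size=(geometry.height_px,
                                                    geometry.width_px, 1))
    img = base[None, None, :] + noise
    return np.clip(img, 0, 255).astype(np.uint8)


def _draw_disc(img: np.ndarray, cx: float, cy: float, radius: float,
               color: Sequence[float], supersample: int = 4) -> None:
    """Alpha-blend an anti-aliased disc into ``img`` via supersampled
    coverage of each pixel."""
    h, w = img.shape[:2]
    pad = int(math.ceil(radius)) + 1
    x0 = max(int(math.floor(cx)) - pad, 0)
    x1 = min(int(math.ceil(cx)) + pad + 1, w)
    y0 = max(int(math.floor(cy)) - pad, 0)
    y1 = min(int(math.ceil(cy)) + pad + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    ss = supersample
    offs = (np.arange(ss) + 0.5) / ss
    xs = np.arange(x0, x1)[:, None] + offs[None, :]  # (nx, ss) sample x coords
    ys = np.arange(y0, y1)[:, None] + offs[None, :]
    dx2 = (xs - cx) ** 2  # (nx, ss)
    dy2 = (ys - cy) ** 2  # (ny, ss)
    inside = (dy2[:, None, :, None] + dx2[None, :, None, :]) <= radius * radius
    cov = inside.mean(axis=(2, 3))  # (ny, nx) coverage in [0, 1]
    patch = img[y0:y1, x0:x1].astype(np.float64)
    col = np.asarray(color, dtype=float)
    blended = patch * (1.0 - cov[..., None]) + col[None, None, :] * cov[..., None]
    img[y0:y1, x0:x1] = np.clip(np.rint(blended), 0, 255).astype(np.uint8)


def render_frames(
    truth: GroundTruth,
    geometry: ArenaGeometry = ArenaGeometry(),
    head_color: str = "red",
    tail_color: str = "green",
    tag_radius_px: float = TAG_RADIUS_PX,
    partial_occlusion: bool = False,
    seed: int = 0,
) -> Iterator[np.ndarray]:
    """Yield one rendered RGB uint8 frame per ground-truth frame.

    Hidden frames omit both discs (or only the tail disc when
    ``partial_occlusion`` is set, emulating an animal half under the shelter
    tile). The background texture is drawn once per trial. Frames stream
    lazily: a full 10-minute trial never has to exist in memory at once.
    """
    rng = np.random.default_rng(seed)
    background = make_background(geometry, rng)
    head_rgb = _TAG_RGB[head_color]
    tail_rgb = _TAG_RGB[tail_color]
    buf = np.empty_like(background)
    for i in range(truth.n_frames):
        np.copyto(buf, background)
        if not truth.hidden[i] or partial_occlusion:
            _draw_disc(buf, truth.head[i, 0], truth.head[i, 1],
                       tag_radius_px, head_rgb)
        if not truth.hidden[i]:
            _draw_disc(buf, truth.tail[i, 0], truth.tail[i, 1],
                       tag_radius_px, tail_rgb)
        yield buf.copy()


def write_frames(frames: Iterator[np.ndarray], out_dir: str | Path) -> int:
    """Write streamed frames as zero-padded PNGs; returns the frame count."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = 0
    for i, frame in enumerate(frames):
        iio.imwrite(out / f"frame_{i:06d}.png", frame)
        n = i + 1
    return n


def make_correlated_pair(
    n: int, r: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two vectors whose *sample* Pearson correlation equals ``r`` exactly.

    A random normal vector is standardized; a second is residualized against
    it, standardized, and recombined with weights r and sqrt(1 - r^2). Used
    to reconstruct correlation-determined PCA quantities without raw data.
    """
    if n < 3:
        raise ValidationError("need n >= 3")
    if not abs(r) < 1:
        raise ValidationError("need |r| < 1")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    e = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    e = e - e.mean()
    e = e - (e @ x) / (x @ x) * x  # orthogonal to x (and mean-zero)
    e = e / e.std(ddof=1)
    y = r * x + math.sqrt(1.0 - r * r) * e
    return x, y


def random_script(
    geometry: ArenaGeometry,
    rng: np.random.Generator,
    n_frames: int = 3600,
    kinds: Sequence[str] = ("rest", "walk", "head_turn", "shelter"),
) -> BehaviorScript:
    """Draw a random plausible bout script of exactly ``n_frames`` frames.

    Bout durations are 1-10 s, walk speeds 0.5-3 px/frame (0.04-0.23 m/s at
    1.278 mm/px, hatchling walking pace), head turns 1-4 deg/frame.
    """
    margin = _WALL_MARGIN_PX + 10.0
    cx = rng.uniform(margin + 50, geometry.width_px - margin - 50)
    cy = rng.uniform(margin + 50, geometry.height_px - margin - 50)
    ang = rng.uniform(0, 2 * math.pi)
    body = 40.0
    head_xy = (cx + body * math.cos(ang) / 2, cy + body * math.sin(ang) / 2)
    tail_xy = (cx - body * math.cos(ang) / 2, cy - body * math.sin(ang) / 2)
    bouts: list[Bout] = []
    left = n_frames
    while left > 0:
        dur = int(min(left, rng.integers(60, 601)))
        kind = str(rng.choice(list(kinds)))
        if kind == "walk":
            bouts.append(Bout("walk", dur,
                              speed_px_per_frame=float(rng.uniform(0.5, 3.0))))
        elif kind == "head_turn":
            bouts.append(Bout("head_turn", dur,
                              turn_deg_per_frame=float(rng.uniform(1.0, 4.0)
                                                       * rng.choice([-1, 1]))))
        else:
            bouts.append(Bout(kind, dur))
        left -= dur
    return BehaviorScript(bouts=bouts, start_head_xy=head_xy,
                          start_tail_xy=tail_xy, body_length_px=body)


def expected_metrics(truth: GroundTruth) -> dict:
    """Oracle summary of a ground truth, for the simulate CLI output."""
    return {
        "n_frames": truth.n_frames,
        "total_walk_path_px": truth.total_walk_path_px,
        "total_hidden_s": truth.total_hidden_s,
        "n_bouts": len(truth.bouts),
    }
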