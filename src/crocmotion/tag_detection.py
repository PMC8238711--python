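"""Color-sticker detection: locate the head and tail-base tags per frame.

Each tag is a small colored adhesive disc (red or blue on the head, green on
the tail-base). Detection thresholds the frame in hue/saturation/value, labels
connected components (8-connectivity), discards components smaller than a
minimum area, and returns the centroid of the largest surviving component.

The hue computation is restricted to pixels that already pass the saturation
and value thresholds; on a matte cardboard background that is a handful of
pixels per frame, which keeps full-resolution tracking fast enough to process
whole trials at well above real time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .core_io import TagTrack, ValidationError

__all__ = [
    "ColorSpec",
    "TagDetection",
    "DEFAULT_COLOR_SPECS",
    "detect_tags_in_frame",
    "track_sequence",
    "interpolate_gaps",
    "rgb_to_hsv_pixels",
]

logger = logging.getLogger(__name__)

_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class ColorSpec:
    """HSV gate for one tag color.

    ``hue_range`` is in degrees [0, 360) and may wrap (e.g. red = (350, 10)).
    """

    tag: str  # "head" | "tail"
    hue_range: tuple[float, float]
    saturation_min: float = 0.5
    value_min: float = 0.3
    min_blob_area_px: int = 5

    def __post_init__(self) -> None:
        if self.tag not in ("head", "tail"):
            raise ValidationError("tag must be 'head' or 'tail'")
        if not (0.0 <= self.saturation_min <= 1.0 and 0.0 <= self.value_min <= 1.0):
            raise ValidationError("saturation_min and value_min must be in [0,1]")
        if self.min_blob_area_px < 1:
            raise ValidationError("min_blob_area_px must be >= 1")

    def hue_mask(self, hue_deg: np.ndarray) -> np.ndarray:
        lo, hi = self.hue_range
        if lo <= hi:
            return (hue_deg >= lo) & (hue_deg <= hi)
        return (hue_deg >= lo) | (hue_deg <= hi)  # wrapping interval


#: Defaults matching the sticker colors: red head, green tail-base. A blue
#: head sticker uses hue_range=(200, 260).
DEFAULT_COLOR_SPECS: tuple[ColorSpec, ColorSpec] = (
    ColorSpec(tag="head", hue_range=(350.0, 10.0)),
    ColorSpec(tag="tail", hue_range=(90.0, 150.0)),
)

BLUE_HEAD_SPEC = ColorSpec(tag="head", hue_range=(200.0, 260.0))


@dataclass
class TagDetection:
    """Per-frame detection result for one tag."""

    tag: str
    centroid_xy: tuple[float, float] | None
    blob_area_px: int = 0


def rgb_to_hsv_pixels(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """HSV (hue in degrees, s and v in [0,1]) for an (n, 3) uint8 pixel list."""
    rgb = np.asarray(rgb, dtype=np.float64)
    r, g, b = rgb[:, 0], rgb[:, 1], rgb[:, 2]
    mx = rgb.max(axis=1)
    mn = rgb.min(axis=1)
    delta = mx - mn
    v = mx / 255.0
    s = np.where(mx > 0, delta / np.maximum(mx, 1e-12), 0.0)
    h = np.zeros_like(mx)
    nz = delta > 0
    rmax = nz & (mx == r)
    gmax = nz & ~rmax & (mx == g)
    bmax = nz & ~rmax & ~gmax
    h[rmax] = 60.0 * ((g[rmax] - b[rmax]) / delta[rmax])
    h[gmax] = 60.0 * ((b[gmax] - r[gmax]) / delta[gmax]) + 120.0
    h[bmax] = 60.0 * ((r[bmax] - g[bmax]) / delta[bmax]) + 240.0
    h = np.mod(h, 360.0)
    return h, s, v


def _largest_blob_centroid(
    ys: np.ndarray,
    xs: np.ndarray,
    min_area: int,
    reference_xy: Sequence[float],
) -> tuple[tuple[float, float] | None, int]:
    """Label candidate pixels (8-connectivity) inside their bounding box and
    return the centroid of the largest component of at least ``min_area``
    pixels. Equal-area ties go to the component whose centroid is nearest
    ``reference_xy`` (previous tag position, else arena center)."""
    if ys.size == 0:
        return None, 0
    y0, x0 = ys.min(), xs.min()
    sub = np.zeros((ys.max() - y0 + 1, xs.max() - x0 + 1), dtype=bool)
    sub[ys - y0, xs - x0] = True
    labels, n_lab = ndimage.label(sub, structure=_EIGHT_CONN)
    if n_lab == 0:
        return None, 0
    lab_at = labels[ys - y0, xs - x0]
    areas = np.bincount(lab_at, minlength=n_lab + 1)[1:]
    keep = np.flatnonzero(areas >= min_area) + 1
    if keep.size == 0:
        return None, 0
    best_area = areas[keep - 1].max()
    tied = keep[areas[keep - 1] == best_area]
    best = None
    best_d = np.inf
    rx, ry = float(reference_xy[0]), float(reference_xy[1])
    for lab in tied:
        sel = lab_at == lab
        # +0.5: pixel (x, y) covers [x, x+1) x [y, y+1), centroid uses centers
        cx = float(xs[sel].mean()) + 0.5
        cy = float(ys[sel].mean()) + 0.5
        d = (cx - rx) ** 2 + (cy - ry) ** 2
        if d < best_d:
            best_d = d
            best = (cx, cy)
    return best, int(best_area)


def detect_tags_in_frame(
    frame: np.ndarray,
    specs: Sequence[ColorSpec] = DEFAULT_COLOR_SPECS,
    prev_xy: Mapping[str, tuple[float, float]] | None = None,
    center_xy: Sequence[float] | None = None,
) -> list[TagDetection]:
    """Detect each spec's tag in a single RGB frame.

    Returns one :class:`TagDetection` per spec, with ``centroid_xy=None`` when
    no connected component of matching color reaches ``min_blob_area_px``.
    ``prev_xy`` (tag -> last known position) only breaks exact area ties.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValidationError("frame must be an (H, W, 3) RGB image")
    h_px, w_px = frame.shape[:2]
    if center_xy is None:
        center_xy = (w_px / 2.0, h_px / 2.0)
    if frame.dtype != np.uint8:
        frame = np.clip(frame, 0, 255).astype(np.uint8)

    # Cheap integer prefilter: saturation/value gate at the loosest thresholds
    # across specs (rounded down, so it never rejects a true candidate); hue
    # and the exact per-spec thresholds are applied only to surviving pixels.
    r, g, b = frame[:, :, 0], frame[:, :, 1], frame[:, :, 2]
    mx = np.maximum(np.maximum(r, g), b).astype(np.uint16)
    mn = np.minimum(np.minimum(r, g), b)
    s_lo = int(min(sp.saturation_min for sp in specs) * 255)
    v_lo = max(int(min(sp.value_min for sp in specs) * 255), 1)
    # (mx - mn)*255 >= s_lo*mx  <=>  s = (mx-mn)/mx >= s_lo/255  (mx > 0);
    # products stay within uint16 (255*255 = 65025)
    cand = ((mx - mn) * np.uint16(255) >= np.uint16(s_lo) * mx) & (mx >= v_lo)
    ys, xs = np.nonzero(cand)
    if ys.size:
        hue, sat, val = rgb_to_hsv_pixels(frame[ys, xs])
    else:
        hue = sat = val = np.empty(0)

    out = []
    for sp in specs:
        m = (
            sp.hue_mask(hue)
            & (sat >= sp.saturation_min)
            & (val >= sp.value_min)
        )
        ref = None
        if prev_xy is not None:
            ref = prev_xy.get(sp.tag)
        if ref is None:
            ref = center_xy
        centroid, area = _largest_blob_centroid(
            ys[m], xs[m], sp.min_blob_area_px, ref
        )
        out.append(TagDetection(tag=sp.tag, centroid_xy=centroid, blob_area_px=area))
    return out


def _iter_frame_dir(path: Path) -> Iterator[np.ndarray]:
    import imageio.v3 as iio

    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg")
    )
    if not files:
        raise ValidationError(f"no PNG/JPG frames found in {path}")
    for p in files:
        yield np.asarray(iio.imread(p))[..., :3]


def track_sequence(
    frames: str | Path | Iterable[np.ndarray],
    specs: Sequence[ColorSpec] = DEFAULT_COLOR_SPECS,
    center_xy: Sequence[float] | None = None,
) -> TagTrack:
    """Run detection over an ordered frame source and assemble a TagTrack.

    ``frames`` is a directory of numbered PNG/JPG frames or any iterable of
    RGB arrays (all with identical dimensions). Logs how many frames had
    0/1/2 tags detected.
    """
    if isinstance(frames, (str, Path)):
        frames = _iter_frame_dir(Path(frames))
    head: list[tuple[float, float]] = []
    tail: list[tuple[float, float]] = []
    prev: dict[str, tuple[float, float]] = {}
    shape = None
    counts = [0, 0, 0]
    nan = (np.nan, np.nan)
    for frame in frames:
        frame = np.asarray(frame)
        if shape is None:
            shape = frame.shape
        elif frame.shape != shape:
            raise ValidationError(
                f"inconsistent frame size {frame.shape} vs {shape}"
            )
        dets = detect_tags_in_frame(frame, specs, prev_xy=prev, center_xy=center_xy)
        got = 0
        for det in dets:
            lst = head if det.tag == "head" else tail
            if det.centroid_xy is not None:
                lst.append(det.centroid_xy)
                prev[det.tag] = det.centroid_xy
                got += 1
            else:
                lst.append(nan)
        counts[got] += 1
    if shape is None:
        raise ValidationError("frame source yielded no frames")
    head_arr = np.asarray(head, dtype=float).reshape(-1, 2)
    tail_arr = np.asarray(tail, dtype=float).reshape(-1, 2)
    logger.info(
        "tracked %d frames: %d with 0 tags, %d with 1, %d with 2",
        len(head),
        counts[0],
        counts[1],
        counts[2],
    )
    return TagTrack(
        head_arr,
        tail_arr,
        np.isfinite(head_arr).all(axis=1),
        np.isfinite(tail_arr).all(axis=1),
    )


def _fill_gaps_one_tag(
    xy: np.ndarray, det: np.ndarray, interp: np.ndarray, max_gap: int
) -> None:
    """In-place linear interpolation of internal missing runs of length
    <= max_gap; boundary runs stay missing."""
    n = det.size
    i = 0
    while i < n:
        if det[i]:
            i += 1
            continue
        j = i
        while j < n and not det[j]:
            j += 1
        run = j - i
        if i > 0 and j < n and run <= max_gap:
            a, b = xy[i - 1], xy[j]
            for k in range(run):
                t = (k + 1) / (run + 1)
                xy[i + k] = a + t * (b - a)
            det[i:j] = True
            interp[i:j] = True
        i = j


def interpolate_gaps(track: TagTrack, max_gap: int = 0) -> TagTrack:
    """Fill short detection gaps by linear interpolation.

    Runs of missing frames of length <= ``max_gap`` that are flanked by
    detections on both sides are filled per coordinate and flagged as
    interpolated; longer runs and runs touching the track boundary stay
    missing. The default ``max_gap=0`` leaves the track untouched, matching a
    manually-corrected, no-imputation workflow. Shelter scoring refuses
    interpolated tracks, since imputation would hide concealment.
    """
    if max_gap < 0:
        raise ValidationError("max_gap must be >= 0")
    out = track.copy()
    if max_gap == 0:
        return out
    _fill_gaps_one_tag(out.head, out.head_detected, out.head_interpolated, max_gap)
    _fill_gaps_one_tag(out.tail, out.tail_detected, out.tail_interpolated, max_gap)
    return out
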