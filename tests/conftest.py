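import numpy as np
import pytest

from crocmotion.core_io import ArenaGeometry, TagTrack
from crocmotion.synthetic import _draw_disc, make_background

RED = (204, 31, 31)
GREEN = (41, 191, 61)


@pytest.fixture
def geometry() -> ArenaGeometry:
    return ArenaGeometry()


@pytest.fixture
def small_geometry() -> ArenaGeometry:
    """Quarter-scale arena for fast frame-level tests."""
    return ArenaGeometry(width_px=240, height_px=136, center_xy=(120.0, 68.0))


def make_frame(geometry, discs, seed=0, flat=False):
    """Render a test frame: cardboard background plus (cx, cy, radius, rgb)
    discs; ``flat=True`` suppresses the background texture."""
    rng = np.random.default_rng(seed)
    img = make_background(geometry, rng, noise_amp=0.0 if flat else 8.0)
    for cx, cy, radius, rgb in discs:
        _draw_disc(img, cx, cy, radius, rgb)
    return img


@pytest.fixture
def frame_factory():
    return make_frame


def random_track(rng, n, missing_head=0.1, missing_tail=0.15):
    """Random walk track with missing tags, mixed step scales, and a 50%
    chance of integer-rounded coordinates (to provoke exact angle ties)."""
    scale = rng.choice([3.0, 10.0, 50.0])
    head = np.cumsum(rng.normal(0, scale, (n, 2)), axis=0) + 480.0
    tail = head + rng.normal(0, 5.0, (n, 2))
    if rng.random() < 0.5:
        head = np.rint(head)
        tail = np.rint(tail)
    hd = rng.random(n) > missing_head
    td = rng.random(n) > missing_tail
    head[~hd] = np.nan
    tail[~td] = np.nan
    return TagTrack(head, tail, hd, td)


@pytest.fixture
def random_track_factory():
    return random_track
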