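"""Shared fixtures: hand-drawn glyphs and small synthetic walkers."""

from __future__ import annotations

import numpy as np
import pytest

from gaitspeed import BinarySilhouette, WalkerParams, generate_sequence


def make_silhouette(mask, frame_index=0):
    return BinarySilhouette(np.asarray(mask, dtype=bool), frame_index)


@pytest.fixture
def solid_rect():
    """A 30-row x 10-col solid rectangle on a 40x20 canvas."""
    m = np.zeros((40, 20), dtype=bool)
    m[5:35, 6:16] = True
    return make_silhouette(m)


@pytest.fixture
def single_pixel():
    m = np.zeros((9, 9), dtype=bool)
    m[4, 7] = True
    return make_silhouette(m)


@pytest.fixture
def l_glyph():
    """An L-shaped glyph on a 12x12 grid."""
    m = np.zeros((12, 12), dtype=bool)
    m[2:11, 3:5] = True
    m[9:11, 3:10] = True
    return make_silhouette(m)


@pytest.fixture
def t_glyph():
    """A T: wide bar rows 0-9, thin stem cols 4-5 rows 10-29 (box height 30)."""
    m = np.zeros((30, 10), dtype=bool)
    m[0:10, 0:10] = True
    m[10:30, 4:6] = True
    return make_silhouette(m)


def draw_legs(m, apex_row, bottom_row, left_foot, right_foot, width=3):
    """Two ``width``-px-wide straight legs from a common apex."""
    for r in range(apex_row, bottom_row + 1):
        frac = (r - apex_row) / (bottom_row - apex_row)
        for foot in (left_foot, right_foot):
            center = 8.5 + frac * (foot - 8.5)
            c0 = int(round(center - width / 2 + 0.5))
            m[r, c0:c0 + width] = True
    return m


def make_inverted_v(speckle=False):
    """Hip bar + two 3-px legs from a common apex, feet 11 px apart.

    The solid bar keeps the crotch below the bounding-box midline (as a
    real torso does), so the lower-half crop's between-legs gap is
    enclosed from above and the hole fill has a triangle to find.
    Optionally adds a 2-pixel speckle near the left foot (disconnected
    from both legs) to exercise the denoising rule.
    """
    m = np.zeros((48, 17), dtype=bool)
    m[0:26, 4:13] = True  # hip/trunk bar
    draw_legs(m, 25, 45, 3, 14)  # feet centers 11 px apart
    if speckle:
        m[44, 1] = True
        m[45, 1] = True
    return make_silhouette(m)


def make_bare_v():
    """Legs only, apex at the top of its own box (no torso above)."""
    m = np.zeros((24, 17), dtype=bool)
    draw_legs(m, 2, 21, 3, 14)
    return make_silhouette(m)


@pytest.fixture
def inverted_v():
    return make_inverted_v()


@pytest.fixture
def inverted_v_speckled():
    return make_inverted_v(speckle=True)


@pytest.fixture(scope="session")
def walker_frames():
    """One mid-speed walker, 60 frames, reused across feature tests."""
    p = WalkerParams(gait_frequency=6 / 240, leg_swing_amplitude=0.30,
                     arm_swing_amplitude=0.69, seed=11)
    return p, generate_sequence(p, 60)
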