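"""Per-frame body measurements from binary walking silhouettes.

A lateral-view silhouette is a boolean foreground mask (row 0 = top,
0-based indices).  From each frame seven raw quantities are measured —
full-body height and width, mid-body width, lower-body width,
apparent-body area, full-body area and the area enclosed between the two
legs — and five dimensionless ratios are derived from them:

    HW1 = full-body height / full-body width
    HW2 = full-body height / mid-body width
    HW3 = full-body height / lower-body width
    A1  = apparent-body area / full-body area
    A2  = between-legs area / full-body area

Because every ratio divides one pixel dimension (or area) by another,
uniform image scaling — i.e. a change in subject-to-camera distance —
cancels out, which is what makes these features usable across recording
setups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as _bresenham_line
from skimage.measure import label as _cc_label

__all__ = [
    "BinarySilhouette",
    "BodyBox",
    "BodyMeasurements",
    "RatioFeatures",
    "EmptyFrameError",
    "FrameMeasurementError",
    "full_body_box",
    "band_box",
    "apparent_body_area",
    "between_legs_area",
    "measure_frame",
    "compute_ratios",
    "measure_sequence",
    "RATIO_NAMES",
    "MEASUREMENT_NAMES",
    "FEATURE_CSV_COLUMNS",
]

logger = logging.getLogger(__name__)

RATIO_NAMES = ("HW1", "HW2", "HW3", "A1", "A2")
MEASUREMENT_NAMES = (
    "full_body_height",
    "full_body_width",
    "mid_body_width",
    "lower_body_width",
    "apparent_body_area",
    "full_body_area",
    "between_legs_area",
)
FEATURE_CSV_COLUMNS = ("frame",) + MEASUREMENT_NAMES + RATIO_NAMES

#: default denoising threshold: lower-half components smaller than this
#: fraction of the largest component are treated as noise (swinging-hand
#: traces, segmentation speckle) and removed before the between-legs step.
DEFAULT_NOISE_FRACTION = 0.10


class EmptyFrameError(ValueError):
    """Raised when a frame contains no foreground pixels."""


class FrameMeasurementError(ValueError):
    """Raised when a frame cannot yield a valid set of measurements."""


@dataclass(frozen=True)
class BinarySilhouette:
    """One frame's boolean foreground mask (origin top-left, row-major)."""

    mask: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2 or mask.size == 0:
            raise ValueError("silhouette mask must be a non-empty 2D grid")
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class BodyBox:
    """Tight axis-aligned bounding box, 0-based, sizes in pixels."""

    top_row: int
    left_col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("box must have height >= 1 and width >= 1")
        if self.top_row < 0 or self.left_col < 0:
            raise ValueError("box must lie inside the image grid")

    @property
    def bottom_row(self) -> int:
        """Last row inside the box (inclusive)."""
        return self.top_row + self.height - 1

    @property
    def right_col(self) -> int:
        """Last column inside the box (inclusive)."""
        return self.left_col + self.width - 1

    def row_slice(self) -> slice:
        return slice(self.top_row, self.top_row + self.height)

    def col_slice(self) -> slice:
        return slice(self.left_col, self.left_col + self.width)


@dataclass(frozen=True)
class BodyMeasurements:
    """The seven raw per-frame quantities (pixels and pixels squared)."""

    full_body_height: int
    full_body_width: int
    mid_body_width: int
    lower_body_width: int
    apparent_body_area: int
    full_body_area: int
    between_legs_area: int

    def as_tuple(self) -> tuple[int, ...]:
        return (
            self.full_body_height,
            self.full_body_width,
            self.mid_body_width,
            self.lower_body_width,
            self.apparent_body_area,
            self.full_body_area,
            self.between_legs_area,
        )


@dataclass(frozen=True)
class RatioFeatures:
    """The five dimensionless per-frame features."""

    HW1: float
    HW2: float
    HW3: float
    A1: float
    A2: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.HW1, self.HW2, self.HW3, self.A1, self.A2)


def full_body_box(sil: BinarySilhouette) -> BodyBox:
    """Tight bounding box around all foreground pixels.

    The box height and width are the frame's full-body height and
    full-body width.  Raises :class:`EmptyFrameError` (naming the frame
    index) when the frame has no foreground at all.
    """
    rows = np.any(sil.mask, axis=1)
    cols = np.any(sil.mask, axis=0)
    if not rows.any():
        raise EmptyFrameError(f"empty frame (frame {sil.frame_index}): no foreground pixels")
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    return BodyBox(int(r0), int(c0), int(r1 - r0 + 1), int(c1 - c0 + 1))


def _band_rows(box: BodyBox, band: int, n_bands: int) -> tuple[int, int]:
    """Half-open absolute row range of a horizontal strip of ``box``.

    The box's vertical extent is split into ``n_bands`` near-equal
    contiguous strips top to bottom; strip ``i`` spans rows
    floor(i*H/n) .. floor((i+1)*H/n) relative to the box top.
    """
    h = box.height
    start = box.top_row + (band * h) // n_bands
    stop = box.top_row + ((band + 1) * h) // n_bands
    return start, stop


def band_box(
    sil: BinarySilhouette, box: BodyBox, band: int, n_bands: int
) -> BodyBox | None:
    """Tight bounding box of foreground within one horizontal band of ``box``.

    ``band_box(sil, box, 1, 3)`` yields the mid-body box (its width is the
    mid-body width); ``band_box(sil, box, 2, 3)`` the lower-body box.
    Returns ``None`` when the band contains no foreground; callers must
    treat the dependent width as an extraction failure for that frame.
    """
    if n_bands not in (2, 3):
        raise ValueError("n_bands must be 2 or 3")
    if not 0 <= band < n_bands:
        raise ValueError(f"band must lie in [0, {n_bands})")
    r0, r1 = _band_rows(box, band, n_bands)
    sub = sil.mask[r0:r1, box.col_slice()]
    if not sub.any():
        return None
    rows = np.flatnonzero(np.any(sub, axis=1))
    cols = np.flatnonzero(np.any(sub, axis=0))
    return BodyBox(
        int(r0 + rows[0]),
        int(box.left_col + cols[0]),
        int(rows[-1] - rows[0] + 1),
        int(cols[-1] - cols[0] + 1),
    )


def apparent_body_area(sil: BinarySilhouette) -> int:
    """Number of foreground (white) pixels in the frame."""
    return int(sil.mask.sum())


def _denoise(lower: np.ndarray, noise_fraction: float) -> np.ndarray:
    """Remove small connected components from the lower-half crop.

    Components (8-connectivity) whose area is below ``noise_fraction``
    times the largest component's area are deleted — a generalisation of
    dropping the single smallest disconnected object that stays robust
    when several speckles are present.
    """
    labels, n = _cc_label(lower, connectivity=2, return_num=True)
    if n == 0:
        return lower
    areas = np.bincount(labels.ravel())[1:]
    keep = areas >= noise_fraction * areas.max()
    return keep[labels - 1] & (labels > 0)


def _toe_points(lower: np.ndarray) -> tuple[tuple[int, int], tuple[int, int]]:
    """Locate the two toe points in a denoised lower-half crop.

    The toes are the bottom-most foreground pixels of the left-most and
    right-most leg components (ties broken toward the outer column).  When
    the legs form a single component it is split at the midpoint of its
    column extent and the bottom-most pixel of each half is used.
    """
    labels, n = _cc_label(lower, connectivity=2, return_num=True)
    if n == 0:
        raise FrameMeasurementError("no components remain in the lower half after denoising")

    def _bottom_most(mask: np.ndarray, prefer_left: bool) -> tuple[int, int]:
        rr, cc = np.nonzero(mask)
        bottom = rr.max()
        cols = cc[rr == bottom]
        return int(bottom), int(cols.min() if prefer_left else cols.max())

    if n >= 2:
        min_cols = ndimage.minimum(
            np.tile(np.arange(lower.shape[1]), (lower.shape[0], 1)),
            labels,
            index=np.arange(1, n + 1),
        )
        max_cols = ndimage.maximum(
            np.tile(np.arange(lower.shape[1]), (lower.shape[0], 1)),
            labels,
            index=np.arange(1, n + 1),
        )
        left_lab = 1 + int(np.argmin(min_cols))
        right_lab = 1 + int(np.argmax(max_cols))
        if left_lab == right_lab:
            n = 1  # one component spans both extremes; fall through to split
        else:
            left = _bottom_most(labels == left_lab, prefer_left=True)
            right = _bottom_most(labels == right_lab, prefer_left=False)
            return left, right

    cols = np.flatnonzero(np.any(lower, axis=0))
    mid = (cols[0] + cols[-1] + 1) // 2
    left_half = lower.copy()
    left_half[:, mid:] = False
    right_half = lower.copy()
    right_half[:, :mid] = False
    if not left_half.any() or not right_half.any():
        # degenerate: all mass on one side; treat the legs as closed
        p = _bottom_most(lower, prefer_left=True)
        return p, p
    return _bottom_most(left_half, True), _bottom_most(right_half, False)


def between_legs_area(
    sil: BinarySilhouette,
    box: BodyBox | None = None,
    noise_fraction: float = DEFAULT_NOISE_FRACTION,
) -> int:
    """Area (pixel count) of the region enclosed between the two legs.

    Operates on the lower half of the full-body box: (a) small
    disconnected objects are removed (see :func:`_denoise`), (b) the two
    toe points are located, (c) a straight (Bresenham) line is drawn
    between them on a working copy, (d) background regions not connected
    to the crop border are hole-filled, and (e) the pre-fill working image
    is subtracted; the remaining pixel count is the enclosed area.
    Returns 0 when the legs are closed (toes coincide or no gap encloses).
    """
    if box is None:
        box = full_body_box(sil)
    r0, r1 = _band_rows(box, 1, 2)
    lower = sil.mask[r0:r1, box.col_slice()]
    if not lower.any():
        raise FrameMeasurementError(
            f"lower half of the body box is empty (frame {sil.frame_index})"
        )
    lower = _denoise(lower, noise_fraction)
    (ra, ca), (rb, cb) = _toe_points(lower)
    if (ra, ca) == (rb, cb):
        return 0
    with_line = lower.copy()
    rr, cc = _bresenham_line(ra, ca, rb, cb)
    with_line[rr, cc] = True
    # hole fill: background 4-connectivity, anything not reachable from the
    # border becomes foreground
    filled = ndimage.binary_fill_holes(with_line)
    return int(np.count_nonzero(filled & ~with_line))


def measure_frame(
    sil: BinarySilhouette, noise_fraction: float = DEFAULT_NOISE_FRACTION
) -> BodyMeasurements:
    """All seven raw body measurements for one frame.

    Raises :class:`EmptyFrameError` / :class:`FrameMeasurementError`
    (annotated with the frame index) when the frame cannot be measured:
    empty frame, empty middle or lower band, or a vanished lower half.
    """
    box = full_body_box(sil)
    mid = band_box(sil, box, band=1, n_bands=3)
    low = band_box(sil, box, band=2, n_bands=3)
    if mid is None:
        raise FrameMeasurementError(
            f"middle third of the body box is empty (frame {sil.frame_index})"
        )
    if low is None:
        raise FrameMeasurementError(
            f"lower third of the body box is empty (frame {sil.frame_index})"
        )
    return BodyMeasurements(
        full_body_height=box.height,
        full_body_width=box.width,
        mid_body_width=mid.width,
        lower_body_width=low.width,
        apparent_body_area=apparent_body_area(sil),
        full_body_area=box.height * box.width,
        between_legs_area=between_legs_area(sil, box, noise_fraction),
    )


def compute_ratios(m: BodyMeasurements) -> RatioFeatures:
    """The five ratio features of one frame's measurements."""
    for name in ("full_body_width", "mid_body_width", "lower_body_width", "full_body_area"):
        if getattr(m, name) <= 0:
            raise FrameMeasurementError(f"zero denominator: {name} must be positive")
    return RatioFeatures(
        HW1=m.full_body_height / m.full_body_width,
        HW2=m.full_body_height / m.mid_body_width,
        HW3=m.full_body_height / m.lower_body_width,
        A1=m.apparent_body_area / m.full_body_area,
        A2=m.between_legs_area / m.full_body_area,
    )


def measure_sequence(
    frames: Iterable[BinarySilhouette],
    noise_fraction: float = DEFAULT_NOISE_FRACTION,
) -> pd.DataFrame:
    """Measurements + ratios for a whole sequence as a tidy DataFrame.

    Frames that cannot be measured (empty frame, empty band, zero
    denominator) are dropped and logged; curated silhouette datasets
    rarely exhibit such frames, and dropping preserves signal continuity
    better than imputation.  Columns follow :data:`FEATURE_CSV_COLUMNS`.
    """
    records: list[dict] = []
    for sil in frames:
        try:
            m = measure_frame(sil, noise_fraction)
            r = compute_ratios(m)
        except (EmptyFrameError, FrameMeasurementError) as exc:
            logger.warning("dropping frame %d: %s", sil.frame_index, exc)
            continue
        rec = {"frame": sil.frame_index}
        rec.update(zip(MEASUREMENT_NAMES, m.as_tuple()))
        rec.update(zip(RATIO_NAMES, r.as_tuple()))
        records.append(rec)
    return pd.DataFrame.from_records(records, columns=list(FEATURE_CSV_COLUMNS))


def upscale_nearest(sil: BinarySilhouette, factor: int) -> BinarySilhouette:
    """Nearest-neighbour integer upscaling (camera moved closer by ``factor``)."""
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    mask = np.repeat(np.repeat(sil.mask, factor, axis=0), factor, axis=1)
    return BinarySilhouette(mask, sil.frame_index)
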