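"""Synthetic lateral-view walking silhouettes with known gait parameters.

The generator draws an articulated stick-body walker — head (disk),
trunk (rectangle), two rigid legs swinging in antiphase about the hip,
optional arms antiphase to the legs — and rasterizes it to a boolean
silhouette per frame.  The legs rotate by ``±A·sat(2π·f·t)`` where ``f``
is the gait frequency in cycles per frame and ``sat`` is a saturated
sine whose clipped extremes model the double-support hold of each
stride, so the between-legs gap opens twice per gait cycle — exactly
the quasi-periodicity the ratio features are meant to capture.  A
uniform ``scale`` factor emulates the
subject-to-camera distance; optional small disconnected blobs in the
lower body emulate segmentation noise such as swinging-hand traces.

Ground truth (frequency, swing, scale) is known for every walker, which
makes the generator the test bed for frequency recovery, distance
invariance and classifier learnability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.draw import disk as _draw_disk, polygon as _draw_polygon
from skimage.measure import label as _cc_label

from .signals import SPEED_CLASSES, WalkingSpeedPattern, pattern_from_dataframe
from .silhouette import BinarySilhouette, measure_sequence

__all__ = [
    "WalkerParams",
    "SpeedClassSpec",
    "default_speed_specs",
    "render_frame",
    "generate_sequence",
    "generate_dataset",
    "write_sequence",
    "write_dataset",
]


@dataclass(frozen=True)
class WalkerParams:
    """Geometry and motion of one synthetic walker.

    Lengths are in pixels at ``scale`` 1 (the rendered canvas and every
    body segment are multiplied by ``scale``); angles in radians;
    ``gait_frequency`` in cycles per frame and bounded by Nyquist.
    Proportions default to a ~200 px figure whose legs are slightly
    shorter than half the body height, as in human stature, so the
    crotch sits below the body-box midline; the size keeps pixel
    quantization well below the frame-to-frame signal changes.
    """

    canvas: tuple[int, int] = (240, 160)
    body_height: float = 200.0
    head_radius: float = 14.0
    trunk_width: float = 32.0
    leg_length: float = 90.0
    leg_width: float = 12.0
    arm_length: float = 58.0
    arm_width: float = 8.0
    gait_frequency: float = 0.025
    leg_swing_amplitude: float = 0.30
    arm_swing_amplitude: float = 0.69
    swing_saturation: float = 1.3
    arm_swing_saturation: float = 2.6
    scale: float = 1.0
    noise_blob_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gait_frequency < 0.5:
            raise ValueError("gait_frequency must lie in (0, 0.5) cycles/frame (Nyquist)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.noise_blob_rate < 0:
            raise ValueError("noise_blob_rate must be non-negative")
        if self.swing_saturation < 1.0 or self.arm_swing_saturation < 1.0:
            raise ValueError("swing saturations must be >= 1 (1 = pure sinusoid)")


@dataclass(frozen=True)
class SpeedClassSpec:
    """Frequency and leg-swing ranges generating one speed class."""

    label: str
    frequency_range: tuple[float, float]
    swing_range: tuple[float, float]


def default_speed_specs() -> list[SpeedClassSpec]:
    """Slow / normal / fast walker populations.

    Frequency bands (cycles/frame at a nominal 30 fps) bracket human
    stride rates at 2-7 km/h and are disjoint and ordered; swing
    amplitude grows with speed, mirroring the wider limb excursions of
    faster walking.
    """
    return [
        SpeedClassSpec("slow", (0.015, 0.020), (0.20, 0.28)),
        SpeedClassSpec("normal", (0.025, 0.030), (0.28, 0.36)),
        SpeedClassSpec("fast", (0.035, 0.040), (0.36, 0.44)),
    ]


def _thick_segment(mask, p0, p1, width):
    """Rasterize a thick line segment (rotated rectangle) onto ``mask``."""
    (r0, c0), (r1, c1) = p0, p1
    dr, dc = r1 - r0, c1 - c0
    norm = math.hypot(dr, dc)
    if norm == 0:
        return
    ur, uc = -dc / norm * width / 2.0, dr / norm * width / 2.0
    rows = [r0 + ur, r0 - ur, r1 - ur, r1 + ur]
    cols = [c0 + uc, c0 - uc, c1 - uc, c1 + uc]
    rr, cc = _draw_polygon(rows, cols, shape=mask.shape)
    mask[rr, cc] = True


def _sat_sin(x: float, kappa: float) -> float:
    """Sine overdriven by ``kappa`` and clipped to [-1, 1]."""
    return max(-1.0, min(1.0, kappa * math.sin(x)))


def _body_mask(p: WalkerParams, t: int) -> np.ndarray:
    s = p.scale
    rows, cols = int(round(p.canvas[0] * s)), int(round(p.canvas[1] * s))
    top = 8.0 * s
    cx = cols / 2.0
    r = p.head_radius * s
    L = p.leg_length * s
    hip_y = top + (p.body_height - p.leg_length) * s

    # saturated sinusoidal swing: the overdriven sine is clipped at +-1, so
    # each stride holds the legs at maximum separation for a double-support
    # interval (the silhouette is then exactly constant there — the signal
    # maxima become flat plateaus instead of shallow sinusoid tops, whose
    # near-flat windows would otherwise breed pixel-quantization micro-peaks).
    # The arms swing antiphase with a stronger saturation, so the arm-driven
    # full-body width is already locked at its extreme while the between-legs
    # gap is still approaching its own plateau: the area-ratio denominators
    # are exactly constant through the gap maxima.
    phase = 2.0 * math.pi * p.gait_frequency * t
    theta = p.leg_swing_amplitude * _sat_sin(phase, p.swing_saturation)
    phi = p.arm_swing_amplitude * _sat_sin(phase + math.pi, p.arm_swing_saturation)

    # fit check: widest excursion of legs/arms/trunk/head must stay inside
    half_w = max(
        p.trunk_width * s / 2.0,
        r,
        L * math.sin(p.leg_swing_amplitude) + p.leg_width * s,
        p.arm_length * s * math.sin(max(p.arm_swing_amplitude, 1e-9)) + p.arm_width * s,
    )
    if cx - half_w < 1 or cx + half_w > cols - 1 or top + p.body_height * s + 2 > rows:
        raise ValueError("walker does not fit the canvas at this scale")

    mask = np.zeros((rows, cols), dtype=bool)
    rr, cc = _draw_disk((top + r, cx), r, shape=mask.shape)
    mask[rr, cc] = True
    # trunk overlaps the head above and the hip below, keeping one component
    tr0, tr1 = top + 1.4 * r, hip_y + 0.03 * p.body_height * s
    tw = p.trunk_width * s / 2.0
    rr, cc = _draw_polygon(
        [tr0, tr0, tr1, tr1], [cx - tw, cx + tw, cx + tw, cx - tw], shape=mask.shape
    )
    mask[rr, cc] = True
    hip = (hip_y, cx)
    for sign in (+1.0, -1.0):
        a = sign * theta
        tip = (hip_y + L * math.cos(a), cx + L * math.sin(a))
        _thick_segment(mask, hip, tip, p.leg_width * s)
    if p.arm_length > 0 and p.arm_width > 0:
        shoulder = (top + 2.4 * r, cx)
        AL = p.arm_length * s
        for sign in (+1.0, -1.0):
            a = sign * phi
            tip = (shoulder[0] + AL * math.cos(a), shoulder[1] + AL * math.sin(a))
            _thick_segment(mask, shoulder, tip, p.arm_width * s)
    return mask


def _add_noise_blobs(mask: np.ndarray, p: WalkerParams, t: int) -> np.ndarray:
    """Scatter Poisson-many tiny (<= 3 px) blobs in the lower body region.

    Blobs are placed inside the body's bounding box (like swinging-hand
    traces) but never touching the body, so they form disconnected
    components for the denoising step to remove.
    """
    rng = np.random.default_rng([p.seed, t])
    n_blobs = rng.poisson(p.noise_blob_rate)
    if n_blobs == 0:
        return mask
    rows_any = np.flatnonzero(mask.any(axis=1))
    r0, r1 = rows_any[0], rows_any[-1]
    # speckle appears around the legs: stay within the leg region's own
    # column span and above the feet so the blobs never stretch any
    # bounding box, only exercise the denoising step
    lo = r0 + 2 * (r1 - r0 + 1) // 3 + 1
    leg_cols = np.flatnonzero(mask[lo:r1 + 1].any(axis=0))
    if len(leg_cols) < 8:
        return mask
    c0, c1 = leg_cols[0], leg_cols[-1]
    out = mask.copy()
    for _ in range(n_blobs):
        for _attempt in range(20):
            size = int(rng.integers(1, 4))
            if c1 - 2 - size <= c0 + 2 or r1 - 2 <= lo + 2:
                break
            br = int(rng.integers(lo + 2, r1 - 2))
            bc = int(rng.integers(c0 + 2, c1 - 2 - size))
            sl = out[br - 1:br + 2, bc - 1:bc + size + 1]
            if sl.any():  # would touch or merge with the body
                continue
            out[br, bc:bc + size] = True
            break
    return out


def render_frame(p: WalkerParams, t: int) -> BinarySilhouette:
    """Rasterize the walker at frame ``t`` (legs together at t = 0).

    Legs (and arms, antiphase) rotate about the hip by the leg-swing
    amplitude times a saturated sine of 2*pi*f*t, holding the extreme
    pose for a double-support fraction of each stride.  The body
    excluding noise is a single 8-connected component; noise blobs, when
    present, are additional tiny components in the lower half.
    """
    mask = _body_mask(p, t)
    n = _cc_label(mask, connectivity=2, return_num=True)[1]
    if n != 1:
        raise RuntimeError(f"walker body rasterized into {n} components at frame {t}")
    if p.noise_blob_rate > 0:
        mask = _add_noise_blobs(mask, p, t)
    return BinarySilhouette(mask, frame_index=t)


def generate_sequence(p: WalkerParams, T: int) -> list[BinarySilhouette]:
    """Render ``T`` consecutive frames; deterministic for a given seed."""
    if T < 3:
        raise ValueError("need at least 3 frames for a gait sequence")
    return [render_frame(p, t) for t in range(T)]


def generate_dataset(
    specs: Sequence[SpeedClassSpec] | None = None,
    n_per_class: int = 10,
    T: int = 240,
    seed: int = 0,
    scale_range: tuple[float, float] = (0.8, 1.3),
    noise_blob_rate: float = 0.0,
    base: WalkerParams | None = None,
) -> tuple[list[WalkingSpeedPattern], list[WalkerParams]]:
    """Labeled walking-speed patterns from three walker populations.

    For each class, ``n_per_class`` walkers draw their gait frequency and
    leg swing uniformly from the class ranges and a uniform random scale
    from ``scale_range`` (exercising distance invariance); arm swing is
    tied to 60% of the leg swing.  Every walker is rendered, measured
    frame by frame and turned into a normalized 5 x T pattern.  Returns
    the patterns and the ground-truth walker parameters in the same
    order.
    """
    specs = list(specs) if specs is not None else default_speed_specs()
    base = base or WalkerParams()
    labels = [SPEED_CLASSES.index(s.label) for s in specs]
    rng = np.random.default_rng(seed)
    patterns: list[WalkingSpeedPattern] = []
    walkers: list[WalkerParams] = []
    for label, spec in zip(labels, specs):
        for j in range(n_per_class):
            f = float(rng.uniform(*spec.frequency_range))
            swing = float(rng.uniform(*spec.swing_range))
            scale = float(rng.uniform(*scale_range))
            wseed = int(rng.integers(2**31 - 1))
            p = replace(
                base,
                gait_frequency=f,
                leg_swing_amplitude=swing,
                arm_swing_amplitude=min(2.3 * swing, 1.05),
                scale=scale,
                noise_blob_rate=noise_blob_rate,
                seed=wseed,
            )
            source = f"{spec.label}-{j:03d}"
            try:
                df = measure_sequence(generate_sequence(p, T))
                patterns.append(pattern_from_dataframe(df, label, T, source_id=source))
            except ValueError as exc:
                raise RuntimeError(f"extraction failed for walker {source}: {exc}") from exc
            walkers.append(p)
    return patterns, walkers


# ------------------------------------------------------------------ file I/O

def write_sequence(frames: Sequence[BinarySilhouette], directory: str | Path) -> list[Path]:
    """Write frames as 8-bit PNGs (255 = foreground) in temporal name order."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, sil in enumerate(frames):
        path = directory / f"frame_{i:05d}.png"
        Image.fromarray(sil.mask.astype(np.uint8) * 255, mode="L").save(path)
        paths.append(path)
    return paths


def write_dataset(
    out_dir: str | Path,
    specs: Sequence[SpeedClassSpec] | None = None,
    n_per_class: int = 3,
    T: int = 60,
    seed: int = 0,
    scale_range: tuple[float, float] = (0.8, 1.3),
    noise_blob_rate: float = 0.0,
) -> Path:
    """Write a PNG silhouette dataset plus a labels manifest CSV.

    Layout: ``<out_dir>/<sequence_id>/frame_*.png`` with
    ``<out_dir>/manifest.csv`` columns sequence_id, directory, label —
    the same shape the dataset reader consumes.
    """
    import pandas as pd

    specs = list(specs) if specs is not None else default_speed_specs()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for spec in specs:
        for j in range(n_per_class):
            f = float(rng.uniform(*spec.frequency_range))
            swing = float(rng.uniform(*spec.swing_range))
            scale = float(rng.uniform(*scale_range))
            wseed = int(rng.integers(2**31 - 1))
            p = WalkerParams(
                gait_frequency=f,
                leg_swing_amplitude=swing,
                arm_swing_amplitude=min(2.3 * swing, 1.05),
                scale=scale,
                noise_blob_rate=noise_blob_rate,
                seed=wseed,
            )
            seq_id = f"{spec.label}_{j:03d}"
            write_sequence(generate_sequence(p, T), out_dir / seq_id)
            rows.append({"sequence_id": seq_id, "directory": seq_id, "label": spec.label})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
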