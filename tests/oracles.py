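"""Independent brute-force oracles used to verify the measurement path.

Everything here is deliberately naive — pure-python pixel scans, BFS
flood fill, sorting-based percentiles — and shares no code with the
package implementation.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bbox_scan(mask) -> tuple[int, int, int, int]:
    """(top, left, height, width) by scanning every pixel."""
    rows = [r for r in range(mask.shape[0]) for c in range(mask.shape[1]) if mask[r, c]]
    cols = [c for r in range(mask.shape[0]) for c in range(mask.shape[1]) if mask[r, c]]
    return min(rows), min(cols), max(rows) - min(rows) + 1, max(cols) - min(cols) + 1


def band_width_scan(mask, band: int, n_bands: int) -> int:
    """Width of the tight box of foreground in one horizontal band of the
    full bounding box, recomputed from raw pixels; 0 if the band is empty."""
    top, left, h, w = bbox_scan(mask)
    r0 = top + (band * h) // n_bands
    r1 = top + ((band + 1) * h) // n_bands
    cols = [
        c
        for r in range(r0, r1)
        for c in range(left, left + w)
        if mask[r, c]
    ]
    return (max(cols) - min(cols) + 1) if cols else 0


def pixel_count(mask) -> int:
    return sum(bool(mask[r, c]) for r in range(mask.shape[0]) for c in range(mask.shape[1]))


def _components(mask, connectivity=8):
    """Connected components by BFS; returns a list of pixel sets."""
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = set()
    comps = []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if not mask[r, c] or (r, c) in seen:
                continue
            comp = set()
            q = deque([(r, c)])
            seen.add((r, c))
            while q:
                cr, cc = q.popleft()
                comp.add((cr, cc))
                for dr, dc in steps:
                    nr, nc = cr + dr, cc + dc
                    if (
                        0 <= nr < mask.shape[0]
                        and 0 <= nc < mask.shape[1]
                        and mask[nr, nc]
                        and (nr, nc) not in seen
                    ):
                        seen.add((nr, nc))
                        q.append((nr, nc))
            comps.append(comp)
    return comps


def _bresenham(r0, c0, r1, c1):
    """Integer midpoint line, inclusive of both endpoints."""
    points = []
    dr, dc = abs(r1 - r0), abs(c1 - c0)
    sr = 1 if r0 < r1 else -1
    sc = 1 if c0 < c1 else -1
    err = dc - dr
    r, c = r0, c0
    while True:
        points.append((r, c))
        if (r, c) == (r1, c1):
            break
        e2 = 2 * err
        if e2 > -dr:
            err -= dr
            c += sc
        if e2 < dr:
            err += dr
            r += sr
    return points


def between_legs_scan(mask, noise_fraction=0.10) -> int:
    """Between-legs area by BFS flood fill of the lower-half crop.

    Re-implements the whole procedure naively: crop the lower half of the
    bounding box, drop small components, find the two toe points, draw
    the toe line, then flood-fill the background from the crop border —
    every background pixel NOT reached is enclosed between the legs.
    """
    top, left, h, w = bbox_scan(mask)
    r0 = top + h // 2
    crop = np.array(mask[r0:top + h, left:left + w], dtype=bool)
    comps = _components(crop)
    biggest = max(len(c) for c in comps)
    kept = [c for c in comps if len(c) >= noise_fraction * biggest]
    clean = np.zeros_like(crop)
    for comp in kept:
        for r, c in comp:
            clean[r, c] = True
    left_comp = min(kept, key=lambda comp: min(c for _, c in comp))
    right_comp = max(kept, key=lambda comp: max(c for _, c in comp))
    if left_comp is right_comp:
        # single component: split halves at the midpoint of its column extent
        cols = [c for _, c in left_comp]
        mid = (min(cols) + max(cols) + 1) // 2
        left_comp = {(r, c) for r, c in left_comp if c < mid}
        right_comp = {(r, c) for r, c in right_comp if c >= mid}
        if not left_comp or not right_comp:
            return 0

    def toe(comp, outer_left):
        bottom = max(r for r, _ in comp)
        cols = [c for r, c in comp if r == bottom]
        return bottom, (min(cols) if outer_left else max(cols))

    ta, tb = toe(left_comp, True), toe(right_comp, False)
    if ta == tb:
        return 0
    with_line = clean.copy()
    for r, c in _bresenham(*ta, *tb):
        with_line[r, c] = True
    # flood-fill background from the border (4-connectivity)
    H, W = with_line.shape
    reach = np.zeros_like(with_line)
    q = deque()
    for r in range(H):
        for c in (0, W - 1):
            if not with_line[r, c] and not reach[r, c]:
                reach[r, c] = True
                q.append((r, c))
    for c in range(W):
        for r in (0, H - 1):
            if not with_line[r, c] and not reach[r, c]:
                reach[r, c] = True
                q.append((r, c))
    while q:
        r, c = q.popleft()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nr, nc = r + dr, c + dc
            if 0 <= nr < H and 0 <= nc < W and not with_line[nr, nc] and not reach[nr, nc]:
                reach[nr, nc] = True
                q.append((nr, nc))
    return int(sum(1 for r in range(H) for c in range(W) if not with_line[r, c] and not reach[r, c]))


def measure_scan(mask, noise_fraction=0.10) -> tuple[int, ...]:
    """All seven raw measurements by brute force, in canonical order."""
    top, left, h, w = bbox_scan(mask)
    return (
        h,
        w,
        band_width_scan(mask, 1, 3),
        band_width_scan(mask, 2, 3),
        pixel_count(mask),
        h * w,
        between_legs_scan(mask, noise_fraction),
    )


def count_peaks_scan(x) -> int:
    """Strict interior maxima; a flat plateau flanked by strictly smaller
    neighbours counts once.  Triple/plateau comparison, no library calls."""
    x = list(x)
    n = len(x)
    count = 0
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                count += 1
            i = j + 1
        else:
            i += 1
    return count


def boxplot_scan(values) -> dict:
    """Sorting-based percentiles (linear interpolation) and Tukey fences."""
    xs = sorted(float(v) for v in values)
    n = len(xs)

    def pct(p):
        if n == 1:
            return xs[0]
        pos = p / 100 * (n - 1)
        lo = int(pos)
        hi = min(lo + 1, n - 1)
        return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])

    p25, p50, p75 = pct(25), pct(50), pct(75)
    iqr = p75 - p25
    lo_f, hi_f = p25 - 1.5 * iqr, p75 + 1.5 * iqr
    inside = [v for v in xs if lo_f <= v <= hi_f]
    mean = sum(xs) / n
    sd = (sum((v - mean) ** 2 for v in xs) / (n - 1)) ** 0.5 if n > 1 else 0.0
    return {
        "n": n, "mean": mean, "sd": sd,
        "p25": p25, "p50": p50, "p75": p75,
        "min": xs[0], "max": xs[-1],
        "lower_adjacent": min(inside), "upper_adjacent": max(inside),
        "range": xs[-1] - xs[0], "iqr": iqr,
        "n_outliers": sum(1 for v in xs if v < lo_f or v > hi_f),
    }
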