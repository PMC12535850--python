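"""Independent brute-force oracles used to cross-check the vectorized pipeline.

Everything here is deliberately naive: per-pixel rational arithmetic for the
HSV conversion, recursive-free flood fill for labeling, and double loops for
region statistics.  None of it shares code with the implementation.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


def round_half_even(fr: Fraction) -> int:
    floor = fr.numerator // fr.denominator
    rem = fr - floor
    if rem > Fraction(1, 2):
        return floor + 1
    if rem < Fraction(1, 2):
        return floor
    return floor if floor % 2 == 0 else floor + 1


def hsv255_pixel(r: int, g: int, b: int) -> tuple[int, int, int]:
    """Exact hexcone HSV on the 0-255 scale via rational arithmetic."""
    mx, mn = max(r, g, b), min(r, g, b)
    d = mx - mn
    v = mx
    s = 0 if mx == 0 else round_half_even(Fraction(d * 255, mx))
    if d == 0:
        h = 0
    else:
        if mx == r:
            num = (g - b) % (6 * d)
        elif mx == g:
            num = (b - r) + 2 * d
        else:
            num = (r - g) + 4 * d
        h = round_half_even(Fraction(num * 255, 6 * d))
    return h, s, v


def hsv_predicate(r: int, g: int, b: int, bounds) -> bool:
    """Per-pixel re-evaluation of the HSV threshold predicate."""
    h, s, v = hsv255_pixel(r, g, b)
    if bounds.h_min <= bounds.h_max:
        h_ok = bounds.h_min <= h <= bounds.h_max
    else:
        h_ok = h >= bounds.h_min or h <= bounds.h_max
    return h_ok and bounds.s_min <= s <= bounds.s_max and bounds.v_min <= v <= bounds.v_max


def flood_fill_label(mask: np.ndarray, min_area: int, connectivity: int = 8) -> np.ndarray:
    """Naive stack-based connected-component labeling + area filter.

    Components are discovered in raster-scan order and survivors relabeled
    1..N in order of their first pixel, mirroring the implementation's
    contract.
    """
    h, w = mask.shape
    if connectivity == 8:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    labels = np.zeros((h, w), dtype=np.int32)
    components = []
    visited = np.zeros((h, w), dtype=bool)
    for y0 in range(h):
        for x0 in range(w):
            if not mask[y0, x0] or visited[y0, x0]:
                continue
            stack = [(y0, x0)]
            visited[y0, x0] = True
            pixels = []
            while stack:
                y, x = stack.pop()
                pixels.append((y, x))
                for dy, dx in steps:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not visited[ny, nx]:
                        visited[ny, nx] = True
                        stack.append((ny, nx))
            components.append(pixels)
    next_id = 1
    for pixels in components:
        if len(pixels) >= max(min_area, 1):
            for y, x in pixels:
                labels[y, x] = next_id
            next_id += 1
    return labels


def naive_object_stats(image: np.ndarray, labels: np.ndarray) -> dict[int, dict]:
    """Double-loop accumulation of per-label pixel lists and their statistics."""
    buckets: dict[int, list[tuple[int, int, int]]] = {}
    h, w = labels.shape
    for y in range(h):
        for x in range(w):
            lab = int(labels[y, x])
            if lab > 0:
                buckets.setdefault(lab, []).append(tuple(int(c) for c in image[y, x]))
    out = {}
    for lab, pix in buckets.items():
        stats = {"area": len(pix)}
        for c, name in enumerate("rgb"):
            vals = sorted(p[c] for p in pix)
            n = len(vals)
            median = vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2
            stats[f"min_{name}"] = vals[0]
            stats[f"max_{name}"] = vals[-1]
            stats[f"median_{name}"] = float(median)
            stats[f"mean_{name}"] = sum(vals) / n
        out[lab] = stats
    return out


def labelings_equivalent(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two label masks agree up to a label permutation."""
    if a.shape != b.shape or not ((a > 0) == (b > 0)).all():
        return False
    mapping: dict[int, int] = {}
    reverse: dict[int, int] = {}
    for la, lb in zip(a.ravel().tolist(), b.ravel().tolist()):
        if la == 0:
            continue
        if mapping.setdefault(la, lb) != lb or reverse.setdefault(lb, la) != la:
            return False
    return True
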