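"""HSV threshold segmentation with a minimum-area filter.

Leaf-like objects are extracted from the background by thresholding in the
hue-saturation-value color space, which filters for color (hue) while also
incorporating color intensity (saturation) and lightness (value).  All
three HSV channels are expressed on a 0-255 integer scale, matching the
ImageJ HSB dialect (hue in degrees maps as H = degrees x 255/360, rounded).
Connected components smaller than a minimum area are discarded, surviving
objects are labeled 1..N in raster-scan order, and background pixels are
set to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as sk_label

from greenleafvi.image_io import as_rgb_image


@dataclass(frozen=True)
class HsvBounds:
    """Segmentation parameter set: per-channel bounds on the 0-255 scale.

    The hue interval may wrap through 0: ``h_min > h_max`` selects hues
    >= h_min or <= h_max (red tones straddle the hue seam).  Saturation and
    value intervals are ordinary closed intervals.
    """

    h_min: int = 0
    h_max: int = 255
    s_min: int = 0
    s_max: int = 255
    v_min: int = 0
    v_max: int = 255
    min_area: int = 0

    def __post_init__(self) -> None:
        for name in ("h_min", "h_max", "s_min", "s_max", "v_min", "v_max"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name} must be in [0, 255], got {v}")
        if self.s_min > self.s_max:
            raise ValueError(f"s_min > s_max ({self.s_min} > {self.s_max})")
        if self.v_min > self.v_max:
            raise ValueError(f"v_min > v_max ({self.v_min} > {self.v_max})")
        if self.min_area < 0:
            raise ValueError(f"min_area must be >= 0, got {self.min_area}")

    @classmethod
    def from_degrees_percent(cls, h_min_deg: float, h_max_deg: float,
                             s_min_pct: float, s_max_pct: float,
                             v_min_pct: float, v_max_pct: float,
                             min_area: int = 0) -> "HsvBounds":
        """Build bounds from hue in degrees [0, 360) and S/V in percent."""
        return cls(
            h_min=int(round(h_min_deg * 255 / 360)),
            h_max=int(round(h_max_deg * 255 / 360)),
            s_min=int(round(s_min_pct * 255 / 100)),
            s_max=int(round(s_max_pct * 255 / 100)),
            v_min=int(round(v_min_pct * 255 / 100)),
            v_max=int(round(v_max_pct * 255 / 100)),
            min_area=min_area,
        )


def rgb_to_hsv255(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert an RGB image to H, S, V planes, each an integer in [0, 255].

    Standard hexcone conversion with every channel on a 0-255 scale: V is
    the channel maximum, S = 255 * (max - min) / max, and H maps hue degrees
    as 255/360 per degree.  Hue is defined as 0 for achromatic pixels
    (S = 0).  S and H are formed as a single division of exact integer
    numerators, so rounding (half-to-even) matches the true rational value
    bit-for-bit.
    """
    image = as_rgb_image(image)
    rgb = image.astype(np.int64)
    r, g, b = rgb[:, :, 0], rgb[:, :, 1], rgb[:, :, 2]
    maxc = rgb.max(axis=2)
    minc = rgb.min(axis=2)
    delta = maxc - minc

    v = maxc.astype(np.uint8)
    chromatic = maxc > 0
    s_f = np.divide(delta * 255, np.where(chromatic, maxc, 1), dtype=np.float64)
    s = np.where(chromatic, np.rint(s_f), 0).astype(np.uint8)

    # hue numerator on the 0..6*delta hexcone scale, 0 where achromatic
    num = np.zeros(maxc.shape, dtype=np.int64)
    has_hue = delta > 0
    is_r = has_hue & (maxc == r)
    is_g = has_hue & ~is_r & (maxc == g)
    is_b = has_hue & ~is_r & ~is_g
    num = np.where(is_r, (g - b) % (6 * np.where(delta > 0, delta, 1)), num)
    num = np.where(is_g, (b - r) + 2 * delta, num)
    num = np.where(is_b, (r - g) + 4 * delta, num)
    h_f = np.divide(num * 255, 6 * np.where(has_hue, delta, 1), dtype=np.float64)
    h = np.where(has_hue, np.rint(h_f), 0).astype(np.uint8)
    return h, s, v


def build_mask(h: np.ndarray, s: np.ndarray, v: np.ndarray,
               bounds: HsvBounds) -> np.ndarray:
    """Boolean foreground mask of pixels whose HSV triple satisfies the bounds."""
    if not (h.shape == s.shape == v.shape):
        raise ValueError("H, S, V planes must share a shape")
    if bounds.h_min <= bounds.h_max:
        h_ok = (h >= bounds.h_min) & (h <= bounds.h_max)
    else:  # hue interval wraps through 0
        h_ok = (h >= bounds.h_min) | (h <= bounds.h_max)
    s_ok = (s >= bounds.s_min) & (s <= bounds.s_max)
    v_ok = (v >= bounds.v_min) & (v <= bounds.v_max)
    return h_ok & s_ok & v_ok


def filter_by_area(mask: np.ndarray, min_area: int,
                   connectivity: int = 8) -> np.ndarray:
    """Label connected components and drop those smaller than ``min_area``.

    Survivors are relabeled 1..N in raster-scan order of their first pixel,
    so labels are consecutive and deterministic.  ``connectivity`` is 4 or 8
    (default 8, keeping diagonal leaf-edge pixels connected).
    """
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    raw = sk_label(mask.astype(bool), connectivity=1 if connectivity == 4 else 2)
    counts = np.bincount(raw.ravel())
    keep = np.flatnonzero(counts >= max(min_area, 1))
    keep = keep[keep != 0]

    # relabel survivors 1..N by first raster-scan occurrence
    relabel = np.zeros(counts.size, dtype=np.int32)
    flat = raw.ravel()
    keep_set = set(int(k) for k in keep)
    next_id = 1
    for lab in flat:
        if lab != 0 and lab in keep_set and relabel[lab] == 0:
            relabel[lab] = next_id
            next_id += 1
            if next_id > len(keep_set):
                break
    return relabel[raw]


def remove_background(image: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Zero out every pixel not covered by an object label."""
    image = as_rgb_image(image)
    if labels.shape != image.shape[:2]:
        raise ValueError(
            f"label mask shape {labels.shape} does not match image {image.shape[:2]}"
        )
    out = image.copy()
    out[labels == 0] = 0
    return out


def segment(image: np.ndarray, bounds: HsvBounds,
            connectivity: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Full segmentation: HSV threshold, area filter, background removal.

    Returns ``(segmented_image, label_mask)``.
    """
    h, s, v = rgb_to_hsv255(image)
    mask = build_mask(h, s, v, bounds)
    labels = filter_by_area(mask, bounds.min_area, connectivity=connectivity)
    return remove_background(image, labels), labels
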