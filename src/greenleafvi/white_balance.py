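"""White balancing against an in-image white reference.

Each image carries a near-white reference patch photographed alongside the
leaves.  Per channel, the adjustment factor is the maximum 8-bit brightness
divided by the mean reference intensity (``255 / mean``).  The reference
patch itself is overwritten to pure white, and every pixel outside it is
multiplied by its channel's factor, rounded half-to-even, and clipped to
[0, 255].  This removes illumination color cast and brightness differences
between images, so that channel statistics are comparable across a batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops

from greenleafvi.image_io import Roi, as_rgb_image

MAX_BRIGHTNESS = 255.0

#: Defaults for auto-locating the white reference patch.
AUTO_MIN_INTENSITY = 200
AUTO_MAX_CHANNEL_SPREAD = 30
AUTO_MIN_AREA = 100


class ReferenceNotFoundError(RuntimeError):
    """Auto-localization found no qualifying near-white region."""


class DegenerateReferenceError(ValueError):
    """The reference area has a non-positive channel mean (e.g. all black)."""


@dataclass(frozen=True)
class WhiteBalanceResult:
    reference_roi: Roi
    channel_means: tuple[float, float, float]
    adjustment_factors: tuple[float, float, float]
    balanced_image: np.ndarray


def locate_white_reference(
    image: np.ndarray,
    roi: Roi | None = None,
    *,
    min_intensity: int = AUTO_MIN_INTENSITY,
    max_channel_spread: int = AUTO_MAX_CHANNEL_SPREAD,
    min_area: int = AUTO_MIN_AREA,
) -> Roi:
    """Find the white reference patch.

    With ``roi`` given (manual mode) the region is validated and returned
    unchanged.  In auto mode, a pixel is near-white when its darkest channel
    is at least ``min_intensity`` and the spread between its brightest and
    darkest channels is at most ``max_channel_spread``; the bounding box of
    the largest 8-connected near-white region of at least ``min_area``
    pixels is returned.

    Raises ``ReferenceNotFoundError`` when no region qualifies, so the
    caller may skip balancing.
    """
    image = as_rgb_image(image)
    if roi is not None:
        roi.validate_within(image)
        return roi

    chmin = image.min(axis=2)
    chmax = image.max(axis=2)
    near_white = (chmin >= min_intensity) & (chmax - chmin <= max_channel_spread)
    labels = label(near_white, connectivity=2)
    best = None
    for region in regionprops(labels):
        if region.area >= min_area and (best is None or region.area > best.area):
            best = region
    if best is None:
        raise ReferenceNotFoundError(
            f"no near-white region of >= {min_area} px found "
            f"(min intensity {min_intensity}, max spread {max_channel_spread})"
        )
    y0, x0, y1, x1 = best.bbox
    return Roi(x0=int(x0), y0=int(y0), width=int(x1 - x0), height=int(y1 - y0))


def compute_adjustment_factors(
    channel_means: tuple[float, float, float],
) -> tuple[float, float, float]:
    """Per-channel scaling factors 255 / mean reference intensity."""
    for m in channel_means:
        if m <= 0:
            raise DegenerateReferenceError(
                f"reference channel mean must be > 0, got {channel_means}"
            )
    return tuple(MAX_BRIGHTNESS / m for m in channel_means)


def apply_white_balance(image: np.ndarray, reference_roi: Roi) -> WhiteBalanceResult:
    """Normalize an image so its white reference reaches full brightness.

    Pixels inside ``reference_roi`` are set to (255, 255, 255); all others
    are channel-wise scaled by 255/mean, rounded half-to-even and clipped.
    """
    image = as_rgb_image(image)
    reference_roi.validate_within(image)
    patch = image[reference_roi.slices()]
    means = tuple(float(patch[:, :, c].mean()) for c in range(3))
    factors = compute_adjustment_factors(means)

    scaled = image.astype(np.float64) * np.asarray(factors)
    balanced = np.clip(np.rint(scaled), 0, 255).astype(np.uint8)
    balanced[reference_roi.slices()] = 255
    return WhiteBalanceResult(
        reference_roi=reference_roi,
        channel_means=means,
        adjustment_factors=factors,
        balanced_image=balanced,
    )
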