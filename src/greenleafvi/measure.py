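"""Per-object, per-channel pixel statistics.

For each labeled object the minimum, maximum, median, and mean intensity is
measured in the red, green, and blue channels, along with the object's
pixel area.  Statistics are taken over exactly the pixels carrying the
object's label; pixels inside an optional exclusion region (the white
reference patch) are left out so an all-permissive HSV profile cannot
contaminate leaf statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from greenleafvi.image_io import Roi, as_rgb_image

logger = logging.getLogger(__name__)

CHANNELS = ("r", "g", "b")


@dataclass(frozen=True)
class ObjectStats:
    """Area and per-channel min/max/median/mean for one labeled object."""

    object_id: int
    area: int
    min_r: int
    max_r: int
    median_r: float
    mean_r: float
    min_g: int
    max_g: int
    median_g: float
    mean_g: float
    min_b: int
    max_b: int
    median_b: float
    mean_b: float


def measure_objects(image: np.ndarray, labels: np.ndarray,
                    exclude_roi: Roi | None = None) -> list[ObjectStats]:
    """Measure channel statistics for every object in ascending label order.

    The median of an even pixel count is the midpoint of the two central
    values.  An object whose pixels all fall inside ``exclude_roi`` is
    dropped with a logged warning.
    """
    image = as_rgb_image(image)
    if labels.shape != image.shape[:2]:
        raise ValueError(
            f"label mask shape {labels.shape} does not match image {image.shape[:2]}"
        )
    include = np.ones(labels.shape, dtype=bool)
    if exclude_roi is not None:
        exclude_roi.validate_within(image)
        include[exclude_roi.slices()] = False

    stats: list[ObjectStats] = []
    n_objects = int(labels.max())
    for obj_id in range(1, n_objects + 1):
        sel = (labels == obj_id) & include
        if not sel.any():
            logger.warning(
                "object %d lies entirely within the excluded region; dropped", obj_id
            )
            continue
        fields: dict[str, float | int] = {"object_id": obj_id, "area": int(sel.sum())}
        for c, name in enumerate(CHANNELS):
            vals = image[:, :, c][sel]
            fields[f"min_{name}"] = int(vals.min())
            fields[f"max_{name}"] = int(vals.max())
            fields[f"median_{name}"] = float(np.median(vals))
            fields[f"mean_{name}"] = float(vals.mean())
        stats.append(ObjectStats(**fields))
    return stats
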