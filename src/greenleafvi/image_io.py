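"""Image data model and raster I/O.

The universal carrier through the pipeline is an 8-bit RGB image stored as a
``numpy.ndarray`` of shape ``(height, width, 3)`` and dtype ``uint8``.
Coordinates are 0-based, row-major; rectangular regions use half-open
extents.  Outputs are always written as lossless PNG so that downstream
measurements are bit-reproducible even when the inputs were JPEG.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

#: Stage suffixes appended to output file stems.
WHITEBALANCED_SUFFIX = "_whitebalanced"
SEGMENTED_SUFFIX = "_segmented"
STAGE_SUFFIXES = (WHITEBALANCED_SUFFIX, SEGMENTED_SUFFIX)


class FormatError(ValueError):
    """Raised for images the pipeline cannot represent (e.g. 16-bit depth)."""


@dataclass(frozen=True)
class Roi:
    """Rectangular region of interest: 0-based top-left corner, half-open extent."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(f"Roi extent must be >= 1, got {self.width}x{self.height}")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"Roi origin must be non-negative, got ({self.x0}, {self.y0})")

    def validate_within(self, image: np.ndarray) -> None:
        h, w = image.shape[:2]
        if self.x0 + self.width > w or self.y0 + self.height > h:
            raise ValueError(
                f"Roi {self} exceeds image bounds {h}x{w}"
            )

    def slices(self) -> tuple[slice, slice]:
        """(row, column) slices addressing this region in an array."""
        return (
            slice(self.y0, self.y0 + self.height),
            slice(self.x0, self.x0 + self.width),
        )

    def contains_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of the region over an image of the given (H, W) shape."""
        m = np.zeros(shape, dtype=bool)
        m[self.slices()] = True
        return m


def as_rgb_image(array: np.ndarray) -> np.ndarray:
    """Validate and coerce an array to the canonical (H, W, 3) uint8 layout."""
    a = np.asarray(array)
    if a.ndim == 2:
        a = np.stack([a] * 3, axis=-1)
    if a.ndim != 3 or a.shape[2] != 3:
        raise FormatError(f"expected an RGB image, got shape {a.shape}")
    if a.shape[0] < 1 or a.shape[1] < 1:
        raise FormatError("image must be at least 1x1")
    if a.dtype != np.uint8:
        if np.issubdtype(a.dtype, np.integer) and a.min() >= 0 and a.max() <= 255:
            a = a.astype(np.uint8)
        else:
            raise FormatError(f"channel values must be 8-bit integers, got dtype {a.dtype}")
    return a


def read_rgb_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/JPEG/TIFF image as an (H, W, 3) uint8 array.

    Grayscale inputs are expanded to three identical channels and alpha
    channels are dropped.  Images with more than 8 bits per channel are
    rejected rather than silently rescaled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    arr = iio.imread(path)
    if arr.dtype != np.uint8:
        raise FormatError(
            f"unsupported bit depth: {path} decodes to {arr.dtype}; only 8-bit images are supported"
        )
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[2] == 2:  # gray + alpha
        arr = arr[:, :, 0]
    return as_rgb_image(arr)


def write_rgb_image(image: np.ndarray, source_path: str | os.PathLike, suffix: str,
                    output_dir: str | os.PathLike | None = None) -> Path:
    """Write ``image`` as lossless PNG named ``<source stem><suffix>.png``.

    The file is placed next to ``source_path`` unless ``output_dir`` is given.
    Returns the path written.
    """
    image = as_rgb_image(image)
    source_path = Path(source_path)
    target_dir = Path(output_dir) if output_dir is not None else source_path.parent
    out = target_dir / f"{source_path.stem}{suffix}.png"
    try:
        iio.imwrite(out, image, extension=".png")
    except OSError as exc:
        raise OSError(f"cannot write image to {out}: {exc}") from exc
    return out
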