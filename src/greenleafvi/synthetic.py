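"""Synthetic leaf scenes and senescence color series with exact ground truth.

The generator emulates the imaging setup the pipeline targets: leaves laid
flat on a homogeneous background, photographed with a near-white reference
square in frame.  Leaves are rendered as ellipses of a given mean color
with optional per-channel Gaussian pixel noise (rounded and clipped to the
8-bit gamut); the truth table records each leaf's rasterized area and its
realized (post-quantization) channel means, so measurement checks can be
exact.

A senescence series emulates the green-to-yellow color shift of
chlorophyll breakdown: a latent chlorophyll value (mg/cm^2) maps to a mean
leaf RGB through an affine color model, and one single-leaf scene is
rendered per sample with chlorophyll evenly spaced over the requested
range.  The default model runs from yellow (180, 170, 60) at zero
chlorophyll to green (60, 140, 50) at 0.04 mg/cm^2, a typical
fully-green leaf content; it keeps all nine CVIs defined while driving the
Woebbecke index toward its blow-up (R close to G) for the yellowest
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from greenleafvi.image_io import Roi
from greenleafvi.segmentation import HsvBounds


class SceneSpecError(ValueError):
    """The scene specification is inconsistent (overlaps, out-of-gamut colors)."""


@dataclass(frozen=True)
class LeafSpec:
    """One elliptical leaf: center (row, col), radii (ry, rx), mean RGB, noise sd."""

    center: tuple[float, float]
    radii: tuple[float, float]
    mean_color: tuple[float, float, float]
    noise_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SceneSpec:
    canvas: tuple[int, int]  # (height, width)
    background_color: tuple[int, int, int] = (0, 0, 0)
    white_ref: tuple[Roi, tuple[int, int, int]] | None = None
    leaves: tuple[LeafSpec, ...] = ()
    seed: int = 0


def _ellipse_mask(shape: tuple[int, int], leaf: LeafSpec) -> np.ndarray:
    cy, cx = leaf.center
    ry, rx = leaf.radii
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _check_gamut(color, what: str) -> None:
    if any(not (0 <= c <= 255) for c in color):
        raise SceneSpecError(f"{what} color {color} leaves the [0, 255] gamut")


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Rasterize a scene; return the image and a per-leaf truth table.

    Truth columns: ``leaf`` (1-based, in spec order), ``area`` (pixels),
    ``mean_r/g/b`` (realized channel means of the rendered leaf pixels).
    Deterministic for a given seed.
    """
    h, w = spec.canvas
    _check_gamut(spec.background_color, "background")
    rng = np.random.default_rng(spec.seed)
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = np.asarray(spec.background_color, dtype=np.uint8)

    ref_mask = np.zeros((h, w), dtype=bool)
    if spec.white_ref is not None:
        roi, color = spec.white_ref
        _check_gamut(color, "white reference")
        roi.validate_within(img)
        ref_mask[roi.slices()] = True
        img[roi.slices()] = np.asarray(color, dtype=np.uint8)

    claimed = ref_mask.copy()
    rows = []
    for i, leaf in enumerate(spec.leaves, start=1):
        _check_gamut(leaf.mean_color, f"leaf {i}")
        mask = _ellipse_mask((h, w), leaf)
        if not mask.any():
            raise SceneSpecError(f"leaf {i} rasterizes to zero pixels")
        if (mask & claimed).any():
            raise SceneSpecError(f"leaf {i} overlaps another shape or the reference")
        claimed |= mask
        n = int(mask.sum())
        pixels = np.asarray(leaf.mean_color, dtype=float) + rng.normal(
            0.0, np.asarray(leaf.noise_sd, dtype=float), size=(n, 3)
        )
        pixels = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)
        img[mask] = pixels
        rows.append(
            {
                "leaf": i,
                "area": n,
                "mean_r": float(pixels[:, 0].mean()),
                "mean_g": float(pixels[:, 1].mean()),
                "mean_b": float(pixels[:, 2].mean()),
            }
        )
    truth = pd.DataFrame(rows, columns=["leaf", "area", "mean_r", "mean_g", "mean_b"])
    return img, truth


# --- senescence series -----------------------------------------------------

#: Latent chlorophyll of a fully green leaf, mg/cm^2.
DEFAULT_CHL_MAX = 0.04

#: Mean leaf RGB at zero chlorophyll (senesced, yellow).
YELLOW_RGB = (180.0, 170.0, 60.0)
#: Mean leaf RGB at DEFAULT_CHL_MAX (healthy, green).
GREEN_RGB = (60.0, 140.0, 50.0)


@dataclass(frozen=True)
class AffineColorModel:
    """Mean leaf RGB as an affine function of latent chlorophyll.

    ``rgb(chl) = intercept + slope * chl`` per channel, chlorophyll in
    mg/cm^2.
    """

    intercept: tuple[float, float, float] = YELLOW_RGB
    slope: tuple[float, float, float] = tuple(
        (g - y) / DEFAULT_CHL_MAX for g, y in zip(GREEN_RGB, YELLOW_RGB)
    )

    def rgb(self, chl: float) -> tuple[float, float, float]:
        return tuple(i + s * chl for i, s in zip(self.intercept, self.slope))


@dataclass(frozen=True)
class SeriesSpec:
    n_samples: int = 30
    chl_range: tuple[float, float] = (0.0, DEFAULT_CHL_MAX)
    color_model: AffineColorModel = field(default_factory=AffineColorModel)
    noise_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0
    canvas: tuple[int, int] = (70, 90)
    white_ref_roi: Roi = field(default_factory=lambda: Roi(2, 2, 14, 14))
    white_ref_color: tuple[int, int, int] = (255, 255, 255)


#: HSV bounds that isolate the leaf in series scenes: the black background
#: fails the value floor and the white reference fails the saturation floor.
SERIES_HSV_BOUNDS = HsvBounds(s_min=60, v_min=60, min_area=50)


def render_series(spec: SeriesSpec) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Render one single-leaf scene per chlorophyll level.

    Chlorophyll values are evenly spaced over ``chl_range``.  Truth columns:
    ``sample`` (1-based), ``chl`` (latent, mg/cm^2), ``gen_r/g/b`` (the
    color model's exact output) and ``mean_r/g/b`` (realized leaf means).
    """
    if spec.n_samples < 1:
        raise SceneSpecError("n_samples must be >= 1")
    chls = np.linspace(spec.chl_range[0], spec.chl_range[1], spec.n_samples)
    for chl in (spec.chl_range[0], spec.chl_range[1]):
        color = spec.color_model.rgb(chl)
        if any(not (0 <= c <= 255) for c in color):
            raise SceneSpecError(
                f"color model leaves gamut at chl={chl}: {color}"
            )
    images: list[np.ndarray] = []
    rows = []
    for i, chl in enumerate(chls, start=1):
        color = spec.color_model.rgb(float(chl))
        leaf = LeafSpec(
            center=(45.0, 45.0),
            radii=(18.0, 30.0),
            mean_color=color,
            noise_sd=spec.noise_sd,
        )
        scene = SceneSpec(
            canvas=spec.canvas,
            background_color=(0, 0, 0),
            white_ref=(spec.white_ref_roi, spec.white_ref_color),
            leaves=(leaf,),
            seed=spec.seed + i,
        )
        img, truth = render_scene(scene)
        images.append(img)
        rows.append(
            {
                "sample": i,
                "chl": float(chl),
                "gen_r": color[0],
                "gen_g": color[1],
                "gen_b": color[2],
                "mean_r": truth.loc[0, "mean_r"],
                "mean_g": truth.loc[0, "mean_g"],
                "mean_b": truth.loc[0, "mean_b"],
            }
        )
    return images, pd.DataFrame(rows)
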