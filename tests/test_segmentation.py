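import numpy as np
import pytest

from greenleafvi.segmentation import (
    HsvBounds,
    build_mask,
    filter_by_area,
    remove_background,
    rgb_to_hsv255,
    segment,
)

from conftest import random_rgb_image
from oracles import flood_fill_label, hsv255_pixel, hsv_predicate, labelings_equivalent


@pytest.mark.parametrize(
    "rgb,expected_hsv",
    [
        ((255, 0, 0), (0, 255, 255)),
        ((0, 255, 0), (85, 255, 255)),  # 120 deg * 255/360
        ((0, 0, 255), (170, 255, 255)),
        ((128, 128, 128), (0, 0, 128)),
        ((0, 0, 0), (0, 0, 0)),
    ],
)
def test_hsv_conversion_known_colors(rgb, expected_hsv):
    img = np.array([[rgb]], dtype=np.uint8)
    h, s, v = rgb_to_hsv255(img)
    assert (int(h[0, 0]), int(s[0, 0]), int(v[0, 0])) == expected_hsv


def test_hsv_matches_exact_rational_oracle():
    """Vectorized conversion is bit-exact against per-pixel rational arithmetic."""
    rng = np.random.default_rng(42)
    img = rng.integers(0, 256, size=(40, 40, 3), dtype=np.uint8)
    h, s, v = rgb_to_hsv255(img)
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            r, g, b = (int(c) for c in img[y, x])
            assert hsv255_pixel(r, g, b) == (int(h[y, x]), int(s[y, x]), int(v[y, x]))


def test_vacuous_bounds_select_everything():
    rng = np.random.default_rng(0)
    img = rng.integers(0, 256, size=(10, 10, 3), dtype=np.uint8)
    h, s, v = rgb_to_hsv255(img)
    assert build_mask(h, s, v, HsvBounds()).all()


def test_green_disk_mask_on_red_background():
    img = np.empty((40, 40, 3), dtype=np.uint8)
    img[:] = (200, 0, 0)
    yy, xx = np.mgrid[:40, :40]
    disk = (yy - 20) ** 2 + (xx - 20) ** 2 <= 10**2
    img[disk] = (0, 255, 0)
    h, s, v = rgb_to_hsv255(img)
    mask = build_mask(h, s, v, HsvBounds(h_min=60, h_max=110))
    assert (mask == disk).all()


def test_wrapping_hue_interval_selects_red_seam():
    """h_min > h_max wraps through 0, catching hues on both sides of the seam."""
    img = np.array([[(255, 10, 0), (255, 0, 20), (0, 255, 0)]], dtype=np.uint8)
    h, s, v = rgb_to_hsv255(img)
    mask = build_mask(h, s, v, HsvBounds(h_min=240, h_max=10))
    assert mask.tolist() == [[True, True, False]]
    for x in range(3):
        r, g, b = (int(c) for c in img[0, x])
        assert hsv_predicate(r, g, b, HsvBounds(h_min=240, h_max=10)) == bool(mask[0, x])


def _disk_mask(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def test_min_area_filter_on_disk():
    mask = _disk_mask((40, 40), (20, 20), 15)
    area = int(mask.sum())
    labels = filter_by_area(mask, 100)
    assert labels.max() == 1
    assert (labels > 0).sum() == area
    assert filter_by_area(mask, area + 1).max() == 0
    assert filter_by_area(np.zeros((5, 5), dtype=bool), 0).max() == 0


def test_labels_are_consecutive_raster_order():
    mask = np.zeros((20, 60), dtype=bool)
    mask[2:6, 40:50] = True   # first pixel later in raster order than...
    mask[1:5, 5:15] = True    # ...this one
    mask[10:18, 20:30] = True
    labels = filter_by_area(mask, 1)
    assert sorted(np.unique(labels).tolist()) == [0, 1, 2, 3]
    assert labels[1, 5] == 1   # earliest first pixel
    assert labels[2, 40] == 2
    assert labels[10, 20] == 3


def test_remove_background():
    rng = np.random.default_rng(5)
    img = rng.integers(0, 256, size=(10, 10, 3), dtype=np.uint8)
    labels = np.zeros((10, 10), dtype=np.int32)
    assert (remove_background(img, labels) == 0).all()
    labels[:] = 1
    assert (remove_background(img, labels) == img).all()
    with pytest.raises(ValueError):
        remove_background(img, np.zeros((5, 5), dtype=np.int32))


def test_two_disks_min_area_keeps_only_large():
    img = np.empty((60, 100, 3), dtype=np.uint8)
    img[:] = (250, 250, 250)
    big = _disk_mask((60, 100), (30, 30), 14)
    small = _disk_mask((60, 100), (30, 75), 5)
    img[big] = (60, 140, 50)
    img[small] = (60, 140, 50)
    assert big.sum() >= 600 and small.sum() <= 100
    segmented, labels = segment(img, HsvBounds(s_min=60, v_min=60, min_area=100))
    assert labels.max() == 1
    assert (labels[big] == 1).all()
    assert (segmented[~big] == 0).all()
    assert (segmented[big] == (60, 140, 50)).all()


def test_bounds_matching_nothing():
    img = np.full((10, 10, 3), (250, 250, 250), dtype=np.uint8)
    segmented, labels = segment(img, HsvBounds(s_min=200, min_area=1))
    assert labels.max() == 0
    assert (segmented == 0).all()


@pytest.mark.parametrize("connectivity", [4, 8])
def test_labeling_matches_flood_fill_oracle(connectivity):
    """Full segmentation agrees with per-pixel predicate + naive flood fill."""
    rng = np.random.default_rng(2024)
    for _ in range(30):
        img = random_rgb_image(rng, max_side=32)
        bounds = HsvBounds(
            h_min=int(rng.integers(0, 256)),
            h_max=int(rng.integers(0, 256)),
            s_min=0,
            s_max=int(rng.integers(100, 256)),
            v_min=int(rng.integers(0, 100)),
            v_max=255,
            min_area=int(rng.integers(0, 20)),
        )
        _, labels = segment(img, bounds, connectivity=connectivity)

        oracle_mask = np.zeros(img.shape[:2], dtype=bool)
        for y in range(img.shape[0]):
            for x in range(img.shape[1]):
                r, g, b = (int(c) for c in img[y, x])
                oracle_mask[y, x] = hsv_predicate(r, g, b, bounds)
        oracle_labels = flood_fill_label(oracle_mask, bounds.min_area, connectivity)
        assert labelings_equivalent(labels, oracle_labels)
        # every retained pixel satisfies the bounds; every object >= min_area
        counts = np.bincount(labels.ravel())
        assert (counts[1:] >= max(bounds.min_area, 1)).all()
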