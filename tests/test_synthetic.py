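import numpy as np
import pytest

from greenleafvi.image_io import Roi
from greenleafvi.measure import measure_objects
from greenleafvi.segmentation import segment
from greenleafvi.synthetic import (
    SERIES_HSV_BOUNDS,
    AffineColorModel,
    LeafSpec,
    SceneSpec,
    SceneSpecError,
    SeriesSpec,
    render_scene,
    render_series,
)
from greenleafvi.white_balance import apply_white_balance


def test_zero_noise_leaf_pixels_exact(green_disk_scene):
    img, truth = green_disk_scene
    assert truth.loc[0, ["mean_r", "mean_g", "mean_b"]].tolist() == [60.0, 140.0, 50.0]


def test_truth_area_matches_brute_force_rasterization():
    leaf = LeafSpec(center=(20.0, 25.0), radii=(15.0, 10.0), mean_color=(60.0, 140.0, 50.0))
    spec = SceneSpec(canvas=(45, 50), leaves=(leaf,))
    _, truth = render_scene(spec)
    count = 0
    for y in range(45):
        for x in range(50):
            if ((y - 20.0) / 15.0) ** 2 + ((x - 25.0) / 10.0) ** 2 <= 1.0:
                count += 1
    assert truth.loc[0, "area"] == count


def test_zero_leaves_gives_pure_background():
    img, truth = render_scene(SceneSpec(canvas=(10, 12), background_color=(7, 8, 9)))
    assert truth.empty
    assert (img == (7, 8, 9)).all()


def test_seeded_determinism():
    leaf = LeafSpec(center=(20.0, 20.0), radii=(8.0, 8.0),
                    mean_color=(100.0, 150.0, 40.0), noise_sd=(5.0, 5.0, 5.0))
    spec = SceneSpec(canvas=(40, 40), leaves=(leaf,), seed=13)
    a, ta = render_scene(spec)
    b, tb = render_scene(spec)
    assert (a == b).all()
    assert ta.equals(tb)


def test_overlapping_shapes_rejected():
    leaves = (
        LeafSpec(center=(20.0, 20.0), radii=(10.0, 10.0), mean_color=(60.0, 140.0, 50.0)),
        LeafSpec(center=(25.0, 25.0), radii=(10.0, 10.0), mean_color=(180.0, 170.0, 60.0)),
    )
    with pytest.raises(SceneSpecError, match="overlaps"):
        render_scene(SceneSpec(canvas=(50, 50), leaves=leaves))
    with pytest.raises(SceneSpecError, match="gamut"):
        render_scene(SceneSpec(canvas=(20, 20), leaves=(
            LeafSpec(center=(10.0, 10.0), radii=(4.0, 4.0), mean_color=(300.0, 0.0, 0.0)),)))


def test_noisy_truth_records_realized_means():
    leaf = LeafSpec(center=(20.0, 20.0), radii=(10.0, 12.0),
                    mean_color=(100.0, 150.0, 40.0), noise_sd=(4.0, 4.0, 4.0))
    img, truth = render_scene(SceneSpec(canvas=(40, 40), leaves=(leaf,), seed=5))
    yy, xx = np.mgrid[:40, :40]
    mask = ((yy - 20.0) / 10.0) ** 2 + ((xx - 20.0) / 12.0) ** 2 <= 1.0
    for c, col in enumerate(["mean_r", "mean_g", "mean_b"]):
        assert truth.loc[0, col] == pytest.approx(img[mask][:, c].mean(), abs=1e-12)


def test_full_pipeline_closure_zero_noise(green_disk_scene):
    """White-balance -> segment -> measure recovers the analytic leaf color."""
    img, truth = green_disk_scene
    ref = Roi(2, 2, 12, 12)
    wb = apply_white_balance(img, ref)
    # predictable analytically: leaf color scaled by the factors, rounded half-to-even
    expected = np.clip(np.rint(np.array([60, 140, 50]) * np.array(wb.adjustment_factors)), 0, 255)
    _, labels = segment(wb.balanced_image, SERIES_HSV_BOUNDS)
    (st,) = measure_objects(wb.balanced_image, labels, exclude_roi=ref)
    assert st.area == truth.loc[0, "area"]
    assert (st.mean_r, st.mean_g, st.mean_b) == tuple(expected)


def test_series_follows_affine_color_model():
    model = AffineColorModel(intercept=(150.0, 60.0, 50.0), slope=(0.0, 4000.0, 0.0))
    spec = SeriesSpec(n_samples=5, chl_range=(0.0, 0.02), color_model=model)
    images, truth = render_series(spec)
    assert len(images) == 5
    assert truth["chl"].tolist() == pytest.approx([0.0, 0.005, 0.01, 0.015, 0.02])
    assert truth["gen_g"].tolist() == pytest.approx([60.0, 80.0, 100.0, 120.0, 140.0])
    assert (truth["gen_r"] == 150.0).all()


def test_series_gamut_violation_rejected():
    model = AffineColorModel(intercept=(150.0, 60.0, 50.0), slope=(0.0, 40000.0, 0.0))
    with pytest.raises(SceneSpecError, match="gamut"):
        render_series(SeriesSpec(n_samples=3, chl_range=(0.0, 0.02), color_model=model))


def test_default_senescence_model_spans_green_to_yellow():
    spec = SeriesSpec(n_samples=3)
    _, truth = render_series(spec)
    assert truth.iloc[0][["gen_r", "gen_g", "gen_b"]].tolist() == [180.0, 170.0, 60.0]
    assert truth.iloc[-1][["gen_r", "gen_g", "gen_b"]].tolist() == [60.0, 140.0, 50.0]
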