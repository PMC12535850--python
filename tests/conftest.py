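import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from greenleafvi.image_io import Roi
from greenleafvi.synthetic import LeafSpec, SceneSpec, render_scene


@pytest.fixture
def green_disk_scene():
    """One green elliptical leaf on a white background with a white reference."""
    spec = SceneSpec(
        canvas=(60, 80),
        background_color=(250, 250, 250),
        white_ref=(Roi(2, 2, 12, 12), (245, 248, 246)),
        leaves=(LeafSpec(center=(38.0, 45.0), radii=(14.0, 20.0), mean_color=(60.0, 140.0, 50.0)),),
        seed=0,
    )
    return render_scene(spec)


def random_rgb_image(rng: np.random.Generator, max_side: int = 64) -> np.ndarray:
    h = int(rng.integers(4, max_side + 1))
    w = int(rng.integers(4, max_side + 1))
    # mix flat patches and pure noise so connected components have structure
    if rng.random() < 0.5:
        img = rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
    else:
        img = np.empty((h, w, 3), dtype=np.uint8)
        img[:] = rng.integers(0, 256, size=3, dtype=np.uint8)
        for _ in range(int(rng.integers(1, 5))):
            y, x = int(rng.integers(0, h)), int(rng.integers(0, w))
            hh = int(rng.integers(1, h - y + 1))
            ww = int(rng.integers(1, w - x + 1))
            img[y : y + hh, x : x + ww] = rng.integers(0, 256, size=3, dtype=np.uint8)
    return img
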