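import numpy as np
import pytest

from spheroscreen import SimulationConfig, simulate_dataset
from spheroscreen.config import PROFILES


def make_disc(shape=(96, 96), radius=30.0, fg=0.85, bg=0.08, blur_sigma=0.0):
    """Analytic test image: centered bright disc on dark background."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full(shape, bg, dtype=np.float32)
    img[(yy - h / 2 + 0.5) ** 2 + (xx - w / 2 + 0.5) ** 2 <= radius**2] = fg
    if blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(img, blur_sigma)
    return img


@pytest.fixture(scope="session")
def smoke_dataset():
    """Reduced-scale labelled dataset (64x64 px, 60 images/class)."""
    cfg = PROFILES["smoke"]
    return simulate_dataset(per_class=cfg.per_class, seed=1, base_config=cfg.simulation)


@pytest.fixture()
def small_sim_config():
    return SimulationConfig(image_height=96, image_width=96, rng_seed=0)
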