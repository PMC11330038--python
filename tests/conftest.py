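import numpy as np
import pytest

import abquant as ab


@pytest.fixture(scope="session")
def default_config():
    return ab.PipelineConfig()


@pytest.fixture(scope="session")
def small_spec():
    """A 512x512 slide with one deposit of each class in known positions."""
    return ab.SyntheticSlideSpec(
        width_px=512,
        height_px=512,
        gm_fraction=0.6,
        deposits=[
            ab.DepositPlacement("cored", (160, 160), 30, "GM"),
            ab.DepositPlacement("diffuse", (160, 340), 28, "GM"),
            ab.DepositPlacement("CAA", (390, 256), 26, "WM"),
        ],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_slide(small_spec):
    slide, truth = ab.render_slide(small_spec)
    return slide, truth


@pytest.fixture(scope="session")
def noise_rgb():
    """A deterministic random RGB raster (not palette-conforming)."""
    rng = np.random.default_rng(42)
    return rng.integers(0, 256, size=(96, 96, 3), dtype=np.uint8)
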