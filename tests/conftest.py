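import numpy as np
import pytest

from neurorecon import (
    GaborBankSpec,
    SimulationConfig,
    build_gabor_bank,
    encode_images,
    fit_reverse_scale,
    generate_images,
)


@pytest.fixture(scope="session")
def paper_bank():
    """The full 1248-filter bank on the 32x32 raster."""
    return build_gabor_bank()


@pytest.fixture(scope="session")
def small_bank():
    """A cheap bank for unit tests that only need valid geometry."""
    spec = GaborBankSpec(
        image_side=16,
        scales=((32, 1, 0.04), (16, 3, 0.09), (8, 5, 0.18)),
    )
    return build_gabor_bank(spec)


@pytest.fixture(scope="session")
def natural_images(paper_bank):
    """1/f^2 random-phase image stack (the synthetic stimulus ensemble)."""
    cfg = SimulationConfig(seed=42, n_images=100)
    return generate_images(cfg)


@pytest.fixture(scope="session")
def fitted_bank(paper_bank, natural_images):
    return fit_reverse_scale(paper_bank, natural_images)


@pytest.fixture(scope="session")
def image_features(fitted_bank, natural_images):
    return encode_images(fitted_bank, natural_images)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
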