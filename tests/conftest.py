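import numpy as np
import pytest

from endowarp import MosaicSpec, generate_mosaic


@pytest.fixture(scope="session")
def clean_pair():
    """A 96x96 20-cell mosaic with no degradations (exact ground truth)."""
    return generate_mosaic(MosaicSpec(96, 96, n_cells=20, seed=7))


@pytest.fixture(scope="session")
def noisy_pair():
    """A realistic mosaic: guttae, illumination gradient, blur, noise."""
    return generate_mosaic(
        MosaicSpec(
            96, 96, n_cells=25, guttae_fraction=0.2, illumination_amplitude=0.15,
            blur_sigma=0.6, noise_sd=0.02, seed=11,
        )
    )


@pytest.fixture(scope="session")
def forty_cell_pair():
    """The 40-cell mosaic used for shift-bound and preservation checks."""
    return generate_mosaic(MosaicSpec(96, 96, n_cells=40, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
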