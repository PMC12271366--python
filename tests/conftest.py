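import numpy as np
import pytest

from nlomics.synthetic import TissuePhenotype, default_presets, generate_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def presets():
    return default_presets()


def small_phenotype(**overrides) -> TissuePhenotype:
    """A sparse, fast-to-render phenotype for unit tests."""
    params = dict(
        label="test",
        collagen_fiber_count=6,
        collagen_length_mean_um=30.0, collagen_length_sd_um=5.0,
        collagen_width_mean_um=4.0, collagen_width_sd_um=0.5,
        collagen_orientation_mean_deg=45.0, collagen_orientation_kappa=2.0,
        collagen_waviness=0.2,
        collagen_intensity_scale=300.0,
        myocardium_fiber_count=5, myocardium_orientation_kappa=3.0,
        myocardium_intensity_scale=300.0,
        myocardium_length_mean_um=80.0, myocardium_length_sd_um=10.0,
        background_level=10.0,
    )
    params.update(overrides)
    return TissuePhenotype(**params)


@pytest.fixture
def small_frame_pair():
    """One small (SHG, TPEF) frame pair with ground truth."""
    return generate_image(small_phenotype(), size_px=128, seed=11)
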