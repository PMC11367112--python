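import numpy as np
import pytest

from tevcf import synthetic as syn


@pytest.fixture
def protocol():
    return syn.make_default_protocol()


@pytest.fixture
def ground_truth():
    return syn.GatingGroundTruth()


@pytest.fixture
def clean_ground_truth():
    """Noise-free, bleach-free ground truth for exact-recovery tests."""
    return syn.GatingGroundTruth(noise_sd_current=0.0, noise_sd_fluor=0.0, bleach_rate=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_image_set():
    """A small ring-cell image pair shared by the imaging tests."""
    return syn.simulate_ratio_images(
        2.0, n_cells=3, image_size=(160, 160), background_level=50.0, noise_sd=2.0, rng=7
    )
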