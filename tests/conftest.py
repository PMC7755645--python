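import numpy as np
import pytest

from rcquant.augment import SegItem
from rcquant.phantom import PhantomSpec, generate_phantom, simulate_raters
from rcquant.train import TrainConfig, train_fold
from rcquant.unet import NetworkConfig


@pytest.fixture(scope="session")
def degenerated_case():
    """Noise-free 128px phantom with mixed degeneration on all muscles."""
    spec = PhantomSpec(
        image_size=128,
        atrophy_fraction=(0.2, 0.0, 0.5, 0.1),
        fat_fraction=(0.1, 0.3, 0.0, 0.2),
        bone_fraction=(0.05, 0.0, 0.0, 0.02),
        hu_noise_sd=0.0,
        seed=3,
    )
    return generate_phantom(spec, "degen")


@pytest.fixture(scope="session")
def noisy_case_with_raters():
    spec = PhantomSpec(image_size=128, atrophy_fraction=0.2, fat_fraction=0.15,
                       bone_fraction=0.0, hu_noise_sd=5.0, seed=7)
    return simulate_raters(generate_phantom(spec, "noisy"), n_raters=3,
                           boundary_sd_mm=0.5, seed=1)


@pytest.fixture(scope="session")
def trained_model():
    """A small network trained on 20 phantoms (one fold, truth masks).

    Shared across tests that need a functioning predictor; held-out cases
    come from the companion fixture below.
    """
    cases = _training_cohort()
    items = [
        AugmentedItem_identity(SegItem(c.case_id, -1, c.section, c.premorbid_masks))
        for c in cases
    ]
    model, log = train_fold(
        items, "SS", NetworkConfig(64, 4, 8),
        TrainConfig(max_epochs=25, patience=25, learning_rate=5e-3, seed=0),
    )
    return model


def AugmentedItem_identity(item):
    from rcquant.augment import AugmentedItem

    return AugmentedItem(item, 0.0, 0.0, True)


def _training_cohort():
    from rcquant.phantom import CohortSampler, generate_cohort

    return generate_cohort(20, CohortSampler(image_size=64), seed=42)


@pytest.fixture(scope="session")
def heldout_cases():
    """Phantoms the trained_model fixture never saw (different seed)."""
    from rcquant.phantom import CohortSampler, generate_cohort

    return generate_cohort(6, CohortSampler(image_size=64), seed=314)


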