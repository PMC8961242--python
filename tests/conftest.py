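import numpy as np
import pytest

from adir import phantom as ph
from adir.data import VolumeChannelStack


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic 32-cube phantom with lesions of every type."""
    return ph.make_tissue_phantom(
        shape=(32, 32, 32),
        spacing=(1.0, 1.0, 1.0),
        n_lesions=3,
        lesion_radius_range=(1.0, 1.6),
        seed=7,
        lesion_types=["intracortical", "juxtacortical", "mixed"],
    )


@pytest.fixture(scope="session")
def channel_stack(small_phantom):
    """Normalized predictor/target stack simulated from the phantom."""
    from adir.pipeline import simulate_subject

    return simulate_subject(small_phantom, noise_sd=0.0, seed=3, subject_id="sub-00")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_stack(rng):
    """Small random stack for geometry-only tests (no physics needed)."""
    pred = rng.uniform(-1, 1, size=(3, 24, 24, 24)).astype(np.float32)
    target = rng.uniform(-1, 1, size=(24, 24, 24)).astype(np.float32)
    mask = np.zeros((24, 24, 24), dtype=np.uint8)
    mask[4:20, 4:20, 4:20] = 1
    return VolumeChannelStack(
        predictors=pred, target=target, spacing=(1, 1, 1), mask=mask, subject_id="s"
    )
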