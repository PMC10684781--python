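import numpy as np
import pytest

from fcdetect.phantom import EFFECT_PRESETS, PhantomConfig, generate_subject


@pytest.fixture(scope="session")
def mirrored_config() -> PhantomConfig:
    """Exactly mirrored anatomy (no left/right jitter) for symmetry checks."""
    return PhantomConfig(seed=0, hemisphere_asym_sd=0.0)


@pytest.fixture(scope="session")
def control_subject(mirrored_config):
    return generate_subject(mirrored_config, is_patient=False, seed=11)


@pytest.fixture(scope="session")
def patient_subject():
    cfg = PhantomConfig(seed=0, lesion_effect=dict(EFFECT_PRESETS["strong"]))
    return generate_subject(cfg, is_patient=True, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
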