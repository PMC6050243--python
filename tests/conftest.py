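import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def regular_train():
    """50-ms metronome train over 2 s."""
    from spitrain import PulseTrain

    return PulseTrain(np.arange(0.0, 2.0001, 0.05), individual_id="metronome")


@pytest.fixture
def bimodal_train():
    from spitrain import simulate_spi, species_preset

    preset = species_preset("bimodal_burster")
    return simulate_spi(preset.config, seed=11, species_label=preset.name,
                        individual_id="bimodal-11")


@pytest.fixture
def broadband_train():
    from spitrain import simulate_spi, species_preset

    preset = species_preset("broadband_slow")
    return simulate_spi(preset.config, seed=11, species_label=preset.name,
                        individual_id="broadband-11")
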