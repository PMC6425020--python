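import numpy as np
import pytest
from hypothesis import settings

from megrsa import DesignSpec, EffectComponent, EffectSpec
from megrsa.synthetic_data import condition_table

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def small_components(**overrides):
    """Effect components that fit inside a short (-100..200 ms) epoch."""
    comps = {
        "image": EffectComponent(onset_ms=46.0, peak_ms=103.0, amplitude=0.32),
        "age": EffectComponent(onset_ms=60.0, peak_ms=120.0, amplitude=0.27),
        "gender": EffectComponent(onset_ms=72.0, peak_ms=125.0, amplitude=0.22),
        "identity": EffectComponent(onset_ms=91.0, peak_ms=125.0, amplitude=0.26),
    }
    comps.update(overrides)
    return comps


@pytest.fixture
def small_design():
    return DesignSpec(
        n_identities=8,
        images_per_identity=2,
        n_trials_per_condition=10,
        n_channels=12,
        tmin_ms=-100.0,
        tmax_ms=200.0,
        tstep_ms=10.0,
    )


@pytest.fixture
def small_effects():
    return EffectSpec(components=small_components(), noise_sd=1.0, seed=7)


@pytest.fixture
def small_conditions(small_design):
    return condition_table(small_design)


@pytest.fixture
def full_conditions():
    """The 80-condition default design table (16 identities x 5 images)."""
    return condition_table(DesignSpec())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
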