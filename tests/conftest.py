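import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from adc_texture import ADCVolume, PhantomSpec, TumorMask, VoxelSample, generate_phantom


def make_sample(values) -> VoxelSample:
    return VoxelSample(np.asarray(values, dtype=float))


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def textured_phantom():
    """Two-component textured phantom with a necrosis exclusion blob."""
    spec = PhantomSpec(
        component_means=(800.0, 1800.0),
        component_weights=(0.5, 0.5),
        spatial_correlation_length=3.0,
        noise_sd=50.0,
        necrosis_fraction=0.08,
        seed=11,
    )
    return generate_phantom(spec)


@pytest.fixture
def flat_phantom():
    """Single-component, noise-free phantom: a perfectly homogeneous tumor."""
    spec = PhantomSpec(
        component_means=(1200.0,),
        component_weights=(1.0,),
        noise_sd=0.0,
        seed=3,
    )
    return generate_phantom(spec)


def small_volume(values, spacing=(1.0, 1.0, 1.0)) -> ADCVolume:
    return ADCVolume(np.asarray(values, dtype=float), spacing=spacing)


def full_mask(shape) -> TumorMask:
    return TumorMask(np.ones(shape, dtype=bool))
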