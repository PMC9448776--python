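import numpy as np
import pytest

from morphdiverge.synthetic import (
    CohortSpec,
    EffectSpec,
    PipelineTransformSpec,
    SexEffect,
    box_region,
    default_mask,
    generate_dataset,
    make_cohort,
    make_latent_stack,
)
from morphdiverge.volio import Grid, VolumeStack


@pytest.fixture(scope="session")
def small_grid() -> Grid:
    return Grid(shape=(10, 10, 10), spacing=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def small_mask(small_grid) -> np.ndarray:
    return default_mask(small_grid)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    return make_cohort(CohortSpec(n_subjects=24, age_range=(18.0, 26.0), seed=3))


@pytest.fixture(scope="session")
def noise_stack(small_grid, small_mask) -> VolumeStack:
    """Pure-noise stack (no effects, no subject intercept) on the small grid."""
    table = make_cohort(CohortSpec(n_subjects=24, seed=9))
    effects = EffectSpec(subject_sd=0.0, voxel_noise_sd=0.05)
    return make_latent_stack(table, effects, small_grid, small_mask, seed=9)


@pytest.fixture(scope="session")
def small_dataset(small_grid, small_mask):
    """Small two-region dataset with 3 divergent pipelines, n=40."""
    sex_region = box_region(small_grid, (3, 5, 5), (3, 3, 3)) & small_mask
    effects = EffectSpec(
        sex_effects=(SexEffect(sex_region, d=1.0),),
        subject_sd=0.03,
        voxel_noise_sd=0.05,
    )
    transforms = (
        PipelineTransformSpec("clean", noise_sd=0.01, seed_offset=0),
        PipelineTransformSpec("biased", intensity_gain=0.95,
                              bias_field_amplitude=0.05,
                              displacement_voxels=(0.3, 0.2, 0.1),
                              noise_sd=0.03, seed_offset=1),
        PipelineTransformSpec("noisy", intensity_gain=1.05,
                              bias_field_amplitude=0.08,
                              displacement_voxels=(0.5, 0.4, 0.3),
                              extra_smooth_fwhm=2.0, noise_sd=0.06,
                              seed_offset=2),
    )
    return generate_dataset(
        CohortSpec(n_subjects=40, seed=11), effects, transforms,
        grid=small_grid, mask=small_mask,
    )
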