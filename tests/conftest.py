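"""Shared fixtures: small phantoms reused across test modules."""

import numpy as np
import pytest

from bundletrac import AxisField, BundleSpec, seeds_from_model, synthesize_bundle


@pytest.fixture(scope="session")
def small_clean():
    """7-filament noise-free bundle with the standard anisotropic PSF."""
    spec = BundleSpec(n_shells=1, length_voxels=120, noise_sigma=0.0)
    vol, truth = synthesize_bundle(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def small_noisy():
    """7-filament bundle at moderate noise, for denoising/variance checks."""
    spec = BundleSpec(n_shells=1, length_voxels=120, noise_sigma=0.5, rng_seed=7)
    vol, truth = synthesize_bundle(spec)
    clean_spec = BundleSpec(n_shells=1, length_voxels=120, noise_sigma=0.0)
    clean_vol, _ = synthesize_bundle(clean_spec)
    return spec, vol, clean_vol, truth


@pytest.fixture(scope="session")
def axis_y():
    return AxisField.constant((0.0, 1.0, 0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_seeds(truth, y0=15, slab_thickness=30):
    return seeds_from_model(truth, y0, slab_thickness)
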