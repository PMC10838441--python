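import numpy as np
import pytest

from chlorospec import (
    LeafSpectrumModel,
    calibrate_reflectance,
    generate_cube,
    generate_dataset,
    make_wavelength_grid,
    trim_to_range,
)

ANALYSIS_RANGE_NM = (437.0, 919.0)


@pytest.fixture(scope="session")
def camera_grid():
    """The 231-band grid spanning 387-1003 nm."""
    return make_wavelength_grid(387, 1003, 231)


@pytest.fixture(scope="session")
def small_dataset():
    """120 synthetic spectra trimmed to the 180-band analysis range."""
    ds = generate_dataset(n=120, seed=7)
    X, grid = trim_to_range(ds.X, ds.grid, *ANALYSIS_RANGE_NM)
    ds.X, ds.grid = X, grid
    return ds


@pytest.fixture(scope="session")
def calibrated_scene():
    """A fixed-seed synthetic scene together with its calibrated cube."""
    scene = generate_cube(spad=35.0, height=64, width=64, seed=1)
    refl = calibrate_reflectance(scene.cube, scene.references)
    return scene, refl


@pytest.fixture(scope="session")
def noise_free_model():
    return LeafSpectrumModel(noise_sd=0.0)
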