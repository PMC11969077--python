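"""Shared fixtures: small rendered WL datasets reused across test modules."""

import numpy as np
import pytest

from wliso.simulator import SimConfig, generate_wl_dataset
from wliso.wl_pipeline import analyze_wl_test, long_plan, short_plan

BB_TRUTH = (1.0, -0.5, 0.7)


@pytest.fixture(scope="session")
def noiseless_short_images():
    """Short WL test, noiseless, BB offset to a known 3D position."""
    cfg = SimConfig(
        bb_position=BB_TRUTH, wobble_sigma_mm=0.0, noise_sigma_rel=0.0,
        field_size_cm=10.0,
    )
    images, truth = generate_wl_dataset(short_plan(), cfg)
    return images, truth, cfg


@pytest.fixture(scope="session")
def noiseless_short_result(noiseless_short_images):
    images, _, _ = noiseless_short_images
    return analyze_wl_test(images)


@pytest.fixture(scope="session")
def noiseless_long_test():
    """56-image long test, noiseless, zero machine offsets, analyzed."""
    cfg = SimConfig(wobble_sigma_mm=0.0, noise_sigma_rel=0.0, field_size_cm=5.0)
    images, _ = generate_wl_dataset(long_plan(), cfg)
    return analyze_wl_test(images)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
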