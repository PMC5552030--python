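import numpy as np
import pytest

import barrier_slr as b


@pytest.fixture(scope="session")
def default_config():
    """Default nine-community landscape generator configuration."""
    return b.SyntheticConfig.default(shape=(380, 380), seed=2026)


@pytest.fixture(scope="session")
def large_landscape(default_config):
    """Default synthetic landscape with >= 1e5 land pixels."""
    return b.generate_landscape(default_config)


@pytest.fixture(scope="session")
def large_pixels(large_landscape):
    px = b.to_pixel_table(large_landscape)
    assert len(px) >= 10**5
    return px


@pytest.fixture(scope="session")
def large_matrix(large_pixels):
    """Full-resolution (1 mm step) community-elevation proportion matrix."""
    return b.build_matrix(large_pixels, step=0.001)


@pytest.fixture(scope="session")
def small_landscape():
    cfg = b.SyntheticConfig.default(shape=(120, 120), seed=7)
    return b.generate_landscape(cfg)


@pytest.fixture(scope="session")
def small_pixels(small_landscape):
    return b.to_pixel_table(small_landscape)


@pytest.fixture(scope="session")
def small_matrix(small_pixels):
    return b.build_matrix(small_pixels, step=0.01)


@pytest.fixture(scope="session")
def initial_proportions(large_pixels, large_matrix):
    return (
        large_pixels["community"]
        .value_counts(normalize=True)
        .reindex(list(large_matrix.communities))
        .fillna(0.0)
    )
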