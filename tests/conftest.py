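"""Shared fixtures: small synthetic chips reused across test modules."""

import numpy as np
import pytest

from beadscreen import SimConfig, default_panel, render_chip_image, sample_bead_layout


@pytest.fixture(scope="session")
def small_panel():
    """Four well-separated populations (two sizes x two dye ratios)."""
    return default_panel(4)


@pytest.fixture(scope="session")
def small_config(small_panel):
    return SimConfig(
        populations=tuple(small_panel.populations),
        image_shape=(760, 760),
        beads_per_population=50,
        min_center_distance=22.0,
        halo_amplitude_map={"P00": 800.0, "P01": 400.0},
        seed=101,
    )


@pytest.fixture(scope="session")
def small_chip(small_config):
    """A rendered 200-bead chip with its ground-truth layout."""
    rng = np.random.default_rng(small_config.seed)
    layout = sample_bead_layout(small_config, rng)
    image = render_chip_image(layout, small_config, rng)
    return image, layout


@pytest.fixture(scope="session")
def noise_free_config(small_config):
    import dataclasses

    return dataclasses.replace(
        small_config, shot_noise=False, read_noise_sd=0.0, encoding_cv=0.0, radius_cv=0.0
    )


@pytest.fixture(scope="session")
def noise_free_chip(noise_free_config):
    rng = np.random.default_rng(noise_free_config.seed)
    layout = sample_bead_layout(noise_free_config, rng)
    image = render_chip_image(layout, noise_free_config, rng)
    return image, layout
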