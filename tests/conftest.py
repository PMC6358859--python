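"""Shared fixtures: synthetic networks and renders reused across test modules."""

import warnings

import numpy as np
import pytest

from poreloadkit import synthetic as syn

warnings.filterwarnings("ignore", message=".*Level value.*")


@pytest.fixture(scope="session")
def dense_network():
    """Default study conditions: 60% porosity, 100 nm median bodies, 3 µm domain."""
    return syn.generate_network(syn.NetworkSpec(seed=1))


@pytest.fixture(scope="session")
def sparse_network():
    """Resolvable-wall conditions used for stereological D_AV comparisons."""
    return syn.generate_network(
        syn.NetworkSpec(seed=2, target_porosity=0.45, min_wall=12.0)
    )


@pytest.fixture(scope="session")
def cylinder_network():
    """Throat diameter equals body diameter: the no-ink-bottle reference case."""
    return syn.generate_network(
        syn.NetworkSpec(seed=4, throat_to_body_ratio=1.0, target_porosity=0.45, min_wall=12.0)
    )


@pytest.fixture(scope="session")
def clean_render(dense_network):
    """Artifact-free cross section plus its ground-truth mask."""
    rs = syn.RenderSpec(
        pixel_size=dense_network.domain_size / 512, image_size=(512, 512), seed=5
    )
    img, truth = syn.render_cross_section(dense_network, "z", 1500.0, rs)
    return img, truth


@pytest.fixture(scope="session")
def noisy_render(dense_network):
    """Cross section with default curtaining, gradient, and 10%-of-contrast noise."""
    rs = syn.RenderSpec(
        pixel_size=dense_network.domain_size / 512,
        image_size=(512, 512),
        seed=5,
        curtain_amplitude=15.0,
        gradient_amplitude=25.0,
        noise_sd=12.0,
    )
    img, truth = syn.render_cross_section(dense_network, "z", 1500.0, rs)
    return img, truth
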