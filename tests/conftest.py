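"""Shared fixtures: small meshes and short reference runs."""

import numpy as np
import pytest

from chmito import geometry


@pytest.fixture(scope="session")
def small_disk():
    """Coarse disk of radius 2 (~700 nodes), granule-free."""
    return geometry.build_domain("disk", [2.0], h_target=0.2)


@pytest.fixture(scope="session")
def disk_with_granule():
    """Disk of radius 2 with one pinned granule at (0.8, 0)."""
    g = geometry.GranuleSpec((0.8, 0.0), 0.5, 1.0)
    return geometry.build_domain("disk", [2.0], [g], h_target=0.2)


@pytest.fixture(scope="session")
def tiny_mesh():
    """Very small structured mesh (< 200 nodes) for brute-force oracles."""
    return geometry.rectangle_domain(2.0, 1.0, 0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
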