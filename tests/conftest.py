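"""Shared fixtures: small phantoms, density fields and meshes.

Heavier objects are session-scoped so the suite builds them once.
"""
from __future__ import annotations

import numpy as np
import pytest

from meshdir import (
    default_phantom, body_mask, extract_feature_edges, density_from_edges,
    feature_mesh,
)


@pytest.fixture(scope="session")
def phantom32():
    return default_phantom(32)


@pytest.fixture(scope="session")
def mask32(phantom32):
    return body_mask(phantom32, 0.01)


@pytest.fixture(scope="session")
def density32(phantom32):
    return density_from_edges(extract_feature_edges(phantom32))


@pytest.fixture(scope="session")
def mesh32(phantom32, mask32, density32):
    return feature_mesh(100, density32, mask32, phantom32.shape,
                        seed=1, max_iter=40)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
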