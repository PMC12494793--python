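import numpy as np
import pytest

from cryocrowd import simgen, structio


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def ball_blob_model():
    """~300-point ball-shaped cloud, radius 40 Å (rasterization fixture)."""
    r = np.random.default_rng(2)
    pts = r.standard_normal((300, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= r.uniform(0.4, 1.0, (300, 1)) ** (1 / 3) * 40
    return structio.model_from_points(pts, element="C")


@pytest.fixture
def small_pools():
    """Small synthetic template/distractor pools at 16 Å sampling."""
    r = np.random.default_rng(9)
    return simgen.make_synthetic_molecules(
        r, n_templates=2, n_distractors=6, size_range=(50.0, 110.0),
        voxel_size=16.0)


def tiny_node_model(n=30, seed=1, box=35.0):
    """Random CA-only cloud: every atom is its own elastic-network node."""
    r = np.random.default_rng(seed)
    return structio.model_from_points(r.uniform(0, box, (n, 3)),
                                      element="C", name="CA")
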