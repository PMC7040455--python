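import numpy as np
import pytest

from voxlight.normalmap import SmoothingConfig, compute_normal_map
from voxlight.phantoms import Medium, MediumTable, make_slab, make_sphere


@pytest.fixture(scope="session")
def sphere_scene_full():
    """Full-scale validation sphere: phantom, media, normal map, oracle."""
    from voxlight.experiments import build_sphere_scene
    return build_sphere_scene()


@pytest.fixture(scope="session")
def small_sphere():
    """60^3 water sphere in air with scattering, plus its normal map."""
    media = MediumTable([
        Medium(0, n=1.00, mua=0.1, mus=5.0, g=0.5),
        Medium(1, n=1.33, mua=0.5, mus=20.0, g=0.8),
    ])
    volume = make_sphere((60, 60, 60), 0.01, (0.3, 0.3, 0.3), 0.2,
                         media=media)
    normal_map = compute_normal_map(volume, media, SmoothingConfig(2.0))
    return volume, media, normal_map


@pytest.fixture(scope="session")
def mismatch_slab():
    """Two-layer slab with an index mismatch and scattering in both layers."""
    media = MediumTable([
        Medium(1, n=1.00, mua=0.5, mus=10.0, g=0.7),
        Medium(2, n=1.40, mua=1.0, mus=50.0, g=0.9),
    ])
    volume = make_slab((40, 40, 60), 0.01, 0.3, media=media)
    normal_map = compute_normal_map(volume, media, SmoothingConfig(2.0))
    return volume, media, normal_map


@pytest.fixture
def rng():
    return np.random.default_rng(42)
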