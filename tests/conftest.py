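import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nucleofiber import ParticlePose, ParticleSet, SceneSpec, generate_scene


def make_set(centers, rotations=None, tomo="t", pixel_size=1.0, ids=None):
    """Build a ParticleSet from raw centre coordinates (Å)."""
    centers = np.asarray(centers, dtype=float)
    n = len(centers)
    if rotations is None:
        rotations = [np.eye(3)] * n
    if ids is None:
        ids = range(n)
    poses = [
        ParticlePose(particle_id=int(i), tomo_id=tomo, center=centers[k], rotation=rotations[k])
        for k, i in enumerate(ids)
    ]
    return ParticleSet(poses, pixel_size_A=pixel_size)


def random_set(rng, n, tomo="t", box=2000.0):
    rots = Rotation.random(n, rng=rng).as_matrix()
    centers = rng.random((n, 3)) * box
    return make_set(centers, list(rots), tomo=tomo)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


NOISE_FREE = dict(
    spacing_sd_A=0.0,
    angle_jitter_deg=0.0,
    orientation_noise_deg=0.0,
    meander_deg=0.0,
    duplicate_rate=0.0,
    decoy_rate=0.0,
)


@pytest.fixture(scope="session")
def noise_free_scene():
    """Perfectly regular zigzag chains, no duplicates or decoys."""
    spec = SceneSpec(n_fibers=6, nucleosomes_per_fiber=20, seed=3, **NOISE_FREE)
    return generate_scene(spec)


@pytest.fixture(scope="session")
def default_scene():
    """One default-noise scene (~1500 particles with duplicates/decoys)."""
    return generate_scene(SceneSpec(seed=7))
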