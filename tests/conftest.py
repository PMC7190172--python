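import numpy as np
import pytest

from coregkit.synthetic_data import (SubjectSpec, generate_head_surface,
                                     generate_headshape,
                                     sample_ground_truth_transform)


def random_rigid(rng: np.random.Generator):
    """A uniformly random rigid transform (rotation via random quaternion)."""
    from coregkit.transforms import RigidTransform

    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    u, _, vt = np.linalg.svd(rot)
    return RigidTransform.from_rotation_translation(u @ vt,
                                                    rng.normal(0, 50, 3))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def coarse_subject():
    """A fast, noise-free subject on a coarse (642-vertex) mesh."""
    rng = np.random.default_rng(11)
    gt = sample_ground_truth_transform(rng)
    spec = SubjectSpec(seed=501, ground_truth=gt, noise_sd=0.0,
                       outlier_fraction=0.0, n_points=120,
                       mesh_subdivisions=3)
    surface = generate_head_surface(spec)
    headshape = generate_headshape(surface, spec)
    return spec, surface, headshape


@pytest.fixture(scope="session")
def noisy_subject():
    """A default-resolution subject with realistic digitization noise."""
    rng = np.random.default_rng(13)
    gt = sample_ground_truth_transform(rng)
    spec = SubjectSpec(seed=502, ground_truth=gt)
    surface = generate_head_surface(spec)
    headshape = generate_headshape(surface, spec)
    return spec, surface, headshape


@pytest.fixture
def unit_square_surface():
    """Two triangles tiling the unit square in the z = 0 plane."""
    from coregkit.surface import HeadSurface

    vertices = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
    triangles = np.array([[0, 1, 2], [0, 2, 3]])
    return HeadSurface(vertices, triangles)
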