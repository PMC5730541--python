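import numpy as np
import pytest
import trimesh

from mandasym.morphometry import SideMeasurements
from mandasym.reference import SIDE_STATS


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def unit_cube():
    return trimesh.creation.box(extents=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def icosphere10():
    """Radius-10 icosphere at subdivision 4 (discretisation error < 0.5 %)."""
    return trimesh.creation.icosphere(subdivisions=4, radius=10.0)


def side_means(group: str, role: str) -> SideMeasurements:
    """Published group-side means as a measurement vector (ramal height
    derived from its partition so the vector is geometrically consistent)."""
    s = SIDE_STATS[(group, role)]
    ch, irh = s["condylar_height"][0], s["inferior_ramal_height"][0]
    return SideMeasurements(
        body_length=s["body_length"][0],
        ramal_height=ch + irh,
        condylar_height=ch,
        inferior_ramal_height=irh,
        condylar_volume=s["condylar_volume"][0],
        gonial_angle=s["gonial_angle"][0],
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
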