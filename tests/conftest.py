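import numpy as np
import pytest

from cycloscope.structure_io import annotate_cd
from cycloscope.synthetic_data import (
    CDBuildSpec,
    ComplexBuildSpec,
    GuestSpec,
    build_complex,
    build_ideal_cd,
)


@pytest.fixture(scope="session")
def ideal_cd():
    """Flat, circular, native builder host plus its ground truth."""
    return build_ideal_cd(CDBuildSpec(o4_radius=5.0))


@pytest.fixture(scope="session")
def ideal_host(ideal_cd):
    structure, _ = ideal_cd
    return annotate_cd(structure)[0]


@pytest.fixture(scope="session")
def guest_complex():
    """Two-host head-to-tail complex with a threaded guest."""
    spec = ComplexBuildSpec(guest=GuestSpec(ring_a_angle=70.0, ring_a_depth=0.5))
    return build_complex(spec)


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random proper rotation plus a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    trans = rng.uniform(-20, 20, 3)
    return rot, trans


def transform_structure(structure, rot, trans):
    out = structure.copy()
    out.set_coords(structure.coords @ rot.T + trans)
    return out
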