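import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from trisym import NumberingMap, Protomer, RigidTransform
from trisym import fixtures as fx


def protomer_from_points(points, chain_id="A", start=1):
    """Bare Cα-only protomer from an array of points (test helper)."""
    pts = np.asarray(points, dtype=float)
    return Protomer(
        chain_id,
        np.arange(start, start + len(pts)),
        ["ALA"] * len(pts),
        [{"CA": p.copy()} for p in pts],
        NumberingMap(),
    )


def random_rigid_transform(rng) -> RigidTransform:
    R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
    return RigidTransform(R, rng.uniform(-50, 50, size=3))


@pytest.fixture
def helix():
    return fx.make_ideal_helix(20)


@pytest.fixture
def bundle():
    # straight-line traces make the r·√3 ring closed form exact
    return fx.make_c3_bundle(n_residues=20, ring_radius=7.0, helix_radius=0.0)


@pytest.fixture
def gapped_pair():
    return fx.make_gapped_pair(protein_length=60, deleted_span=(28, 39), seed=11)
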