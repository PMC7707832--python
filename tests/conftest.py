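import numpy as np
import pytest

from igageom import (
    LatticeParams,
    make_bent_assembly,
    make_toy_fab,
)
from igageom.fab_sampler import ConformerSet
from igageom.geometry import RigidTransform


@pytest.fixture(scope="session")
def toy_fab():
    return make_toy_fab(n_atoms=80, arm_length=40.0, seed=3)


@pytest.fixture(scope="session")
def siga_like_assembly():
    """Synthetic assembly at the secretory-IgA default geometry (97°/30°)."""
    return make_bent_assembly(97.0, 30.0, seed=11)


@pytest.fixture()
def identity_conformer():
    """A one-conformer set that leaves the Fab in its input placement."""
    return ConformerSet(
        transforms=[RigidTransform.identity()],
        lattice_index=np.array([0]),
        spin_index=np.array([0]),
        params=LatticeParams(n_points=1, gamma=360.0),
    )


def brute_force_clash_count(fab, env_coords, cutoff, transform=None):
    """All-pairs reference for the clash rule (non-linker atoms only)."""
    coords = fab.coords[fab.nonlinker_mask()]
    if transform is not None:
        coords = transform.apply(coords)
    if len(env_coords) == 0:
        return 0
    d = np.linalg.norm(coords[:, None, :] - np.asarray(env_coords)[None, :, :], axis=2)
    return int((d.min(axis=1) <= cutoff).sum())
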