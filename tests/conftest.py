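"""Shared fixtures: small synthetic volumes sized for fast unit tests."""

import numpy as np
import pytest

from corealign.image_model import VoxelGrid
from corealign.synthetic import CoreSpec, PhantomSpec, make_core, make_phantom


def disc_slice(n: int, radius_vox: float, centre_vox: tuple[float, float],
               inside: float = 0.0, outside: float = -1000.0) -> np.ndarray:
    """One axial slice with a filled disc (voxel units)."""
    jj, ii = np.meshgrid(np.arange(n), np.arange(n), indexing="xy")
    mask = (jj - centre_vox[0]) ** 2 + (ii - centre_vox[1]) ** 2 <= radius_vox**2
    sl = np.full((n, n), outside, dtype=np.float32)
    sl[mask] = inside
    return sl


def disc_grid(n: int = 512, radius_vox: float = 50.0, centre_vox=(256.0, 256.0),
              nz: int = 1, spacing_xy: float = 1.0, spacing_z: float = 1.0) -> VoxelGrid:
    sl = disc_slice(n, radius_vox, centre_vox)
    return VoxelGrid(np.repeat(sl[None], nz, axis=0), spacing_xy, spacing_z)


@pytest.fixture(scope="session")
def small_phantom_spec() -> PhantomSpec:
    # geometrically faithful scaled-down phantom: full 143 mm length and
    # 0.39 mm voxels but fewer slices via a coarser increment would change
    # the study conditions, so shrink only the in-plane sampling cost by
    # keeping the default radius/FOV and cutting the length
    return PhantomSpec(length=60.0, inset_z_range=(-20.0, 10.0))


@pytest.fixture(scope="session")
def small_phantom(small_phantom_spec):
    return make_phantom(small_phantom_spec)


@pytest.fixture(scope="session")
def default_phantom():
    """The full default phantom (the study conditions); generated once."""
    return make_phantom()


@pytest.fixture(scope="session")
def small_core():
    spec = CoreSpec(length=45.0, diameter=60.0, clast_count=8, seed=11,
                    clast_semiaxis_range=(2.0, 6.0))
    return make_core(spec), spec
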