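import numpy as np
import pytest

from ventrivol.phantom import PhantomSpec, ScanProtocol, Ellipsoid, make_phantom, scan_phantom
from ventrivol.volume import CTVolume


@pytest.fixture(scope="session")
def small_phantom():
    """A full-geometry phantom at the smallest suite scale."""
    return make_phantom(0.951, seed=1)


@pytest.fixture(scope="session")
def fast_protocol():
    """Reduced scan grid for registration-heavy tests: 96 px, uniform 5 mm."""
    return ScanProtocol(grid=96, fov_mm=200.0, fine_thickness=5.0,
                        coarse_thickness=5.0, z_min=-65.0, z_max=65.0,
                        noise_sigma=0.0)


@pytest.fixture(scope="session")
def small_scan(small_phantom):
    """Default-protocol noisy scan plus ground truth, shared across tests."""
    proto = ScanProtocol()
    vol, truth = scan_phantom(small_phantom, proto, seed=11)
    return vol, truth


@pytest.fixture(scope="session")
def phantom_slice(small_scan):
    """One mid-stack slice containing substantial ventricle."""
    vol, truth = small_scan
    areas = truth.n_vk
    k = int(np.argmax(areas))
    return vol.voxels[k], truth.data[k]


@pytest.fixture
def ramp_volume():
    """Linear intensity field a + b.z + c.y + d.x on an anisotropic grid."""
    K, R, C = 6, 10, 12
    pos = np.array([0.0, 3.0, 6.0, 9.0, 16.0, 23.0])  # mixed 3/7 mm spacing
    coeff = (5.0, 0.7, -0.3, 0.9)
    zz = pos[:, None, None]
    yy = (np.arange(R) * 1.25)[None, :, None]
    xx = (np.arange(C) * 1.25)[None, None, :]
    vox = coeff[0] + coeff[1] * zz + coeff[2] * yy + coeff[3] * xx
    vol = CTVolume(
        voxels=np.broadcast_to(vox, (K, R, C)).copy(),
        pixel_spacing=1.25,
        slice_thickness=np.array([3, 3, 3, 7, 7, 7], dtype=float),
        slice_positions=pos,
    )
    return vol, coeff


def sphere_spec(radius_mm: float = 28.79) -> PhantomSpec:
    """Pure-sphere cavity variant with a closed-form volume oracle.

    The brain matrix is shrunk to a compact ball so the variant also fits
    small test fields of view.
    """
    r = radius_mm + 6.0
    return PhantomSpec(
        brain_semi_axes=(r, r, r),
        ventricle_solids=[Ellipsoid(center=(0.0, 0.0, 0.0),
                                    semi_axes=(radius_mm,) * 3)],
    )
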