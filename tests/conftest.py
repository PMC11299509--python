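import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def digitized_sphere(radius_vox: int, pad: int = 4) -> np.ndarray:
    """Boolean ball of the given radius on the voxel grid."""
    n = 2 * (radius_vox + pad)
    z, y, x = np.mgrid[:n, :n, :n]
    c = (n - 1) / 2.0
    return (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= radius_vox**2


def digitized_cube(side_vox: int, pad: int = 3) -> np.ndarray:
    n = side_vox + 2 * pad
    m = np.zeros((n, n, n), dtype=bool)
    m[pad : pad + side_vox, pad : pad + side_vox, pad : pad + side_vox] = True
    return m


def digitized_ellipsoid(semi_axes_vox, pad: int = 4) -> np.ndarray:
    a = np.asarray(semi_axes_vox, dtype=float)
    n = int(2 * (a.max() + pad))
    z, y, x = np.mgrid[:n, :n, :n]
    c = (n - 1) / 2.0
    return ((z - c) / a[0]) ** 2 + ((y - c) / a[1]) ** 2 + ((x - c) / a[2]) ** 2 <= 1.0
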