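import numpy as np
import pytest

import flowtke as ft


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free whole-heart phantom at reduced size (32^3, 10 frames)."""
    spec = ft.default_spec(grid_shape=(32, 32, 32), n_frames=10, seed=7)
    return ft.build_phantom(spec)


@pytest.fixture(scope="session")
def cylinder_mask():
    """Voxelized straight cylinder: (mask, voxel_size, radius_mm, axis_center)."""

    def make(radius_mm=15.0, voxel_size=2.8, n=48, z0=5, z1=42, cx_frac=0.4875):
        ax = np.arange(n, dtype=float) * voxel_size
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        cx = cy = cx_frac * n * voxel_size
        mask = ((x - cx) ** 2 + (y - cy) ** 2 <= radius_mm**2) & (z >= z0 * voxel_size) & (
            z <= z1 * voxel_size
        )
        return mask, voxel_size, radius_mm, (cx, cy)

    return make


@pytest.fixture
def uniform_acq():
    """Tiny acquisition factory with uniform sigma and velocity."""

    def make(sigma=0.0, u=0.0, venc=120.0, shape=(6, 6, 6, 4)):
        sig = np.full(shape + (3,), sigma)
        vel = np.full(shape + (3,), u)
        s0 = np.ones(shape)
        return ft.encode_signals(vel, sig, venc, s0, voxel_size=2.8)

    return make
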