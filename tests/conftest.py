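"""Shared fixtures: digitized analytic shapes and noiseless configurations."""

import numpy as np
import pytest

from syribbon_quant.image import ImageStack
from syribbon_quant.synthetic import NoiseModel, SimConfig

PAPER_VOXEL = (0.2, 0.08, 0.08)  # (dz, dy, dx) µm


def digitize_sphere(radius_um, voxel_size_zyx, pad=4, center_offset=(0.0, 0.0, 0.0)):
    """Binary voxelization of a sphere (voxel-center membership)."""
    dz, dy, dx = voxel_size_zyx
    shape = [int(np.ceil(2 * radius_um / d)) + 2 * pad for d in voxel_size_zyx]
    zz, yy, xx = np.indices(shape)
    cz = (shape[0] - 1) / 2 + center_offset[0] / dz
    cy = (shape[1] - 1) / 2 + center_offset[1] / dy
    cx = (shape[2] - 1) / 2 + center_offset[2] / dx
    d2 = ((zz - cz) * dz) ** 2 + ((yy - cy) * dy) ** 2 + ((xx - cx) * dx) ** 2
    return d2 <= radius_um**2


def digitize_cube(side_um, voxel_size_zyx, pad=4):
    dz, dy, dx = voxel_size_zyx
    n = [int(round(side_um / d)) for d in voxel_size_zyx]
    shape = [ni + 2 * pad for ni in n]
    m = np.zeros(shape, dtype=bool)
    m[pad:pad + n[0], pad:pad + n[1], pad:pad + n[2]] = True
    return m


def digitize_ellipsoid(semi_axes_zyx, voxel_size_zyx, pad=4):
    dz, dy, dx = voxel_size_zyx
    az, ay, ax = semi_axes_zyx
    shape = [int(np.ceil(2 * a / d)) + 2 * pad
             for a, d in zip(semi_axes_zyx, voxel_size_zyx)]
    zz, yy, xx = np.indices(shape)
    c = [(s - 1) / 2 for s in shape]
    rho = (((zz - c[0]) * dz / az) ** 2 + ((yy - c[1]) * dy / ay) ** 2
           + ((xx - c[2]) * dx / ax) ** 2)
    return rho <= 1.0


def mask_stack(mask, voxel_size_zyx, channel="spots", intensity=1000.0):
    """Wrap a binary mask as a single-channel ImageStack."""
    return ImageStack(mask[None].astype(float) * intensity, voxel_size_zyx, [channel])


@pytest.fixture
def noiseless_config():
    return SimConfig(
        stack_shape=(32, 120, 120),
        cell_semi_axes=(4.0, 4.0, 2.8),
        psf_sigma=None,
        noise=NoiseModel(enabled=False),
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
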