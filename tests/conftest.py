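"""Shared fixtures: small deterministic phantoms, projectors and meshes."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from qctfe import femodel, phantom, pipeline, projsim


@pytest.fixture(scope="session")
def desk_spec() -> phantom.PhantomSpec:
    """The pipeline's default (desk-scale) phantom geometry, fixed seed."""
    return dataclasses.replace(pipeline.RunConfig().base_spec, seed=0)


@pytest.fixture(scope="session")
def desk_phantom(desk_spec):
    """Phantom volume + body mask + calibration inserts at desk scale."""
    vol, body = phantom.make_vertebra_phantom(desk_spec)
    inserts = phantom.default_insert_set(desk_spec)
    vol = phantom.add_calibration_inserts(vol, inserts, body_mask=body)
    return vol, body, inserts


@pytest.fixture(scope="session")
def disk_image():
    """64x64 uniform disk attenuation image (1 mm pixels) and its geometry."""
    n = 64
    xs = (np.arange(n) + 0.5) - n / 2
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    r, mu0 = 20.0, 0.02
    disk = np.where(X**2 + Y**2 <= r**2, mu0, 0.0)
    return disk, r, mu0


@pytest.fixture(scope="session")
def disk_projector():
    geo = projsim.Geometry(n_angles=180, bin_width=1.0)
    return projsim.Projector((64, 64), 1.0, geo)


def make_cuboid(nx=12, ny=12, nz=22, hu=300.0, spacing=(1.0, 1.0, 1.0)):
    """10x10x20 mm homogeneous cuboid mask + HU volume with a 1-voxel pad."""
    mask = np.zeros((nx, ny, nz), bool)
    mask[1 : nx - 1, 1 : ny - 1, 1 : nz - 1] = True
    vol = phantom.VoxelVolume(np.full((nx, ny, nz), hu), spacing)
    return vol, mask


@pytest.fixture(scope="session")
def cuboid_mesh_materials():
    """Homogeneous cuboid mesh (2 mm elements) with uniform material."""
    vol, mask = make_cuboid()
    mesh = femodel.mask_to_tet_mesh(mask, vol.spacing, 2.0)
    mat = femodel.map_material(femodel.element_hu(mesh, vol))
    return mesh, mat
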