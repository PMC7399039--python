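"""Meshing and material mapping: subdivision identities, mapped constants."""

import numpy as np
import pytest

from qctfe import femodel, phantom
from qctfe.femodel import MaterialMapping, build_elasticity_tensor, map_material

from conftest import make_cuboid


def test_single_cell_gives_six_tets_with_exact_volume():
    mask = np.zeros((4, 4, 4), bool)
    mask[1:3, 1:3, 1:3] = True  # one 2 mm cube at 1 mm voxels
    mesh = femodel.mask_to_tet_mesh(mask, (1.0, 1.0, 1.0), 2.0)
    assert mesh.n_elements == 6
    assert mesh.total_volume == pytest.approx(8.0)


def test_cube_mask_counting():
    vol, mask = make_cuboid(nx=12, ny=12, nz=12)  # 10 mm cube
    mesh = femodel.mask_to_tet_mesh(mask, (1.0, 1.0, 1.0), 2.0)
    assert mesh.n_elements == 125 * 6
    assert mesh.total_volume == pytest.approx(1000.0)


def test_elliptical_cylinder_volume_within_5pct():
    # finely voxelized body so the cell-occupancy resampling, not the
    # voxelization itself, dominates the volume error
    spec = phantom.PhantomSpec(voxel_spacing=(0.5, 0.5, 0.5), grid_shape=(192, 192, 96))
    _, mask = phantom.make_vertebra_phantom(spec)
    mesh = femodel.mask_to_tet_mesh(mask, spec.voxel_spacing, 2.0)
    a, b = spec.body_half_axes
    analytic = np.pi * a * b * spec.body_height
    assert abs(mesh.total_volume - analytic) / analytic < 0.05
    mask_volume = mask.sum() * 0.5**3
    assert abs(mesh.total_volume - mask_volume) / mask_volume < 0.05


def test_face_sets_nonempty_and_disjoint(cuboid_mesh_materials):
    mesh, _ = cuboid_mesh_materials
    assert mesh.inferior_nodes.size > 0 and mesh.superior_nodes.size > 0
    assert not set(mesh.inferior_nodes) & set(mesh.superior_nodes)
    assert np.all(mesh.element_volumes > 0)


def test_edge_below_voxel_spacing_rejected():
    _, mask = make_cuboid()
    with pytest.raises(ValueError, match="edge"):
        femodel.mask_to_tet_mesh(mask, (1.0, 1.0, 2.0), 1.5)


def test_element_hu_constant_and_split_volume():
    vol, mask = make_cuboid(hu=300.0)
    mesh = femodel.mask_to_tet_mesh(mask, vol.spacing, 2.0)
    assert np.all(femodel.element_hu(mesh, vol) == 300.0)
    # two-valued volume split at the mid-plane in z
    vol2 = vol.copy()
    zmid = vol.shape[2] // 2
    vol2.values[:, :, :zmid] = 100.0
    vol2.values[:, :, zmid:] = 500.0
    hu = femodel.element_hu(mesh, vol2)
    centroids_z = mesh.nodes[mesh.elements, 2].mean(axis=1)
    low = centroids_z < zmid - 1.0
    high = centroids_z > zmid + 1.0
    assert np.all(hu[low] == 100.0)
    assert np.all(hu[high] == 500.0)


def test_element_hu_equals_bruteforce_cell_average():
    rng = np.random.default_rng(7)
    vol, mask = make_cuboid()
    vol.values[:] = rng.uniform(0, 500, vol.shape)
    mesh = femodel.mask_to_tet_mesh(mask, vol.spacing, 2.0)
    hu = femodel.element_hu(mesh, vol)
    centers = vol.voxel_centers()
    for e in rng.choice(mesh.n_elements, size=10, replace=False):
        c = np.unravel_index(mesh.cell_id[e], mesh.cell_grid_shape)
        lo = [mesh.cell_origin[a] + c[a] * mesh.cell_size_mm[a] for a in range(3)]
        hi = [lo[a] + mesh.cell_size_mm[a] for a in range(3)]
        sel = np.ones(vol.shape, bool)
        for a, ax in enumerate(np.meshgrid(*centers, indexing="ij")):
            sel &= (ax >= lo[a]) & (ax < hi[a])
        assert hu[e] == pytest.approx(vol.values[sel].mean())


def test_material_mapping_hand_values():
    m = map_material(100.0)
    assert m.rho_app[0] == pytest.approx(159.2)
    assert m.E_z[0] == pytest.approx(577.544)
    assert m.E_x[0] == pytest.approx(192.322152)
    assert m.G_xy[0] == pytest.approx(69.882824)
    assert m.G_xz[0] == pytest.approx(90.674408)
    # as-printed density direction: rho_app = 0.6 * rho_ash
    assert m.rho_ash[0] == pytest.approx(0.2653333, rel=1e-6)
    assert m.sigma_max[0] == pytest.approx(11.3097, rel=1e-4)
    assert m.sigma_min[0] == pytest.approx(5.02920, rel=1e-4)
    assert m.eps_ab[0] == pytest.approx(0.0161663, rel=1e-4)


def test_modulus_clamp_at_low_hu():
    root_hu = (349.0 / 5.82 - 47.0) / 1.122  # E_z crosses zero here (~11.56 HU)
    below = map_material(root_hu - 1.0)
    assert below.E_z[0] == MaterialMapping().e_min_mpa
    above = map_material(root_hu + 1.0)
    assert above.E_z[0] > MaterialMapping().e_min_mpa


def test_conventional_density_direction():
    m = map_material(100.0, MaterialMapping(ash_direction="conventional"))
    assert m.rho_ash[0] == pytest.approx(0.6 * 159.2 / 1000.0)
    # 0.09552 g/cc < 0.317 -> low branch
    assert m.sigma_max[0] == pytest.approx(137.0 * (0.09552) ** 1.88, rel=1e-4)


def test_sigma_branch_switch_at_threshold():
    mapping = MaterialMapping()
    # HU putting rho_ash just above 0.317 g/cc (as printed: rho_app = 190.2 mg/cc)
    hu_hi = ((0.3171 * 1000 * 0.6) - 47.0) / 1.122
    hi = map_material(hu_hi, mapping)
    assert hi.sigma_max[0] == pytest.approx(114.0 * hi.rho_ash[0] ** 1.72, rel=1e-6)


def test_mapping_monotone_in_hu():
    hu = np.linspace(-100, 1500, 400)
    m = map_material(hu)
    for field in (m.E_z, m.sigma_max, m.sigma_min, m.eps_ab):
        assert np.all(np.diff(field) >= 0)


def test_mapping_is_pure():
    a = map_material(np.array([50.0, 200.0]))
    b = map_material(np.array([50.0, 200.0]))
    assert np.array_equal(a.E_z, b.E_z) and np.array_equal(a.sigma_max, b.sigma_max)


def test_elasticity_isotropic_limit():
    E, nu = 1000.0, 0.3
    m = map_material(100.0)
    m.E_x[:] = m.E_y[:] = m.E_z[:] = E
    m.G_xy[:] = m.G_xz[:] = m.G_yz[:] = E / (2 * (1 + nu))
    m = femodel.ElementMaterial(**{**m.__dict__, "nu_p": nu, "nu_zp": nu})
    C = build_elasticity_tensor(m)[0]
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    iso = np.zeros((6, 6))
    iso[:3, :3] = lam
    iso[np.arange(3), np.arange(3)] = lam + 2 * mu
    iso[np.arange(3, 6), np.arange(3, 6)] = mu
    assert np.allclose(C, iso, rtol=1e-10)


def test_elasticity_positive_definite_and_xy_symmetric():
    C = build_elasticity_tensor(map_material(np.array([50.0, 100.0, 500.0, 1200.0])))
    assert np.all(np.linalg.eigvalsh(C) > 0)
    # swapping x and y leaves a transversely isotropic matrix invariant
    P = np.zeros((6, 6))
    for i, j in ((0, 1), (1, 0), (2, 2), (3, 4), (4, 3), (5, 5)):
        P[i, j] = 1.0
    for c in C:
        assert np.allclose(P @ c @ P.T, c, atol=1e-8 * np.abs(c).max())


def test_nonpositive_definite_raises():
    m = map_material(100.0)
    m = femodel.ElementMaterial(**{**m.__dict__, "nu_p": 0.99, "nu_zp": 0.99})
    with pytest.raises(ValueError, match="positive-definite"):
        build_elasticity_tensor(m)


def test_exports_write_valid_text_files(tmp_path, cuboid_mesh_materials):
    mesh, mat = cuboid_mesh_materials
    inp = tmp_path / "model.inp"
    vtu = tmp_path / "model.vtu"
    femodel.write_abaqus_inp(mesh, mat, inp)
    femodel.write_vtu(mesh, vtu, cell_data={"E_z": mat.E_z})
    text = inp.read_text()
    assert "*ELEMENT, TYPE=C3D4" in text and "*NSET, NSET=SUPERIOR" in text
    xml = vtu.read_text()
    assert xml.count("<DataArray") >= 4 and "UnstructuredGrid" in xml
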