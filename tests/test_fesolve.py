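"""FE solver: assembly oracle, closed-form checks, damage states, failure load."""

import numpy as np
import pytest

from qctfe import femodel, fesolve
from qctfe.femodel import map_material, mask_to_tet_mesh
from qctfe.fesolve import (
    FAILED,
    INTACT,
    YIELDED,
    BoundaryConditions,
    ElementStates,
    SolverConfig,
    assemble_stiffness,
    failure_load_from_curve,
    run_compression,
    solve_displacement_step,
    update_element_states,
)

from conftest import make_cuboid


def dense_assembly(mesh, material, scale=None):
    """Brute-force dense assembly: per-element loops, no vectorization."""
    C = femodel.build_elasticity_tensor(material)
    ndof = 3 * mesh.n_nodes
    K = np.zeros((ndof, ndof))
    for e in range(mesh.n_elements):
        conn = mesh.elements[e]
        p = mesh.nodes[conn]
        M = p[1:] - p[0]
        Minv = np.linalg.inv(M)
        grads = np.zeros((4, 3))
        grads[1:] = Minv.T
        grads[0] = -grads[1:].sum(axis=0)
        B = np.zeros((6, 12))
        for i in range(4):
            bx, by, bz = grads[i]
            B[0, 3 * i] = bx
            B[1, 3 * i + 1] = by
            B[2, 3 * i + 2] = bz
            B[3, 3 * i + 1] = bz
            B[3, 3 * i + 2] = by
            B[4, 3 * i] = bz
            B[4, 3 * i + 2] = bx
            B[5, 3 * i] = by
            B[5, 3 * i + 1] = bx
        s = 1.0 if scale is None else scale[e]
        Ke = s * mesh.element_volumes[e] * B.T @ C[e] @ B
        dof = np.concatenate([3 * conn[i] + np.arange(3) for i in range(4)])
        for a in range(12):
            for b in range(12):
                K[dof[a], dof[b]] += Ke[a, b]
    return K


@pytest.fixture(scope="module")
def small_mesh():
    mask = np.zeros((5, 4, 5), bool)
    mask[1:4, 1:3, 1:4] = True  # 8 cells -> 48 tets at 1.5 mm... keep < 50
    mesh = mask_to_tet_mesh(mask, (1.0, 1.0, 1.0), 1.5)
    rng = np.random.default_rng(0)
    mat = map_material(rng.uniform(50, 400, mesh.n_elements))
    return mesh, mat


def test_sparse_assembly_matches_dense_oracle(small_mesh):
    mesh, mat = small_mesh
    assert mesh.n_elements <= 50
    K = assemble_stiffness(mesh, mat).toarray()
    K_dense = dense_assembly(mesh, mat)
    assert np.allclose(K, K_dense, atol=1e-9 * np.abs(K_dense).max())
    rng = np.random.default_rng(1)
    scale = rng.uniform(0.05, 1.0, mesh.n_elements)
    K2 = assemble_stiffness(mesh, mat, scale).toarray()
    assert np.allclose(K2, dense_assembly(mesh, mat, scale), atol=1e-9 * np.abs(K2).max())


def test_single_tet_stiffness_has_six_rigid_modes():
    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    mesh = femodel.TetMesh(
        nodes=nodes,
        elements=np.array([[0, 1, 2, 3]]),
        element_volumes=np.array([1.0 / 6.0]),
        inferior_nodes=np.array([0]),
        superior_nodes=np.array([3]),
        cell_id=np.array([0]),
        cell_grid_shape=(1, 1, 1),
        cell_origin=(0.0, 0.0, 0.0),
        cell_size_mm=(1.0, 1.0, 1.0),
        target_edge_mm=1.0,
    )
    mat = map_material(np.array([200.0]))
    K = assemble_stiffness(mesh, mat).toarray()
    assert np.allclose(K, K.T)
    eig = np.linalg.eigvalsh(K)
    assert np.sum(np.abs(eig) < 1e-8 * eig.max()) == 6  # rigid translations + rotations


def test_stiffness_linearity_in_moduli(small_mesh):
    mesh, mat = small_mesh
    K1 = assemble_stiffness(mesh, mat)
    doubled = femodel.ElementMaterial(
        **{
            **mat.__dict__,
            **{
                f: 2 * getattr(mat, f)
                for f in ("E_z", "E_x", "E_y", "G_xy", "G_xz", "G_yz")
            },
        }
    )
    K2 = assemble_stiffness(mesh, doubled)
    assert np.allclose(K2.toarray(), 2 * K1.toarray(), rtol=1e-12)


def test_cuboid_axial_stiffness_closed_form(cuboid_mesh_materials):
    mesh, mat = cuboid_mesh_materials
    K = assemble_stiffness(mesh, mat)
    bc = BoundaryConditions.from_mesh(mesh)
    u, r, residual = solve_displacement_step(K, bc, -0.01)
    force = -r[3 * bc.driven_nodes + 2].sum()
    E_z, A, L = mat.E_z[0], 100.0, 20.0
    assert force / 0.01 == pytest.approx(E_z * A / L, rel=0.05)
    assert residual <= 1e-6


def test_reactions_balance_and_force_linearity(cuboid_mesh_materials):
    mesh, mat = cuboid_mesh_materials
    K = assemble_stiffness(mesh, mat)
    bc = BoundaryConditions.from_mesh(mesh)
    u1, r1, _ = solve_displacement_step(K, bc, -0.01)
    u2, r2, _ = solve_displacement_step(K, bc, -0.02)
    driven = 3 * bc.driven_nodes + 2
    fixed = np.concatenate([3 * bc.fixed_nodes + d for d in range(3)])
    total = r1[driven].sum() + r1[fixed].sum()
    assert abs(total) <= 1e-6 * abs(r1[driven]).sum()
    assert r2[driven].sum() == pytest.approx(2 * r1[driven].sum(), rel=1e-9)


def test_state_update_rules():
    mat = map_material(np.array([100.0, 100.0, 100.0]))
    states = ElementStates.fresh(3)
    sig_min = mat.sigma_min[0]
    # element 0 below limits, element 1 at twice the compressive limit,
    # element 2 in tension above sigma_max
    stresses = np.zeros((3, 6))
    stresses[1, 2] = -2.0 * sig_min
    stresses[2, 2] = 1.5 * mat.sigma_max[0]
    strains = np.zeros((3, 6))
    strains[1, 2] = -0.004
    strains[2, 2] = 0.004
    new, changed = update_element_states(stresses, strains, mat, states)
    assert changed
    assert new.state[0] == INTACT and new.scale[0] == 1.0
    assert new.state[1] == YIELDED
    assert new.scale[1] == pytest.approx(0.5)  # secant cap at the limit
    assert new.state[2] == YIELDED
    # no stresses above limits -> nothing changes
    unchanged, changed2 = update_element_states(np.zeros((3, 6)), np.zeros((3, 6)), mat, new)
    assert not changed2 and np.array_equal(unchanged.state, new.state)


def test_single_element_trace_intact_yield_fail():
    mat = map_material(np.array([100.0]))
    states = ElementStates.fresh(1)
    seq = [int(states.state[0])]
    eps_y = -mat.sigma_min[0] / mat.E_z[0]
    for step in range(1, 12):
        eps = eps_y * (1.0 + 0.35 * step)  # monotone compression past eps_AB
        stress = np.array([[0.0, 0.0, states.scale[0] * mat.E_z[0] * eps, 0, 0, 0]])
        strain = np.array([[0.0, 0.0, eps, 0, 0, 0]])
        states, _ = update_element_states(stress, strain, mat, states)
        seq.append(int(states.state[0]))
    assert seq[0] == INTACT
    assert YIELDED in seq
    assert states.state[0] == FAILED
    assert states.scale[0] == pytest.approx(0.05)
    # one-way transitions
    assert np.all(np.diff(seq) >= 0)


def test_cuboid_failure_load_matches_uniform_strength_bound(cuboid_mesh_materials):
    mesh, mat = cuboid_mesh_materials
    res = run_compression(mesh, mat, cfg=SolverConfig(n_steps=20))
    bound = mat.sigma_min[0] * 100.0  # sigma_min_limit * cross-section area
    assert res.failure_load_n == pytest.approx(bound, rel=0.10)
    assert res.max_residual <= 1e-6
    assert res.curve.force_n[0] == 0.0 and res.curve.displacement_mm[0] == 0.0


def test_curve_scales_exactly_with_material_scaling(cuboid_mesh_materials):
    mesh, mat = cuboid_mesh_materials
    c = 1.7
    scaled = femodel.ElementMaterial(
        **{
            **mat.__dict__,
            **{
                f: c * getattr(mat, f)
                for f in ("E_z", "E_x", "E_y", "G_xy", "G_xz", "G_yz",
                          "sigma_max", "sigma_min")
            },
        }
    )
    cfg = SolverConfig(n_steps=8)
    base = run_compression(mesh, mat, cfg=cfg)
    scl = run_compression(mesh, scaled, cfg=cfg)
    n = min(len(base.curve.force_n), len(scl.curve.force_n))
    assert np.allclose(scl.curve.force_n[:n], c * base.curve.force_n[:n], rtol=1e-8)


def test_element_state_counts_are_monotone(cuboid_mesh_materials):
    mesh, mat = cuboid_mesh_materials
    res = run_compression(mesh, mat, cfg=SolverConfig(n_steps=12))
    counts = res.curve.state_counts
    assert np.all(np.diff(counts[:, 0]) <= 0)  # intact never recovers
    assert np.all(np.diff(counts[:, 2]) >= 0)  # failed never heals


def test_failure_load_is_curve_peak():
    fl, u = failure_load_from_curve([0.0, 0.5, 1.0, 1.5], [0.0, 800.0, 1200.0, 950.0])
    assert fl == 1200.0 and u == 1.0


def test_stronger_bone_carries_more_load():
    wins = 0
    for seed in range(3):
        rng = np.random.default_rng(seed)
        vol, mask = make_cuboid()
        vol.values[:] = rng.uniform(50, 150, vol.shape)
        mesh = mask_to_tet_mesh(mask, vol.spacing, 2.0)
        low = run_compression(mesh, map_material(femodel.element_hu(mesh, vol)),
                              cfg=SolverConfig(n_steps=8))
        vol.values += 100.0
        high = run_compression(mesh, map_material(femodel.element_hu(mesh, vol)),
                               cfg=SolverConfig(n_steps=8))
        wins += high.failure_load_n > low.failure_load_n
    assert wins >= 2


def test_convergence_study_homogeneous_cuboid_varies_little():
    vol, mask = make_cuboid(nx=14, ny=14, nz=24)
    df = fesolve.mesh_convergence_study(vol, mask, edges_mm=[3.0, 2.5, 2.0, 1.5])
    assert len(df) == 4
    fl = df["failure_load_n"].to_numpy()
    assert np.all(np.isfinite(fl))
    assert (fl.max() - fl.min()) / fl.min() < 0.05  # nothing to resolve


def test_convergence_study_has_requested_rows(desk_phantom):
    vol, mask, _ = desk_phantom
    df = fesolve.mesh_convergence_study(vol, mask, edges_mm=[3.0, 2.75, 2.5])
    assert list(df["edge_mm"]) == [3.0, 2.75, 2.5]
    assert {"failure_load_n", "converged"} <= set(df.columns)
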