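"""Displacement-controlled nonlinear compression to vertebral failure load.

The inferior face is fixed in all directions; the superior face is driven
axially (transverse DOF free).  Loading is incremental: at each prescribed
displacement the linear system is re-solved while element damage states
are updated to a fixed point:

* INTACT -> YIELDED when the maximum principal stress exceeds sigma_max or
  the minimum principal stress drops below -sigma_min; the element's
  stiffness is then scaled by a secant factor limit/|driving stress| so
  its stress is capped at the limit;
* YIELDED -> FAILED when the post-yield principal strain (in excess of the
  strain at first yield) exceeds eps_AB; failed elements keep a small
  residual stiffness (default 5%).

Transitions are one-way, states are element-wise (exact for
constant-strain tetrahedra), and the whole run is deterministic.  The
failure load is the peak of the recorded force-displacement curve; if the
peak sits at the displacement cap the result is flagged censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

from .femodel import ElementMaterial, TetMesh, build_elasticity_tensor

__all__ = [
    "BoundaryConditions",
    "SolverConfig",
    "ForceDisplacementCurve",
    "FailureLoadResult",
    "ElementStates",
    "assemble_stiffness",
    "solve_displacement_step",
    "update_element_states",
    "run_compression",
    "failure_load_from_curve",
    "mesh_convergence_study",
]

INTACT, YIELDED, FAILED = 0, 1, 2


@dataclass
class BoundaryConditions:
    """Fixed (all DOF) and axially driven node sets; load axis is z."""

    fixed_nodes: np.ndarray
    driven_nodes: np.ndarray

    def __post_init__(self) -> None:
        self.fixed_nodes = np.asarray(self.fixed_nodes, dtype=np.int64)
        self.driven_nodes = np.asarray(self.driven_nodes, dtype=np.int64)
        if self.fixed_nodes.size == 0 or self.driven_nodes.size == 0:
            raise ValueError("fixed and driven node sets must be nonempty")
        if np.intersect1d(self.fixed_nodes, self.driven_nodes).size:
            raise ValueError("fixed and driven node sets must be disjoint")

    @classmethod
    def from_mesh(cls, mesh: TetMesh) -> "BoundaryConditions":
        return cls(mesh.inferior_nodes, mesh.superior_nodes)


@dataclass(frozen=True)
class SolverConfig:
    """Increment size, caps and damage parameters of the quasi-static run."""

    n_steps: int = 16
    max_displacement_frac: float = 0.02  # of specimen height
    max_displacement_mm: float | None = None  # overrides the fraction if set
    max_inner_iterations: int = 8
    damage_residual: float = 0.05
    scale_tolerance: float = 0.01
    equilibrium_tolerance: float = 1.0e-6
    early_stop_drop: float = 0.2  # stop once F < (1 - drop) * max F
    min_steps_before_stop: int = 4

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not 0 < self.damage_residual < 1:
            raise ValueError("damage_residual must be in (0, 1)")


@dataclass
class ForceDisplacementCurve:
    """Ordered (u, F) samples from (0, 0) plus element-state counts per step."""

    displacement_mm: np.ndarray
    force_n: np.ndarray
    state_counts: np.ndarray  # (n_steps+1, 3) intact/yielded/failed

    def __post_init__(self) -> None:
        if np.any(np.diff(self.displacement_mm) <= 0):
            raise ValueError("displacement must be strictly increasing")
        if self.displacement_mm[0] != 0 or self.force_n[0] != 0:
            raise ValueError("curve must start at (0, 0)")


@dataclass
class FailureLoadResult:
    """Peak force of the compression curve and where it occurred."""

    failure_load_n: float
    displacement_at_peak_mm: float
    curve: ForceDisplacementCurve
    censored: bool
    max_residual: float = 0.0
    mesh_edge_mm: float = 0.0


@dataclass
class ElementStates:
    """Damage state, secant scale and post-yield strain bookkeeping."""

    state: np.ndarray  # (E,) int
    scale: np.ndarray  # (E,) in (0, 1]
    strain_at_yield: np.ndarray  # (E,) signed driving principal strain
    driving_sign: np.ndarray  # (E,) +1 tension, -1 compression, 0 intact

    @classmethod
    def fresh(cls, n: int) -> "ElementStates":
        return cls(
            state=np.zeros(n, dtype=np.int8),
            scale=np.ones(n),
            strain_at_yield=np.zeros(n),
            driving_sign=np.zeros(n, dtype=np.int8),
        )

    def counts(self) -> np.ndarray:
        return np.array(
            [(self.state == s).sum() for s in (INTACT, YIELDED, FAILED)], dtype=np.int64
        )


# ---------------------------------------------------------------------------
# element matrices and assembly
# ---------------------------------------------------------------------------


def _element_b_matrices(mesh: TetMesh) -> np.ndarray:
    """(E, 6, 12) strain-displacement matrices of the constant-strain tets."""
    p = mesh.nodes[mesh.elements]  # (E, 4, 3)
    M = p[:, 1:] - p[:, :1]  # (E, 3, 3) rows are edge vectors
    Minv = np.linalg.inv(M)  # columns give gradients of N1..N3
    grads = np.empty((mesh.n_elements, 4, 3))
    g123 = Minv.transpose(0, 2, 1)  # (E, 3nodes, 3xyz)
    grads[:, 1:] = g123
    grads[:, 0] = -g123.sum(axis=1)
    B = np.zeros((mesh.n_elements, 6, 12))
    for i in range(4):
        bx, by, bz = grads[:, i, 0], grads[:, i, 1], grads[:, i, 2]
        c = 3 * i
        B[:, 0, c] = bx
        B[:, 1, c + 1] = by
        B[:, 2, c + 2] = bz
        B[:, 3, c + 1] = bz
        B[:, 3, c + 2] = by
        B[:, 4, c] = bz
        B[:, 4, c + 2] = bx
        B[:, 5, c] = by
        B[:, 5, c + 1] = bx
    return B


class FeSystem:
    """Cached element matrices for one mesh + material set.

    Reassembling the global stiffness for a new damage-scale vector reuses
    the unscaled element matrices, which keeps the inner damage loop cheap.
    """

    def __init__(self, mesh: TetMesh, material: ElementMaterial):
        self.mesh = mesh
        self.material = material
        self.C = build_elasticity_tensor(material)  # (E, 6, 6)
        self.B = _element_b_matrices(mesh)
        V = mesh.element_volumes[:, None, None]
        self.Ke = V * np.einsum("eba,ebc,ecd->ead", self.B, self.C, self.B)
        conn = mesh.elements
        dof = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
        self.rows = np.repeat(dof, 12, axis=1).ravel()
        self.cols = np.tile(dof, (1, 12)).ravel()
        self.ndof = 3 * mesh.n_nodes

    def assemble(self, scale: np.ndarray | None = None) -> sparse.csr_matrix:
        Ke = self.Ke if scale is None else self.Ke * scale[:, None, None]
        K = sparse.coo_matrix(
            (Ke.ravel(), (self.rows, self.cols)), shape=(self.ndof, self.ndof)
        )
        return K.tocsr()

    def element_strains(self, u: np.ndarray) -> np.ndarray:
        """(E, 6) Voigt strains (engineering shear) from the global DOF vector."""
        ue = u.reshape(-1, 3)[self.mesh.elements].reshape(-1, 12)
        return np.einsum("eij,ej->ei", self.B, ue)


def assemble_stiffness(
    mesh: TetMesh,
    material: ElementMaterial,
    scale: np.ndarray | None = None,
) -> sparse.csr_matrix:
    """Global sparse stiffness K = sum_e s_e V_e B_e^T C_e B_e (symmetric)."""
    if scale is not None and (np.any(scale <= 0) or np.any(scale > 1)):
        raise ValueError("element scales must be in (0, 1]")
    return FeSystem(mesh, material).assemble(scale)


# ---------------------------------------------------------------------------
# linear step
# ---------------------------------------------------------------------------


def _dof_partition(ndof: int, bc: BoundaryConditions, u_value: float):
    """Constrained DOF indices/values for prescribed axial displacement."""
    fixed_dof = (3 * bc.fixed_nodes[:, None] + np.arange(3)[None, :]).ravel()
    driven_dof = 3 * bc.driven_nodes + 2
    cons = np.concatenate([fixed_dof, driven_dof])
    vals = np.concatenate([np.zeros(fixed_dof.size), np.full(driven_dof.size, u_value)])
    free = np.setdiff1d(np.arange(ndof), cons)
    return cons, vals, free, driven_dof, fixed_dof


def solve_displacement_step(
    K: sparse.csr_matrix,
    bc: BoundaryConditions,
    u_step: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Solve K u = 0 with the prescribed displacements; returns (u, r, residual).

    ``r`` is the full reaction vector K u (nonzero only on constrained
    DOF up to the solver residual); ``residual`` is the relative
    equilibrium residual on the free DOF.
    """
    ndof = K.shape[0]
    cons, vals, free, _, _ = _dof_partition(ndof, bc, u_step)
    u = np.zeros(ndof)
    u[cons] = vals
    Kff = K[free][:, free].tocsc()
    rhs = -K[free][:, cons] @ vals
    try:
        u[free] = splu(Kff).solve(rhs)
    except RuntimeError as err:  # pragma: no cover - singular system diagnostic
        raise RuntimeError(
            f"linear solve failed ({err}); check for unconstrained rigid-body modes"
        ) from err
    r = K @ u
    denom = max(float(np.linalg.norm(r[cons])), 1e-30)
    residual = float(np.linalg.norm(r[free])) / denom
    return u, r, residual


# ---------------------------------------------------------------------------
# damage update
# ---------------------------------------------------------------------------


def update_element_states(
    stresses_voigt: np.ndarray,
    strains_voigt: np.ndarray,
    material: ElementMaterial,
    states: ElementStates,
    residual_factor: float = 0.05,
) -> tuple[ElementStates, bool]:
    """One damage-update pass; returns (new states, changed?).

    Stresses are the current (secant-scaled) element stresses.  Yield when
    sigma_1 > sigma_max or sigma_3 < -sigma_min; the secant scale caps the
    driving stress at its limit.  Failure when post-yield driving strain
    exceeds eps_AB; failed elements keep ``residual_factor`` stiffness.
    """
    s = _voigt_to_tensor(stresses_voigt)
    sig_eig = np.linalg.eigvalsh(s)  # ascending
    s3, s1 = sig_eig[:, 0], sig_eig[:, -1]
    e = _voigt_to_tensor(strains_voigt, shear_half=True)
    eps_eig = np.linalg.eigvalsh(e)
    e3, e1 = eps_eig[:, 0], eps_eig[:, -1]

    st = states.state.copy()
    scale = states.scale.copy()
    strain_y = states.strain_at_yield.copy()
    sign = states.driving_sign.copy()

    tension_ratio = s1 / material.sigma_max
    compression_ratio = -s3 / material.sigma_min

    intact = st == INTACT
    newly = intact & ((tension_ratio > 1.0) | (compression_ratio > 1.0))
    comp_driven = compression_ratio >= tension_ratio
    sign[newly] = np.where(comp_driven[newly], -1, 1)
    strain_y[newly] = np.where(comp_driven[newly], e3[newly], e1[newly])
    st[newly] = YIELDED

    yielded = st == YIELDED
    ratio = np.where(sign == -1, compression_ratio, tension_ratio)
    over = yielded & (ratio > 1.0)
    scale[over] = np.maximum(scale[over] / ratio[over], residual_factor)

    drive_strain = np.where(sign == -1, e3, e1)
    post_yield = np.abs(drive_strain - strain_y)
    fails = yielded & (post_yield > material.eps_ab)
    st[fails] = FAILED
    scale[fails] = residual_factor

    new = ElementStates(state=st, scale=scale, strain_at_yield=strain_y, driving_sign=sign)
    changed = bool(
        np.any(new.state != states.state)
        or np.any(np.abs(new.scale - states.scale) > 0)
    )
    return new, changed


def _voigt_to_tensor(v: np.ndarray, shear_half: bool = False) -> np.ndarray:
    """(E, 6) Voigt (xx, yy, zz, yz, xz, xy) -> (E, 3, 3) symmetric tensors."""
    f = 0.5 if shear_half else 1.0
    t = np.zeros((v.shape[0], 3, 3))
    t[:, 0, 0] = v[:, 0]
    t[:, 1, 1] = v[:, 1]
    t[:, 2, 2] = v[:, 2]
    t[:, 1, 2] = t[:, 2, 1] = f * v[:, 3]
    t[:, 0, 2] = t[:, 2, 0] = f * v[:, 4]
    t[:, 0, 1] = t[:, 1, 0] = f * v[:, 5]
    return t


# ---------------------------------------------------------------------------
# nonlinear run
# ---------------------------------------------------------------------------


def run_compression(
    mesh: TetMesh,
    material: ElementMaterial,
    bc: BoundaryConditions | None = None,
    cfg: SolverConfig | None = None,
) -> FailureLoadResult:
    """Incremental compression of the meshed vertebra to its failure load."""
    cfg = cfg if cfg is not None else SolverConfig()
    bc = bc if bc is not None else BoundaryConditions.from_mesh(mesh)
    system = FeSystem(mesh, material)
    u_max = (
        cfg.max_displacement_mm
        if cfg.max_displacement_mm is not None
        else cfg.max_displacement_frac * mesh.height
    )
    du = u_max / cfg.n_steps
    states = ElementStates.fresh(mesh.n_elements)

    us = [0.0]
    fs = [0.0]
    counts = [states.counts()]
    max_residual = 0.0
    driven_dof = 3 * bc.driven_nodes + 2

    # the LU factorization is reused until damage actually changes a scale
    cons, vals0, free, _, _ = _dof_partition(system.ndof, bc, 1.0)
    K = lu = Kfc = None
    scales_dirty = True

    def _solve(u_value: float):
        nonlocal K, lu, Kfc, scales_dirty
        if scales_dirty:
            K = system.assemble(states.scale)
            Kff = K[free][:, free].tocsc()
            Kfc = K[free][:, cons]
            lu = splu(Kff)
            scales_dirty = False
        u = np.zeros(system.ndof)
        u[cons] = vals0 * u_value
        u[free] = lu.solve(-(Kfc @ (vals0 * u_value)))
        r = K @ u
        denom = max(float(np.linalg.norm(r[cons])), 1e-30)
        return u, r, float(np.linalg.norm(r[free])) / denom

    for step in range(1, cfg.n_steps + 1):
        u_presc = -step * du  # compression: superior face moves down
        for _ in range(cfg.max_inner_iterations):
            u, r, residual = _solve(u_presc)
            strains = system.element_strains(u)
            stresses = np.einsum(
                "eij,ej->ei", system.C * states.scale[:, None, None], strains
            )
            states_new, changed = update_element_states(
                stresses, strains, material, states, cfg.damage_residual
            )
            max_scale_change = float(np.max(np.abs(states_new.scale - states.scale)))
            states = states_new
            if changed:
                scales_dirty = True
            if not changed or max_scale_change < cfg.scale_tolerance:
                break
        max_residual = max(max_residual, residual)
        force = -float(r[driven_dof].sum())  # reaction opposing the downward motion
        us.append(step * du)
        fs.append(force)
        counts.append(states.counts())
        if step >= cfg.min_steps_before_stop and force < (1.0 - cfg.early_stop_drop) * max(fs):
            break

    curve = ForceDisplacementCurve(
        displacement_mm=np.asarray(us),
        force_n=np.asarray(fs),
        state_counts=np.asarray(counts),
    )
    peak_idx = int(np.argmax(curve.force_n))
    censored = peak_idx == len(us) - 1
    return FailureLoadResult(
        failure_load_n=float(curve.force_n[peak_idx]),
        displacement_at_peak_mm=float(curve.displacement_mm[peak_idx]),
        curve=curve,
        censored=censored,
        max_residual=max_residual,
        mesh_edge_mm=mesh.target_edge_mm,
    )


def failure_load_from_curve(displacement_mm, force_n) -> tuple[float, float]:
    """Peak force and its displacement from an arbitrary (u, F) curve."""
    f = np.asarray(force_n, dtype=np.float64)
    u = np.asarray(displacement_mm, dtype=np.float64)
    i = int(np.argmax(f))
    return float(f[i]), float(u[i])


def mesh_convergence_study(
    volume,
    mask: np.ndarray,
    edges_mm=None,
    mapping=None,
    cfg: SolverConfig | None = None,
    converge_tol: float = 0.02,
) -> pd.DataFrame:
    """Failure load versus element edge length (default 3.0 down to 1.5 mm).

    Edges are evaluated coarse to fine; a row's ``converged`` flag is set
    when its failure load changed by less than ``converge_tol`` relative
    to the next-coarser edge.  A failing edge yields a NaN row and a
    warning rather than aborting the table.
    """
    import warnings

    from .femodel import element_hu, map_material, mask_to_tet_mesh

    if cfg is None:
        # fine meshes dominate the cost; a lean stepping schedule is enough
        # to locate the force peak for the convergence comparison
        cfg = SolverConfig(n_steps=10, max_inner_iterations=3)
    if edges_mm is None:
        edges_mm = np.arange(3.0, 1.5 - 1e-9, -0.25)
    edges = sorted((float(e) for e in edges_mm), reverse=True)
    rows = []
    prev_fl = None
    for e in edges:
        try:
            mesh = mask_to_tet_mesh(mask, volume.spacing, e)
            mat = map_material(element_hu(mesh, volume), mapping)
            res = run_compression(mesh, mat, cfg=cfg)
            fl = res.failure_load_n
        except Exception as err:  # keep a partial table
            warnings.warn(f"edge {e} mm failed: {err}", stacklevel=2)
            rows.append({"edge_mm": e, "failure_load_n": np.nan, "converged": False})
            continue
        rel = np.nan if prev_fl is None else abs(fl - prev_fl) / abs(prev_fl)
        rows.append(
            {
                "edge_mm": e,
                "failure_load_n": fl,
                "rel_change": rel,
                "converged": bool(rel < converge_tol) if np.isfinite(rel) else False,
            }
        )
        prev_fl = fl
    return pd.DataFrame(rows)
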