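"""Tetrahedral FE model construction and density-modulus material mapping.

A segmented vertebral-body mask is resampled onto cubic cells of the
requested edge length; each occupied cell is split into six tetrahedra
(Kuhn subdivision with a consistent diagonal, so neighboring cells share
conforming faces).  All six tetrahedra of a cell share the cell's mean HU,
matching the voxel support of the data and making the brute-force voxel
average an exact oracle.

Material mapping (per element, transversely isotropic about the axial z
direction; densities from HU, moduli in MPa):

    rho_app = 47 + 1.122 * HU                      [mg/cc]
    rho_ash : as printed, rho_app = 0.6 * rho_ash  -> rho_ash = rho_app / 0.6
              (the conventional direction rho_ash = 0.6 * rho_app is
              selectable; rho_ash is carried in g/cc)
    E_z  = -349 + 5.82 * rho_app     (clamped to a small positive floor)
    E_x  = E_y = 0.333 * E_z
    G_xy = 0.121 * E_z ;  G_xz = G_yz = 0.157 * E_z
    sigma_max = 137 * rho_ash^1.88   (rho_ash < 0.317 g/cc)
              = 114 * rho_ash^1.72   (otherwise)
    sigma_min = 65.1 * rho_ash^1.93
    eps_AB    = -0.00315 + 0.0728 * rho_ash        (clamped >= 1e-4)

Poisson ratios are not part of the mapping; the in-plane ratio
nu_p = 0.376 is chosen so that E_p / (2 (1 + nu_p)) reproduces
G_xy = 0.121 E_z given E_p = 0.333 E_z, and nu_zp = 0.30 is a standard
bone value.  Positive definiteness of every element's 6x6 stiffness is
checked at build time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "TetMesh",
    "ElementMaterial",
    "MaterialMapping",
    "mask_to_tet_mesh",
    "element_hu",
    "map_material",
    "build_elasticity_tensor",
    "write_abaqus_inp",
    "write_vtu",
]

# Kuhn subdivision: six tets per cube, all sharing the 000-111 diagonal.
# Corner offsets indexed (dx, dy, dz).
_KUHN_PATHS = (
    ((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)),
    ((0, 0, 0), (1, 0, 0), (1, 0, 1), (1, 1, 1)),
    ((0, 0, 0), (0, 1, 0), (1, 1, 0), (1, 1, 1)),
    ((0, 0, 0), (0, 1, 0), (0, 1, 1), (1, 1, 1)),
    ((0, 0, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1)),
    ((0, 0, 0), (0, 0, 1), (0, 1, 1), (1, 1, 1)),
)


@dataclass
class TetMesh:
    """Linear tetrahedral mesh with inferior/superior face node sets.

    ``cell_id`` maps each element to its source cubic cell (six elements
    per cell), which is how per-element HU is looked up.
    """

    nodes: np.ndarray  # (N, 3) mm
    elements: np.ndarray  # (E, 4) node indices
    element_volumes: np.ndarray  # (E,) mm^3
    inferior_nodes: np.ndarray  # node indices at global min z
    superior_nodes: np.ndarray  # node indices at global max z
    cell_id: np.ndarray  # (E,) flat index of the source cell
    cell_grid_shape: tuple[int, int, int]
    cell_origin: tuple[float, float, float]  # mm, lower corner of cell grid
    cell_size_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    target_edge_mm: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.element_volumes <= 0):
            raise ValueError("all element volumes must be positive (orientation)")
        if self.inferior_nodes.size == 0 or self.superior_nodes.size == 0:
            raise ValueError("inferior/superior face sets must be nonempty")
        if np.intersect1d(self.inferior_nodes, self.superior_nodes).size:
            raise ValueError("inferior and superior face sets must be disjoint")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def height(self) -> float:
        return float(self.nodes[:, 2].max() - self.nodes[:, 2].min())

    @property
    def total_volume(self) -> float:
        return float(self.element_volumes.sum())


def mask_to_tet_mesh(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    target_edge_mm: float,
) -> TetMesh:
    """Resample a voxel mask to cubic cells and split each into 6 tets.

    A cell is occupied when at least half of the voxel centers falling in
    it are inside the mask.  A disconnected cell set triggers a warning and
    only the largest connected component is kept.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if target_edge_mm < max(spacing):
        raise ValueError("target_edge_mm must be >= the largest voxel spacing")

    idx = np.argwhere(mask)
    lo_vox = idx.min(axis=0)
    hi_vox = idx.max(axis=0)
    e = float(target_edge_mm)
    origin = tuple(float(lo_vox[a] * spacing[a]) for a in range(3))
    extent = [(hi_vox[a] - lo_vox[a] + 1) * spacing[a] for a in range(3)]
    # fit the grid exactly to the mask bounding box with ~edge-length cells:
    # avoids thin partial end layers whose presence would flip with edge phase
    ncell = tuple(max(1, int(round(ext / e))) for ext in extent)
    cell_size = tuple(ext / n for ext, n in zip(extent, ncell))

    # voxel centers inside the cell bounding box -> cell indices
    occ_num = np.zeros(ncell)
    occ_den = np.zeros(ncell)
    coords = [
        ((np.arange(lo_vox[a], hi_vox[a] + 1) + 0.5) * spacing[a] - origin[a]) / cell_size[a]
        for a in range(3)
    ]
    ci = [np.clip(np.floor(c).astype(int), 0, n - 1) for c, n in zip(coords, ncell)]
    sub = mask[
        lo_vox[0] : hi_vox[0] + 1, lo_vox[1] : hi_vox[1] + 1, lo_vox[2] : hi_vox[2] + 1
    ]
    cell_of_voxel = (
        ci[0][:, None, None] * (ncell[1] * ncell[2])
        + ci[1][None, :, None] * ncell[2]
        + ci[2][None, None, :]
    )
    np.add.at(occ_den.reshape(-1), cell_of_voxel.ravel(), 1.0)
    np.add.at(occ_num.reshape(-1), cell_of_voxel.ravel(), sub.ravel().astype(float))
    with np.errstate(invalid="ignore"):
        occupied = (occ_num / np.maximum(occ_den, 1)) >= 0.5
    if not occupied.any():
        raise ValueError("no occupied cells at this edge length")

    labels, n_comp = ndimage.label(occupied)
    if n_comp > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n_comp + 1))
        keep = 1 + int(np.argmax(sizes))
        warnings.warn(
            f"mesh has {n_comp} disconnected components; keeping the largest", stacklevel=2
        )
        occupied = labels == keep

    cells = np.argwhere(occupied)  # (C, 3)
    # corner grid node ids
    corner_shape = tuple(n + 1 for n in ncell)

    def corner_flat(cxyz):  # (M, 3) -> flat corner ids
        return (
            cxyz[:, 0] * (corner_shape[1] * corner_shape[2])
            + cxyz[:, 1] * corner_shape[2]
            + cxyz[:, 2]
        )

    elem_corner_ids = []
    for path in _KUHN_PATHS:
        for off in path:
            elem_corner_ids.append(corner_flat(cells + np.array(off)))
    # shape (C, 6, 4) after regrouping
    ecs = np.stack(elem_corner_ids, axis=1).reshape(-1, 6, 4)
    conn_flat = ecs.reshape(-1, 4)

    used, inverse = np.unique(conn_flat, return_inverse=True)
    conn = inverse.reshape(-1, 4)
    ux = used // (corner_shape[1] * corner_shape[2])
    uy = (used // corner_shape[2]) % corner_shape[1]
    uz = used % corner_shape[2]
    nodes = np.stack(
        [
            origin[0] + ux * cell_size[0],
            origin[1] + uy * cell_size[1],
            origin[2] + uz * cell_size[2],
        ],
        axis=1,
    ).astype(np.float64)

    # consistent positive orientation
    p = nodes[conn]
    vol6 = np.einsum(
        "ei,ei->e",
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
        p[:, 3] - p[:, 0],
    )
    flip = vol6 < 0
    conn[flip, 2], conn[flip, 3] = conn[flip, 3].copy(), conn[flip, 2].copy()
    volumes = np.abs(vol6) / 6.0

    zmin, zmax = nodes[:, 2].min(), nodes[:, 2].max()
    tol = cell_size[2] / 4.0
    inferior = np.where(nodes[:, 2] <= zmin + tol)[0]
    superior = np.where(nodes[:, 2] >= zmax - tol)[0]

    cell_flat = cells[:, 0] * (ncell[1] * ncell[2]) + cells[:, 1] * ncell[2] + cells[:, 2]
    cell_id = np.repeat(cell_flat, 6)

    return TetMesh(
        nodes=nodes,
        elements=conn.astype(np.int64),
        element_volumes=volumes,
        inferior_nodes=inferior,
        superior_nodes=superior,
        cell_id=cell_id,
        cell_grid_shape=ncell,
        cell_origin=origin,
        cell_size_mm=cell_size,
        target_edge_mm=e,
    )


def element_hu(mesh: TetMesh, volume) -> np.ndarray:
    """Per-element HU: mean over voxels whose centers fall in the source cell.

    ``volume`` is a :class:`~qctfe.phantom.VoxelVolume` covering the mesh;
    all six tetrahedra of a cell share its value.
    """
    vals = volume.values
    ncell = mesh.cell_grid_shape
    centers = volume.voxel_centers()
    ci = []
    inside = []
    for a in range(3):
        c = (centers[a] - mesh.cell_origin[a]) / mesh.cell_size_mm[a]
        idx = np.floor(c).astype(int)
        inside.append((idx >= 0) & (idx < ncell[a]))
        ci.append(np.clip(idx, 0, ncell[a] - 1))
    in_box = inside[0][:, None, None] & inside[1][None, :, None] & inside[2][None, None, :]
    if not in_box.any():
        raise ValueError("mesh cell grid lies outside the volume")
    flat_cell = (
        ci[0][:, None, None] * (ncell[1] * ncell[2])
        + ci[1][None, :, None] * ncell[2]
        + ci[2][None, None, :]
    )
    ncells_total = int(np.prod(ncell))
    acc = np.zeros(ncells_total)
    cnt = np.zeros(ncells_total)
    sel = in_box.ravel()
    np.add.at(acc, flat_cell.ravel()[sel], vals.ravel()[sel])
    np.add.at(cnt, flat_cell.ravel()[sel], 1.0)
    used = np.unique(mesh.cell_id)
    if np.any(cnt[used] == 0):
        raise ValueError("some mesh cells contain no voxel centers (element outside volume?)")
    cell_mean = np.zeros(ncells_total)
    nz = cnt > 0
    cell_mean[nz] = acc[nz] / cnt[nz]
    return cell_mean[mesh.cell_id]


# ---------------------------------------------------------------------------
# material mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaterialMapping:
    """Configuration of the HU -> density -> mechanics mapping."""

    ash_direction: str = "as_printed"  # or "conventional"
    e_min_mpa: float = 0.01
    eps_ab_min: float = 1.0e-4
    rho_ash_floor_gcc: float = 1.0e-6
    sigma_branch_gcc: float = 0.317
    nu_p: float = 0.376
    nu_zp: float = 0.30

    def __post_init__(self) -> None:
        if self.ash_direction not in ("as_printed", "conventional"):
            raise ValueError("ash_direction must be 'as_printed' or 'conventional'")


@dataclass
class ElementMaterial:
    """Per-element material constants (struct of arrays; all arrays (E,))."""

    hu: np.ndarray
    rho_app: np.ndarray  # mg/cc
    rho_ash: np.ndarray  # g/cc
    E_z: np.ndarray  # MPa
    E_x: np.ndarray
    E_y: np.ndarray
    G_xy: np.ndarray
    G_xz: np.ndarray
    G_yz: np.ndarray
    sigma_max: np.ndarray  # MPa, maximum-principal-stress limit
    sigma_min: np.ndarray  # MPa, minimum-principal-stress limit (magnitude)
    eps_ab: np.ndarray  # plastic strain to failure
    nu_p: float
    nu_zp: float

    @property
    def n(self) -> int:
        return self.hu.size


def map_material(hu: np.ndarray | float, mapping: MaterialMapping | None = None) -> ElementMaterial:
    """Apply the density-modulus-strength mapping to HU values (vectorized)."""
    m = mapping if mapping is not None else MaterialMapping()
    hu = np.atleast_1d(np.asarray(hu, dtype=np.float64))
    rho_app = 47.0 + 1.122 * hu  # mg/cc
    if m.ash_direction == "as_printed":
        rho_ash = rho_app / 0.6 / 1000.0  # g/cc
    else:
        rho_ash = 0.6 * rho_app / 1000.0
    rho_ash = np.maximum(rho_ash, m.rho_ash_floor_gcc)

    E_z = np.maximum(-349.0 + 5.82 * rho_app, m.e_min_mpa)
    E_x = 0.333 * E_z
    G_xy = 0.121 * E_z
    G_xz = 0.157 * E_z

    low = rho_ash < m.sigma_branch_gcc
    sigma_max = np.where(low, 137.0 * rho_ash**1.88, 114.0 * rho_ash**1.72)
    sigma_min = 65.1 * rho_ash**1.93
    eps_ab = np.maximum(-0.00315 + 0.0728 * rho_ash, m.eps_ab_min)

    return ElementMaterial(
        hu=hu,
        rho_app=rho_app,
        rho_ash=rho_ash,
        E_z=E_z,
        E_x=E_x,
        E_y=E_x.copy(),
        G_xy=G_xy,
        G_xz=G_xz,
        G_yz=G_xz.copy(),
        sigma_max=sigma_max,
        sigma_min=sigma_min,
        eps_ab=eps_ab,
        nu_p=m.nu_p,
        nu_zp=m.nu_zp,
    )


def build_elasticity_tensor(material: ElementMaterial, check: bool = True) -> np.ndarray:
    """(E, 6, 6) stiffness matrices in Voigt order (xx, yy, zz, yz, xz, xy).

    Built by inverting the transversely isotropic compliance assembled from
    the engineering constants (z = axis of symmetry).  Raises if any
    element's stiffness is not positive definite.
    """
    n = material.n
    S = np.zeros((n, 6, 6))
    Ep = material.E_x
    Ez = material.E_z
    nu_p, nu_zp = material.nu_p, material.nu_zp
    S[:, 0, 0] = S[:, 1, 1] = 1.0 / Ep
    S[:, 2, 2] = 1.0 / Ez
    S[:, 0, 1] = S[:, 1, 0] = -nu_p / Ep
    S[:, 0, 2] = S[:, 2, 0] = -nu_zp / Ez
    S[:, 1, 2] = S[:, 2, 1] = -nu_zp / Ez
    S[:, 3, 3] = 1.0 / material.G_yz
    S[:, 4, 4] = 1.0 / material.G_xz
    S[:, 5, 5] = 1.0 / material.G_xy
    C = np.linalg.inv(S)
    C = 0.5 * (C + C.transpose(0, 2, 1))
    if check:
        eig = np.linalg.eigvalsh(C)
        bad = np.where(eig[:, 0] <= 0)[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                "non-positive-definite stiffness for element "
                f"{i}: E_z={Ez[i]:.4g} MPa, E_p={Ep[i]:.4g} MPa, "
                f"nu_p={nu_p}, nu_zp={nu_zp}"
            )
    return C


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_abaqus_inp(mesh: TetMesh, material: ElementMaterial, path) -> None:
    """Abaqus-style .inp export: nodes, C3D4 elements, per-element materials."""
    with open(path, "w") as f:
        f.write("*HEADING\nqctfe vertebral body export\n*NODE\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            f.write(f"{i}, {x:.6f}, {y:.6f}, {z:.6f}\n")
        f.write("*ELEMENT, TYPE=C3D4\n")
        for i, el in enumerate(mesh.elements, start=1):
            f.write(f"{i}, {el[0] + 1}, {el[1] + 1}, {el[2] + 1}, {el[3] + 1}\n")
        for i in range(mesh.n_elements):
            f.write(f"*ELSET, ELSET=EL{i + 1}\n{i + 1},\n")
            f.write(f"*SOLID SECTION, ELSET=EL{i + 1}, MATERIAL=MAT{i + 1}\n")
            f.write(f"*MATERIAL, NAME=MAT{i + 1}\n*ELASTIC, TYPE=ENGINEERING CONSTANTS\n")
            f.write(
                f"{material.E_x[i]:.4f}, {material.E_y[i]:.4f}, {material.E_z[i]:.4f}, "
                f"{material.nu_p:.4f}, {material.nu_zp:.4f}, {material.nu_zp:.4f}, "
                f"{material.G_xy[i]:.4f}, {material.G_xz[i]:.4f}\n{material.G_yz[i]:.4f},\n"
            )
        f.write("*NSET, NSET=INFERIOR\n")
        f.write(", ".join(str(i + 1) for i in mesh.inferior_nodes) + "\n")
        f.write("*NSET, NSET=SUPERIOR\n")
        f.write(", ".join(str(i + 1) for i in mesh.superior_nodes) + "\n")


def write_vtu(mesh: TetMesh, path, cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Minimal ASCII VTK unstructured-grid (.vtu) export with cell fields."""
    E = mesh.n_elements
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{E}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
    ]
    lines += [" ".join(f"{v:.6f}" for v in row) for row in mesh.nodes]
    lines += [
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        " ".join(" ".join(map(str, el)) for el in mesh.elements),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str(4 * (i + 1)) for i in range(E)),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join("10" for _ in range(E)),
        "</DataArray>",
        "</Cells>",
    ]
    if cell_data:
        lines.append("<CellData>")
        for name, arr in cell_data.items():
            lines.append(f'<DataArray type="Float64" Name="{name}" format="ascii">')
            lines.append(" ".join(f"{float(v):.6g}" for v in arr))
            lines.append("</DataArray>")
        lines.append("</CellData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    with open(path, "w") as f:
        f.write("\n".join(lines))
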