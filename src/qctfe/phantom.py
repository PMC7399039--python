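"""Synthetic vertebra phantoms with a QCT calibration insert.

The generator stands in for patient MDCT scans: an elliptical-cylinder
vertebral body (dense cortical shell, heterogeneous trabecular interior
modelled as a correlated Gaussian random field) embedded in soft tissue,
with calibration rods of known equivalent density placed beneath the body
the way a QCT reference phantom sits under the scanner mat.

Cohorts emulate a ~12-subject study population whose trabecular QCT BMD is
normally distributed (default 89.3 +/- 14.55 mg/cc).  Rod HU values equal
their equivalent densities by construction, so the ground-truth calibration
line is the identity and a subject's target BMD maps directly onto the mean
trabecular HU of its phantom.

Axis convention: volumes are indexed ``[x, y, z]`` with z the axial
(superior-inferior) direction, which is also the FE load axis.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "HU_RANGE",
    "PhantomSpec",
    "VoxelVolume",
    "CalibrationInsertSet",
    "CohortSpec",
    "make_vertebra_phantom",
    "default_insert_set",
    "add_calibration_inserts",
    "make_cohort",
    "save_volume",
    "load_volume",
]

#: Physical HU range phantoms are clipped to.
HU_RANGE = (-200.0, 2000.0)


class DimensionError(ValueError):
    """Raised when a phantom component does not fit inside the voxel grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry + tissue parameters of one synthetic vertebra volume.

    Lengths in mm, intensities in HU.  ``grid_shape`` is (nx, ny, nz) and
    ``voxel_spacing`` is (dx, dy, dz); identical spec + seed gives a
    bit-identical volume.
    """

    body_half_axes: tuple[float, float] = (18.0, 13.0)  # (a, b) in-plane, mm
    body_height: float = 32.0
    cortical_thickness: float = 2.0
    trabecular_mean_hu: float = 89.3
    trabecular_sd_hu: float = 30.0
    correlation_length: float = 3.0
    soft_tissue_hu: float = 40.0
    cortical_hu: float = 300.0
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    grid_shape: tuple[int, int, int] = (96, 96, 48)
    body_center_frac: tuple[float, float] = (0.5, 0.40)  # (x, y) as grid fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cortical_thickness < 0:
            raise ValueError("cortical_thickness must be >= 0")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacings must be > 0")
        if any(n < 4 for n in self.grid_shape):
            raise ValueError("grid_shape too small")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.grid_shape, self.voxel_spacing))

    @property
    def body_center_mm(self) -> tuple[float, float, float]:
        ex, ey, ez = self.extent_mm
        return (self.body_center_frac[0] * ex, self.body_center_frac[1] * ey, 0.5 * ez)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        for k in ("body_half_axes", "voxel_spacing", "grid_shape", "body_center_frac"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class VoxelVolume:
    """A 3-D HU grid with physical spacing.

    ``values`` has axes (x, y, z); z is the axial/load direction.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("VoxelVolume expects a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HU values must be finite")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-D physical coordinates of voxel centers along each axis (mm)."""
        return tuple(
            o + (np.arange(n) + 0.5) * s
            for n, s, o in zip(self.values.shape, self.spacing, self.origin)
        )

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.values.copy(), tuple(self.spacing), tuple(self.origin))


@dataclass(frozen=True)
class CalibrationInsertSet:
    """Cylindrical calibration rods (axis along z, spanning the grid).

    ``centers_mm`` are in-plane (x, y) rod centers; ``densities_mgcc`` the
    equivalent densities and ``hu_values`` the HU each rod is set to.  At
    least two rods with distinct densities are required so a linear
    calibration fit has rank 2.
    """

    centers_mm: tuple[tuple[float, float], ...]
    radius_mm: float
    densities_mgcc: tuple[float, ...]
    hu_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.centers_mm) != len(self.densities_mgcc) or len(self.centers_mm) != len(
            self.hu_values
        ):
            raise ValueError("centers, densities and HU lists must have equal length")
        if len(set(self.densities_mgcc)) < 2:
            raise ValueError("need >= 2 rods with distinct densities")
        if self.radius_mm <= 0:
            raise ValueError("rod radius must be positive")

    def rod_masks(self, volume: VoxelVolume) -> list[np.ndarray]:
        """Boolean mask per rod on the volume's grid."""
        xs, ys, _ = volume.voxel_centers()
        masks = []
        for cx, cy in self.centers_mm:
            in_plane = (xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2 <= self.radius_mm**2
            masks.append(np.broadcast_to(in_plane[:, :, None], volume.shape).copy())
        return masks


@dataclass(frozen=True)
class CohortSpec:
    """A study population: subject count and target trabecular BMD distribution."""

    n_subjects: int = 12
    bmd_mean: float = 89.3
    bmd_sd: float = 14.55
    vertebrae_per_subject: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.bmd_sd < 0:
            raise ValueError("bmd_sd must be >= 0")
        if self.vertebrae_per_subject < 1:
            raise ValueError("vertebrae_per_subject must be >= 1")


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------


def _ellipse_mask(xs, ys, cx, cy, a, b):
    return ((xs[:, None] - cx) / a) ** 2 + ((ys[None, :] - cy) / b) ** 2 <= 1.0


def _correlated_field(shape, spacing, correlation_length, rng):
    """Unit-variance Gaussian random field with ~Gaussian correlation kernel."""
    noise = rng.standard_normal(shape)
    if correlation_length <= 0:
        return noise
    sigma_vox = [correlation_length / s for s in spacing]
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="reflect")
    sd = smooth.std()
    if sd == 0:  # degenerate tiny grid
        return np.zeros(shape)
    return smooth / sd


def make_vertebra_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, np.ndarray]:
    """Build the HU volume and its ground-truth vertebral-body mask.

    The body is an elliptical cylinder: a cortical shell of
    ``cortical_thickness`` at ``cortical_hu`` surrounds a trabecular
    interior drawn from a correlated Gaussian random field with the spec's
    mean/sd, all embedded in uniform soft tissue.  Raises
    :class:`DimensionError` if the body does not fit inside the grid.
    """
    a, b = spec.body_half_axes
    h = spec.body_height
    ex, ey, ez = spec.extent_mm
    cx, cy, cz = spec.body_center_mm
    if cx - a < 0 or cx + a > ex or cy - b < 0 or cy + b > ey or h > ez:
        raise DimensionError(
            f"vertebral body (a={a}, b={b}, h={h} mm) exceeds grid extent {spec.extent_mm}"
        )
    if spec.cortical_thickness >= min(a, b, h / 2) and spec.cortical_thickness > 0:
        raise DimensionError("cortical_thickness leaves no trabecular interior")

    vol = VoxelVolume(
        np.full(spec.grid_shape, spec.soft_tissue_hu, dtype=np.float64),
        spec.voxel_spacing,
    )
    xs, ys, zs = vol.voxel_centers()
    in_z = np.abs(zs - cz) <= h / 2
    body2d = _ellipse_mask(xs, ys, cx, cy, a, b)
    body = body2d[:, :, None] & in_z[None, None, :]

    t = spec.cortical_thickness
    if t > 0:
        inner2d = _ellipse_mask(xs, ys, cx, cy, a - t, b - t)
        in_z_inner = np.abs(zs - cz) <= h / 2 - t
        interior = inner2d[:, :, None] & in_z_inner[None, None, :]
    else:
        interior = body

    rng = np.random.default_rng(spec.seed)
    if spec.trabecular_sd_hu > 0:
        fld = _correlated_field(spec.grid_shape, spec.voxel_spacing, spec.correlation_length, rng)
        trab = spec.trabecular_mean_hu + spec.trabecular_sd_hu * fld
    else:
        trab = np.full(spec.grid_shape, spec.trabecular_mean_hu)

    values = vol.values
    values[body] = spec.cortical_hu
    values[interior] = trab[interior]
    np.clip(values, HU_RANGE[0], HU_RANGE[1], out=values)
    return vol, body


def default_insert_set(
    spec: PhantomSpec,
    densities_mgcc: tuple[float, ...] = (0.0, 200.0),
    radius_mm: float = 5.0,
) -> CalibrationInsertSet:
    """Two-rod calibration insert placed beneath the body (larger y).

    Rod HU is set equal to its equivalent density, making the ground-truth
    calibration the identity line (slope 1 (mg/cc)/HU, intercept 0).
    """
    ex, ey, _ = spec.extent_mm
    n = len(densities_mgcc)
    xs = tuple(ex * (i + 1) / (n + 1) for i in range(n))
    y = 0.85 * ey
    centers = tuple((x, y) for x in xs)
    return CalibrationInsertSet(
        centers_mm=centers,
        radius_mm=radius_mm,
        densities_mgcc=tuple(densities_mgcc),
        hu_values=tuple(densities_mgcc),
    )


def add_calibration_inserts(
    volume: VoxelVolume,
    inserts: CalibrationInsertSet,
    body_mask: np.ndarray | None = None,
) -> VoxelVolume:
    """Return a copy of ``volume`` with rod voxels set to their HU values.

    Raises if a rod extends outside the grid or overlaps the body mask.
    """
    ex = volume.shape[0] * volume.spacing[0]
    ey = volume.shape[1] * volume.spacing[1]
    for cx, cy in inserts.centers_mm:
        if (
            cx - inserts.radius_mm < 0
            or cx + inserts.radius_mm > ex
            or cy - inserts.radius_mm < 0
            or cy + inserts.radius_mm > ey
        ):
            raise DimensionError(f"calibration rod at ({cx:.1f}, {cy:.1f}) mm lies outside the grid")
    out = volume.copy()
    for mask, hu in zip(inserts.rod_masks(volume), inserts.hu_values):
        if body_mask is not None and np.any(mask & body_mask):
            raise ValueError("calibration rod overlaps the vertebral body")
        out.values[mask] = hu
    return out


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def make_cohort(cohort: CohortSpec, base_spec: PhantomSpec | None = None) -> list[PhantomSpec]:
    """Draw per-subject phantom specs for a study population.

    Each subject's target trabecular BMD is drawn from
    Normal(bmd_mean, bmd_sd); because the default calibration rods put HU
    equal to equivalent density, the target BMD is used directly as the
    subject's ``trabecular_mean_hu``.  Body size and shell thickness get
    mild multiplicative jitter around ``base_spec`` so failure loads vary
    through geometry as well as density.  Deterministic under ``seed``.
    """
    base = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(cohort.seed)
    specs: list[PhantomSpec] = []
    for _ in range(cohort.n_subjects):
        target_bmd = float(rng.normal(cohort.bmd_mean, cohort.bmd_sd))
        ga = float(np.clip(rng.normal(1.0, 0.06), 0.85, 1.12))
        gb = float(np.clip(rng.normal(1.0, 0.06), 0.85, 1.12))
        gh = float(np.clip(rng.normal(1.0, 0.05), 0.85, 1.10))
        gt = float(np.clip(rng.normal(1.0, 0.10), 0.75, 1.25))
        shell_ratio = float(np.clip(target_bmd / max(cohort.bmd_mean, 1e-9), 0.7, 1.3))
        subj_seed = int(rng.integers(0, 2**31 - 1))
        for v in range(cohort.vertebrae_per_subject):
            vert_bmd = target_bmd if cohort.vertebrae_per_subject == 1 else float(
                target_bmd + rng.normal(0.0, 3.0)
            )
            specs.append(
                dataclasses.replace(
                    base,
                    body_half_axes=(base.body_half_axes[0] * ga, base.body_half_axes[1] * gb),
                    body_height=base.body_height * gh,
                    cortical_thickness=base.cortical_thickness * gt,
                    cortical_hu=base.cortical_hu * shell_ratio,
                    trabecular_mean_hu=vert_bmd,
                    seed=(subj_seed + v) % (2**31 - 1),
                )
            )
    return specs


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def save_volume(volume: VoxelVolume, path: str | Path, spec: PhantomSpec | None = None) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or MetaImage (.mha).

    A JSON sidecar with the generating :class:`PhantomSpec` is written next
    to the image when ``spec`` is given.
    """
    path = Path(path)
    if path.suffix == ".mha":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.T))  # -> (z, y, x)
        img.SetSpacing(tuple(float(s) for s in volume.spacing))
        img.SetOrigin(tuple(float(o) for o in volume.origin))
        sitk.WriteImage(img, str(path))
    else:
        import nibabel as nib

        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(volume.values, affine), str(path))
    if spec is not None:
        sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .mha
        Path(str(sidecar) + ".spec.json").write_text(spec.to_json())


def load_volume(path: str | Path) -> VoxelVolume:
    """Read a NIfTI or MetaImage volume back into a :class:`VoxelVolume`."""
    path = Path(path)
    if path.suffix == ".mha":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        values = sitk.GetArrayFromImage(img).T  # (z, y, x) -> (x, y, z)
        return VoxelVolume(values, tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    import nibabel as nib

    img = nib.load(str(path))
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VoxelVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)
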