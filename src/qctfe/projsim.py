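"""CT acquisition simulation and the two dose-reduction strategies.

A 2-D parallel-beam, slice-wise geometry stands in for the clinical helical
cone-beam scanner: the study's question concerns dose-versus-strength
fidelity, not scanner geometry, and a small invertible operator is what
makes every downstream stage testable.

The projector is an explicit sparse matrix (pixel-driven with linear
splatting onto detector bins), so forward projection and backprojection are
exact matrix transposes — the property the separable-surrogate
reconstruction in :mod:`qctfe.sir_recon` relies on.

Dose reduction:

* tube-current reduction — photon counts per ray are drawn as
  ``Poisson(d * I0 * exp(-p)) * gain + Normal(0, sigma_e)``, i.e. quantum
  noise scaled by the dose fraction ``d`` plus detector-gain-aware
  electronic noise;
* sparse sampling — only every k-th projection angle of the full-current
  data is kept, the rest are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

from .phantom import VoxelVolume

__all__ = [
    "Geometry",
    "DoseProtocol",
    "Sinogram",
    "Projector",
    "hu_to_mu",
    "mu_to_hu",
    "forward_project",
    "simulate_counts",
    "counts_to_sinogram",
    "sparse_sample",
    "simulate_dose",
]

#: Linear attenuation of water at ~120 kVp, 1/mm.
MU_WATER = 0.019


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam acquisition geometry for one axial slice.

    ``n_angles`` views are spread uniformly over [0, pi); the detector has
    ``n_bins`` bins of ``bin_width`` mm centred on the rotation axis.
    """

    n_angles: int = 360
    n_bins: int = 0  # 0 -> sized to cover the image diagonal at build time
    bin_width: float = 1.0

    def __post_init__(self) -> None:
        if self.n_angles < 2:
            raise ValueError("need at least 2 projection angles")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles


@dataclass(frozen=True)
class DoseProtocol:
    """One acquisition condition of the factorial dose experiment.

    ``dose_fraction`` scales tube current (quantum flux); ``sparse_every``
    keeps every k-th view of full-current data.  The reference condition is
    ``dose_fraction=1, sparse_every=1``; the study varies exactly one of
    the two away from 1 at a time.
    """

    dose_fraction: float = 1.0
    incident_photons: float = 1.0e5
    electronic_noise_sd: float = 10.0
    detector_gain: float = 1.0
    sparse_every: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.dose_fraction <= 1:
            raise ValueError("dose_fraction must be in (0, 1]")
        if self.dose_fraction < 1 and self.sparse_every > 1:
            raise ValueError("apply either tube-current reduction or sparse sampling, not both")
        if self.incident_photons * self.dose_fraction < 1:
            raise ValueError("dose_fraction * incident_photons must be >= 1")
        if self.sparse_every < 1:
            raise ValueError("sparse_every must be >= 1")

    @property
    def label(self) -> str:
        d = int(round(100 * self.dose_fraction))
        p = 100 if self.sparse_every == 1 else int(round(100 / self.sparse_every))
        return f"D{d}P{p}"


@dataclass
class Sinogram:
    """Line integrals p (mu * mm) on an (angle, bin) grid plus ray weights.

    ``weights`` are the variance-inverse statistical weights used by the
    penalized weighted-least-squares reconstruction; ``None`` for
    noiseless data (interpreted as uniform).
    """

    p: np.ndarray  # (n_angles, n_bins)
    angles: np.ndarray  # radians, strictly increasing
    bin_width: float
    weights: np.ndarray | None = None
    protocol: DoseProtocol | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.p.ndim not in (2, 3) or self.p.shape[0] != self.angles.size:
            raise ValueError("p must be (n_angles, n_bins[, n_slices]) matching the angle list")
        if not np.all(np.isfinite(self.p)):
            raise ValueError("sinogram values must be finite")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.weights is not None and np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def n_angles(self) -> int:
        return self.angles.size

    @property
    def n_bins(self) -> int:
        return self.p.shape[1]


# ---------------------------------------------------------------------------
# HU <-> attenuation
# ---------------------------------------------------------------------------


def hu_to_mu(values: np.ndarray | VoxelVolume, mu_water: float = MU_WATER) -> np.ndarray:
    """Standard HU definition: mu = mu_water * (1 + HU/1000), clamped at >= 0."""
    if mu_water <= 0:
        raise ValueError("mu_water must be positive")
    hu = values.values if isinstance(values, VoxelVolume) else np.asarray(values, dtype=np.float64)
    return np.maximum(mu_water * (1.0 + hu / 1000.0), 0.0)


def mu_to_hu(mu: np.ndarray, mu_water: float = MU_WATER) -> np.ndarray:
    """Inverse of :func:`hu_to_mu` (without the clamp)."""
    return 1000.0 * (np.asarray(mu) / mu_water - 1.0)


# ---------------------------------------------------------------------------
# projector
# ---------------------------------------------------------------------------


class Projector:
    """Sparse-matrix parallel-beam projector for square pixel grids.

    Pixel-driven construction: each pixel center projects to detector
    coordinate ``s = x cos(theta) + y sin(theta)`` and deposits its
    intersection measure ``dx*dy/bin_width`` onto the two adjacent bins
    with linear weights.  ``forward``/``back`` apply A and A^T; they accept
    a single slice (flattened or 2-D) or a stack of slices as columns.
    """

    def __init__(
        self,
        image_shape: tuple[int, int],
        pixel_size: float | tuple[float, float],
        geometry: Geometry,
        angles: np.ndarray | None = None,
        dtype=np.float64,
    ):
        nx, ny = image_shape
        dx, dy = (pixel_size, pixel_size) if np.isscalar(pixel_size) else pixel_size
        self.image_shape = (nx, ny)
        self.pixel_size = (float(dx), float(dy))
        half_diag = 0.5 * np.hypot(nx * dx, ny * dy)
        n_bins = geometry.n_bins
        if n_bins == 0:
            n_bins = 2 * int(np.ceil(half_diag / geometry.bin_width)) + 3
            geometry = replace(geometry, n_bins=n_bins)
        self.geometry = geometry
        self.angles = geometry.angles if angles is None else np.asarray(angles, dtype=np.float64)
        self.n_angles = self.angles.size
        self.n_rays = self.n_angles * geometry.n_bins

        # pixel center coordinates relative to the grid center
        xs = (np.arange(nx) + 0.5) * dx - nx * dx / 2.0
        ys = (np.arange(ny) + 0.5) * dy - ny * dy / 2.0
        X = np.repeat(xs, ny)
        Y = np.tile(ys, nx)
        npix = nx * ny
        b = geometry.bin_width
        s_max_px = float(np.max(np.hypot(X, Y)))
        if s_max_px > (geometry.n_bins / 2.0) * b:
            raise ValueError("detector does not cover the image support")

        area = dx * dy / b
        rows = np.empty(2 * npix * self.n_angles, dtype=np.int64)
        cols = np.empty_like(rows)
        vals = np.empty(rows.shape, dtype=dtype)
        center = (geometry.n_bins - 1) / 2.0
        pix_idx = np.arange(npix, dtype=np.int64)
        for ia, th in enumerate(self.angles):
            s = X * np.cos(th) + Y * np.sin(th)
            t = s / b + center
            i0 = np.floor(t).astype(np.int64)
            frac = t - i0
            i0 = np.clip(i0, 0, geometry.n_bins - 2)
            base = ia * geometry.n_bins
            sl = slice(2 * ia * npix, 2 * (ia + 1) * npix)
            rows[sl] = np.concatenate([base + i0, base + i0 + 1])
            cols[sl] = np.concatenate([pix_idx, pix_idx])
            vals[sl] = np.concatenate([(1.0 - frac) * area, frac * area]).astype(dtype)
        A = sparse.coo_matrix((vals, (rows, cols)), shape=(self.n_rays, npix))
        self.A = A.tocsr()
        self.AT = self.A.T.tocsr()

    def forward(self, x: np.ndarray) -> np.ndarray:
        """A @ x; x is (nx, ny), (npix,) or (npix, n_slices)."""
        flat = x.reshape(-1, *x.shape[2:]) if x.ndim >= 2 and x.shape[:2] == self.image_shape else x
        return self.A @ flat

    def back(self, q: np.ndarray) -> np.ndarray:
        """A.T @ q; q is (n_rays,) or (n_rays, n_slices)."""
        return self.AT @ q

    def rays_for_angles(self, angle_idx: np.ndarray) -> np.ndarray:
        """Row indices of all rays belonging to the given angle indices."""
        nb = self.geometry.n_bins
        return (np.asarray(angle_idx)[:, None] * nb + np.arange(nb)[None, :]).ravel()


def forward_project(mu_slice: np.ndarray, projector: Projector) -> Sinogram:
    """Noiseless full-view sinogram of one attenuation slice (1/mm)."""
    mu_slice = np.asarray(mu_slice, dtype=np.float64)
    if mu_slice.shape != projector.image_shape:
        raise ValueError("slice shape does not match projector")
    # support check: attenuating pixels must project inside the detector
    g = projector.geometry
    p = projector.forward(mu_slice).reshape(projector.n_angles, g.n_bins)
    return Sinogram(p=p, angles=projector.angles.copy(), bin_width=g.bin_width)


# ---------------------------------------------------------------------------
# dose insertion
# ---------------------------------------------------------------------------


def simulate_counts(
    sinogram: Sinogram,
    protocol: DoseProtocol,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Noisy detector counts per ray for a tube-current dose fraction.

    ``N = Poisson(d * I0 * exp(-p)) * gain + Normal(0, sigma_e)``.
    """
    if rng is None:
        rng = np.random.default_rng(protocol.seed)
    lam = protocol.dose_fraction * protocol.incident_photons * np.exp(-sinogram.p)
    counts = rng.poisson(lam).astype(np.float64) * protocol.detector_gain
    if protocol.electronic_noise_sd > 0:
        counts += rng.normal(0.0, protocol.electronic_noise_sd, size=counts.shape)
    return counts


def counts_to_sinogram(
    counts: np.ndarray,
    protocol: DoseProtocol,
    template: Sinogram,
    floor_counts: float = 1.0,
) -> Sinogram:
    """Log-transform counts back to line integrals with statistical weights.

    ``p_hat = ln(d*I0*g / max(N, floor))`` and ``w = max(N, floor)/g`` — the
    inverse-variance weight of the log-domain ray.  Flooring keeps rays
    finite through photon starvation.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.shape != template.p.shape:
        raise ValueError("counts shape does not match template sinogram")
    n = np.maximum(counts, floor_counts)
    full = protocol.dose_fraction * protocol.incident_photons * protocol.detector_gain
    p_hat = np.log(full / n)
    w = n / protocol.detector_gain
    return Sinogram(
        p=p_hat,
        angles=template.angles.copy(),
        bin_width=template.bin_width,
        weights=w,
        protocol=protocol,
    )


def sparse_sample(sinogram: Sinogram, keep_every: int) -> Sinogram:
    """Keep angles with index 0, k, 2k, ... and drop the rest.

    The per-ray statistics of retained rays are untouched (exact subset).
    """
    k = int(keep_every)
    if k == 1:
        return sinogram
    if k not in (2, 4, 10):
        warnings.warn(f"sparse_every={k} is outside the study's set {{2, 4, 10}}", stacklevel=2)
    idx = np.arange(0, sinogram.n_angles, k)
    if idx.size < 2:
        raise ValueError("fewer than 2 projection angles would survive sparse sampling")
    return Sinogram(
        p=sinogram.p[idx],
        angles=sinogram.angles[idx],
        bin_width=sinogram.bin_width,
        weights=None if sinogram.weights is None else sinogram.weights[idx],
        protocol=sinogram.protocol,
    )


def simulate_dose(
    sinogram: Sinogram,
    protocol: DoseProtocol,
    rng: np.random.Generator | None = None,
    floor_counts: float = 1.0,
) -> Sinogram:
    """Apply one acquisition condition to a noiseless sinogram.

    Counts are always simulated at the protocol's tube current (the
    reference and the sparse-sampling series use full current, d=1); sparse
    sampling then removes views from that full-current data.
    """
    counts = simulate_counts(sinogram, protocol, rng=rng)
    noisy = counts_to_sinogram(counts, protocol, sinogram, floor_counts=floor_counts)
    if protocol.sparse_every > 1:
        noisy = sparse_sample(noisy, protocol.sparse_every)
    return noisy
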