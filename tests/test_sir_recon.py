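"""Reconstruction: FBP accuracy, SPS monotonicity, convergence, acceleration."""

import dataclasses

import numpy as np
import pytest

from qctfe import projsim, sir_recon
from qctfe.sir_recon import SirConfig


@pytest.fixture(scope="module")
def disk_sino(disk_image, disk_projector):
    disk, _, _ = disk_image
    return projsim.forward_project(disk, disk_projector)


@pytest.fixture(scope="module")
def noisy_sino(disk_sino):
    protocol = projsim.DoseProtocol(dose_fraction=0.25, seed=1)
    return projsim.simulate_dose(disk_sino, protocol)


def test_fbp_recovers_disk_mean(disk_image, disk_projector, disk_sino):
    disk, r, mu0 = disk_image
    rec = sir_recon.fbp_reconstruct(disk_sino, disk_projector)
    xs = (np.arange(64) + 0.5) - 32
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    inside = X**2 + Y**2 <= (r - 3) ** 2
    assert rec[inside].mean() == pytest.approx(mu0, rel=0.03)


def test_fbp_zero_sinogram_gives_zero_image(disk_projector):
    sino = projsim.Sinogram(
        p=np.zeros((disk_projector.n_angles, disk_projector.geometry.n_bins)),
        angles=disk_projector.angles,
        bin_width=1.0,
    )
    assert np.allclose(sir_recon.fbp_reconstruct(sino, disk_projector), 0.0)


def test_fbp_sparser_views_increase_in_disk_noise(disk_image, disk_projector, disk_sino):
    disk, r, _ = disk_image
    geo = disk_projector.geometry
    sparse = projsim.sparse_sample(disk_sino, 10)
    proj10 = projsim.Projector((64, 64), 1.0, geo, angles=disk_projector.angles[::10])
    full_rec = sir_recon.fbp_reconstruct(disk_sino, disk_projector)
    sparse_rec = sir_recon.fbp_reconstruct(sparse, proj10)
    xs = (np.arange(64) + 0.5) - 32
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    inside = X**2 + Y**2 <= (r - 3) ** 2
    assert sparse_rec[inside].std() > full_rec[inside].std()


def test_objective_zero_at_truth_and_penalty_properties(disk_image, disk_projector, disk_sino):
    disk, _, mu0 = disk_image
    cfg0 = SirConfig(beta=0.0)
    phi = sir_recon.sir_objective(disk, disk_sino, disk_projector, cfg0)
    scale = sir_recon.sir_objective(np.zeros_like(disk), disk_sino, disk_projector, cfg0)
    assert phi <= 1e-8 * scale
    cfg_pen = SirConfig(beta=10.0)
    assert sir_recon.sir_objective(disk, disk_sino, disk_projector, cfg_pen) > phi
    # quadratic roughness of a constant image is zero
    const = np.full_like(disk, mu0)
    assert sir_recon._penalty_value(const, cfg_pen) == 0.0


def test_sps_objective_monotone_single_subset(noisy_sino, disk_projector):
    cfg = SirConfig(n_iterations=15, n_subsets=1, momentum=False, beta=1e3)
    _, trace = sir_recon.sir_reconstruct(noisy_sino, disk_projector, cfg)
    assert len(trace) == 16
    assert np.all(np.diff(trace) <= 1e-9 * abs(trace[0]))


def test_noiseless_reconstruction_converges_to_truth(disk_image, disk_projector, disk_sino):
    disk, _, mu0 = disk_image
    cfg = SirConfig(n_iterations=200, n_subsets=10, beta=0.0, momentum=True)
    rec, _ = sir_recon.sir_reconstruct(disk_sino, disk_projector, cfg)
    rmse = np.sqrt(np.mean((rec - disk) ** 2))
    assert rmse <= 0.005 * mu0  # 0.5% of the dynamic range


def test_momentum_accelerates_at_equal_budget(noisy_sino, disk_projector):
    on = SirConfig(n_iterations=30, n_subsets=10, beta=1e3, momentum=True)
    off = dataclasses.replace(on, momentum=False)
    _, tr_on = sir_recon.sir_reconstruct(noisy_sino, disk_projector, on)
    _, tr_off = sir_recon.sir_reconstruct(noisy_sino, disk_projector, off)
    assert tr_on[-1] <= 1.01 * tr_off[-1]


def test_subsets_partition_the_angle_set():
    subsets = sir_recon._subset_indices(47, 10)
    allidx = np.concatenate(subsets)
    assert len(allidx) == len(set(allidx.tolist())) == 47
    assert set(allidx.tolist()) == set(range(47))


def test_reconstruction_deterministic(noisy_sino, disk_projector):
    cfg = SirConfig(n_iterations=10, beta=1e3)
    a, _ = sir_recon.sir_reconstruct(noisy_sino, disk_projector, cfg)
    b, _ = sir_recon.sir_reconstruct(noisy_sino, disk_projector, cfg)
    assert np.array_equal(a, b)


def test_divergence_guard_trips_on_bad_scaling(disk_sino, disk_projector):
    # destroy the curvature majorization via absurd negative-weight-free trick:
    # a huge beta with zeros init keeps Phi finite, so instead corrupt weights
    bad = projsim.Sinogram(
        p=disk_sino.p,
        angles=disk_sino.angles,
        bin_width=disk_sino.bin_width,
        weights=np.full(disk_sino.p.shape, 1e12),
    )
    cfg = SirConfig(n_iterations=50, n_subsets=10, momentum=True, beta=0.0, init="zeros")
    # momentum over-extrapolation on an ill-scaled problem either converges or
    # raises the divergence guard; both leave the objective finite
    try:
        _, trace = sir_recon.sir_reconstruct(bad, disk_projector, cfg)
        assert np.all(np.isfinite(trace))
    except RuntimeError as err:
        assert "diverged" in str(err)


def test_dose_monotone_image_noise_after_reconstruction(disk_image, disk_projector):
    """Image-domain noise grows as tube current falls (1.0 -> 0.1)."""
    disk, r, _ = disk_image
    sino = projsim.forward_project(disk, disk_projector)
    xs = (np.arange(64) + 0.5) - 32
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    inside = X**2 + Y**2 <= (r - 4) ** 2
    cfg = SirConfig(n_iterations=12, beta=1e3, objective_every=0)
    noise = []
    for d in (1.0, 0.5, 0.25, 0.1):
        sds = []
        for rep in range(3):
            protocol = projsim.DoseProtocol(dose_fraction=d, seed=100 + rep)
            noisy = projsim.simulate_dose(sino, protocol)
            rec, _ = sir_recon.sir_reconstruct(noisy, disk_projector, cfg)
            sds.append(rec[inside].std())
        noise.append(np.mean(sds))
    assert np.all(np.diff(noise) > 0)


def test_sparse_view_beats_matched_tube_current_reduction(desk_phantom):
    """90% fewer views (full current) reconstructs the body more faithfully
    than 90% less current (all views) at matched iterations."""
    from qctfe import pipeline

    vol, body, _ = desk_phantom
    cfg = pipeline.RunConfig()
    projectors = pipeline._ProjectorCache(cfg)
    noiseless = pipeline.project_volume(projsim.hu_to_mu(vol), projectors.get(1))
    sircfg = dataclasses.replace(cfg.sir, beta=3.0e4)
    wins = 0
    for rep in range(3):
        rmse = {}
        for label in ("D10P100", "D100P10"):
            d, k = pipeline.CONDITIONS[label]
            protocol = projsim.DoseProtocol(
                dose_fraction=d,
                incident_photons=cfg.incident_photons,
                electronic_noise_sd=cfg.electronic_noise_sd,
                sparse_every=k,
                seed=700 + rep,
            )
            noisy = projsim.simulate_dose(noiseless, protocol)
            mu, _ = sir_recon.sir_reconstruct(noisy, projectors.get(k), sircfg)
            hu = projsim.mu_to_hu(mu)
            rmse[label] = np.sqrt(np.mean((hu[body] - vol.values[body]) ** 2))
        wins += rmse["D100P10"] < rmse["D10P100"]
    assert wins >= 2
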