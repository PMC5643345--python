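import numpy as np
import pytest

from cortivas import pci_sim
from cortivas.errors import GeometryError
from cortivas.pci_sim import BeamConfig, Sinogram
from cortivas.phantom import MaterialVolume


def cylinder_materials(n=64, nz=4, radius=20.0, delta=1e-6, beta=0.0,
                       voxel=1.0, antialias=False):
    """Homogeneous cylinder along z, centred on the rotation centre.

    With ``antialias`` the rim voxels get fractional coverage, which makes
    line integrals track the analytic chord length closely.
    """
    c = n // 2
    yy, xx = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
    r = np.sqrt(yy ** 2 + xx ** 2) * voxel
    if antialias:
        disk = np.clip((radius - r) / voxel + 0.5, 0.0, 1.0)
    else:
        disk = (r <= radius).astype(np.float64)
    delta_map = np.zeros((nz, n, n), dtype=np.float32)
    beta_map = np.zeros((nz, n, n), dtype=np.float32)
    delta_map[:] = disk * delta
    beta_map[:] = disk * beta
    return MaterialVolume(delta_map=delta_map, beta_map=beta_map,
                          voxel_size=voxel, energy_kev=21.0)


class TestBeamConfig:
    def test_wavelength_21kev(self):
        assert BeamConfig(energy_kev=21.0).wavelength_nm == pytest.approx(
            0.0590401, rel=1e-5)

    def test_energy_wavelength_roundtrip(self):
        for e in (5.0, 21.0, 80.0):
            lam = pci_sim.wavelength_nm(e)
            assert pci_sim.HC_KEV_NM / lam == pytest.approx(e, rel=1e-6)

    @pytest.mark.parametrize("kw", [
        dict(propagation_distance_mm=-1.0),
        dict(n_projections=0),
        dict(detector_pixel_um=0.0),
    ])
    def test_invalid_config(self, kw):
        with pytest.raises(GeometryError):
            BeamConfig(**kw).validate()


class TestProjectComplex:
    def test_zero_volume_unit_transmission(self):
        mat = cylinder_materials(delta=0.0, beta=0.0)
        beam = BeamConfig(n_projections=7)
        t = pci_sim.project_complex(mat, beam)
        assert np.allclose(t, 1.0, atol=1e-12)

    def test_cylinder_phase_matches_chord_length(self):
        radius, delta = 20.0, 1e-7  # small δ keeps |φ| < π (no wrapping)
        mat = cylinder_materials(n=128, nz=2, radius=radius, delta=delta,
                                 antialias=True)
        beam = BeamConfig(n_projections=3)
        t = pci_sim.project_complex(mat, beam)
        lam_um = beam.wavelength_nm * 1e-3
        phi = -np.angle(t[1, 0, :])
        c = 128 // 2
        offsets = (np.arange(128) - c) * 1.0
        inside = np.abs(offsets) <= radius - 2.0
        chord = 2.0 * np.sqrt(radius ** 2 - offsets[inside] ** 2)
        expected = (2 * np.pi / lam_um) * delta * chord
        assert np.allclose(phi[inside], expected, rtol=0.02)

    def test_mirror_symmetry(self):
        # Odd grid so the voxel mirror axis coincides with the rotation
        # centre: projecting a y-mirrored volume at θ equals the mirrored
        # projection at π−θ.
        rng = np.random.default_rng(0)
        vol = rng.random((3, 65, 65)).astype(np.float32)
        zeros = np.zeros_like(vol)
        theta = 0.4
        a, _ = pci_sim.line_integral_pair(vol[:, ::-1, :], zeros, theta)
        b, _ = pci_sim.line_integral_pair(vol, zeros, np.pi - theta)
        assert np.allclose(a, b[:, ::-1], atol=1e-10 * vol.sum())

    def test_pixel_voxel_mismatch_raises(self):
        mat = cylinder_materials()
        beam = BeamConfig(detector_pixel_um=2.0)
        with pytest.raises(GeometryError):
            pci_sim.project_complex(mat, beam)


def fresnel_integral_1d(t_profile, xs_um, lam_um, d_um, out_xs_um):
    """Direct 1D Fresnel diffraction integral (quadrature oracle)."""
    dx = xs_um[1] - xs_um[0]
    out = np.empty(len(out_xs_um), dtype=complex)
    for i, x in enumerate(out_xs_um):
        phase = np.pi * (x - xs_um) ** 2 / (lam_um * d_um)
        out[i] = np.sum(t_profile * np.exp(1j * phase)) * dx
    return out / np.sqrt(1j * lam_um * d_um)


class TestFresnelPropagate:
    def test_distance_zero_identity(self):
        rng = np.random.default_rng(1)
        t = np.exp(1j * rng.random((32, 32))) * rng.random((32, 32))
        out = pci_sim.fresnel_propagate(t, 0.0, 0.059, 1.0)
        assert np.max(np.abs(out - np.abs(t) ** 2)) < 1e-12

    def test_uniform_phase_invariance(self):
        t = np.full((64, 64), np.exp(1j * 0.7))
        out = pci_sim.fresnel_propagate(t, 25.0, 0.059, 1.0)
        assert np.allclose(out, 1.0, atol=1e-10)

    def test_phase_edge_fringe_position_vs_quadrature(self):
        # A pure phase step propagated 25 mm: the first intensity maximum
        # must sit where the direct Fresnel integral puts it, within 10 %.
        lam_um = 0.059e-3
        d_um = 25e3
        n = 512
        pixel = 0.5
        xs = (np.arange(n) - n // 2) * pixel
        phase = np.where(xs >= 0, 0.5, 0.0)
        t2d = np.tile(np.exp(1j * phase), (4, 1))
        intensity = pci_sim.fresnel_propagate(t2d, 25.0, 0.059, pixel)[0]

        fine = np.linspace(-40, 40, 4001)
        t_fine = np.exp(1j * np.where(fine >= 0, 0.5, 0.0))
        probe = np.linspace(0.1, 10.0, 400)
        oracle = np.abs(fresnel_integral_1d(t_fine, fine, lam_um, d_um,
                                            probe)) ** 2
        x_oracle = probe[np.argmax(oracle)]

        half = n // 2
        window = intensity[half:half + int(12 / pixel)]
        x_fft = np.argmax(window) * pixel
        assert x_fft == pytest.approx(x_oracle, rel=0.10, abs=pixel)
        # Characteristic fringe scale ~ sqrt(λD) ≈ 1.2 µm
        assert 0.4 < x_oracle < 3.0

    def test_sampling_bound_warning(self):
        t = np.ones((16, 16), dtype=complex)
        with pytest.warns(UserWarning, match="under-sampled"):
            pci_sim.fresnel_propagate(t, 5e4, 0.059, 0.5)

    def test_negative_distance_raises(self):
        with pytest.raises(GeometryError):
            pci_sim.fresnel_propagate(np.ones((8, 8), complex), -1, 0.059, 1.0)


class TestAcquire:
    def test_absorption_sinogram_matches_line_integrals(self):
        mat = cylinder_materials(radius=15.0, delta=0.0, beta=5e-9)
        beam = BeamConfig(propagation_distance_mm=0.0, n_projections=13)
        sino = pci_sim.acquire(mat, beam)
        t = pci_sim.project_complex(mat, beam)
        mu = -2.0 * np.log(np.abs(t))
        assert np.max(np.abs(-np.log(sino.intensities) - mu)) < 1e-6

    def test_noiseless_background_is_unity(self):
        mat = cylinder_materials(radius=10.0, delta=1e-7, beta=1e-9)
        sino = pci_sim.acquire(mat, BeamConfig(propagation_distance_mm=0.0,
                                               n_projections=5))
        # Rays missing the object see unit intensity (contact plane).
        assert sino.intensities[:, :, 2] == pytest.approx(1.0, abs=1e-6)
        # After propagation only weak diffraction tails reach the far field.
        sino25 = pci_sim.acquire(mat, BeamConfig(propagation_distance_mm=25.0,
                                                 n_projections=5))
        assert sino25.intensities[:, :, 2] == pytest.approx(1.0, abs=1e-4)

    def test_noiseless_determinism(self):
        mat = cylinder_materials(radius=10.0, delta=1e-7, beta=1e-9)
        beam = BeamConfig(n_projections=5)
        a = pci_sim.acquire(mat, beam)
        b = pci_sim.acquire(mat, beam)
        assert np.array_equal(a.intensities, b.intensities)

    def test_noisy_reproducible_with_seed(self):
        mat = cylinder_materials(radius=10.0, beta=5e-9)
        beam = BeamConfig(n_projections=5, photons_per_pixel=1e3, rng_seed=42)
        a = pci_sim.acquire(mat, beam)
        b = pci_sim.acquire(mat, beam)
        assert np.array_equal(a.intensities, b.intensities)

    def test_poisson_background_mean(self):
        # Mean over 100 seeded draws of a background pixel ≈ 1 within 3·SE.
        mat = cylinder_materials(n=16, nz=1, radius=4.0, beta=5e-9)
        n0 = 1000.0
        draws = []
        for seed in range(100):
            beam = BeamConfig(n_projections=1, photons_per_pixel=n0,
                              rng_seed=seed)
            draws.append(pci_sim.acquire(mat, beam).intensities[0, 0, 0])
        se = 1.0 / np.sqrt(n0 * 100)
        assert np.mean(draws) == pytest.approx(1.0, abs=3 * se)

    def test_two_distances_share_projection(self):
        mat = cylinder_materials(radius=10.0, delta=1e-6, beta=1e-9)
        b0 = BeamConfig(propagation_distance_mm=0.0, n_projections=5)
        b1 = BeamConfig(propagation_distance_mm=25.0, n_projections=5)
        multi = pci_sim.acquire_multi(mat, [b0, b1])
        assert np.array_equal(multi[0].intensities,
                              pci_sim.acquire(mat, b0).intensities)
        assert np.array_equal(multi[1].intensities,
                              pci_sim.acquire(mat, b1).intensities)


def _unit_sinogram(n_angles=16, n_det=32, value=1.0):
    beam = BeamConfig(n_projections=n_angles, detector_pixel_um=1.0)
    return Sinogram(intensities=np.full((n_angles, 4, n_det), value),
                    angles=beam.angles(), geometry=beam)


class TestRingCorrect:
    def test_clean_sinogram_passthrough(self):
        mat = cylinder_materials(radius=15.0, beta=5e-9)
        sino = pci_sim.acquire(mat, BeamConfig(propagation_distance_mm=0.0,
                                               n_projections=16))
        out = pci_sim.ring_correct(sino)
        assert np.max(np.abs(out.intensities - sino.intensities)) < 1e-6

    def test_defective_column_corrected(self):
        mat = cylinder_materials(radius=15.0, beta=5e-9)
        sino = pci_sim.acquire(mat, BeamConfig(propagation_distance_mm=0.0,
                                               n_projections=32))
        col = 30
        sino.intensities[:, :, col] *= 1.1
        out = pci_sim.ring_correct(sino)
        mean = out.intensities.mean(axis=(0, 1))
        neighbours = 0.5 * (mean[col - 1] + mean[col + 1])
        assert abs(mean[col] - neighbours) / neighbours < 0.01

    def test_zero_sinogram_stays_zero(self):
        sino = _unit_sinogram(value=0.0)
        out = pci_sim.ring_correct(sino)
        assert not out.intensities.any()

    def test_too_few_angles(self):
        with pytest.raises(GeometryError):
            pci_sim.ring_correct(_unit_sinogram(n_angles=4))


class TestReconstructFBP:
    def test_unit_sinogram_reconstructs_zero(self):
        recon = pci_sim.reconstruct_fbp(_unit_sinogram())
        assert np.max(np.abs(recon.values)) < 1e-6

    def test_disk_phantom_rmse(self):
        # Absorption-only disk, 181 angles, noiseless, D=0: RMSE < 5 % of
        # the disk contrast away from the 2-voxel rim band.
        beta = 5e-9
        mat = cylinder_materials(n=64, nz=2, radius=20.0, beta=beta)
        beam = BeamConfig(propagation_distance_mm=0.0, n_projections=181)
        recon = pci_sim.reconstruct_fbp(pci_sim.acquire(mat, beam))
        lam_um = beam.wavelength_nm * 1e-3
        mu_map = 4 * np.pi * mat.beta_map[0] / lam_um  # per µm = per voxel
        c = 64 // 2
        yy, xx = np.meshgrid(np.arange(64) - c, np.arange(64) - c,
                             indexing="ij")
        r = np.sqrt(yy ** 2 + xx ** 2)
        keep = (r <= 18.0) | ((r >= 22.0) & (r <= 28.0))
        err = recon.values[0][keep] - mu_map[keep]
        contrast = mu_map.max()
        assert np.sqrt(np.mean(err ** 2)) < 0.05 * contrast

    def test_linearity_in_log_domain(self):
        mat = cylinder_materials(radius=15.0, beta=5e-9)
        sino = pci_sim.acquire(mat, BeamConfig(propagation_distance_mm=0.0,
                                               n_projections=31))
        rec1 = pci_sim.reconstruct_fbp(sino)
        scaled = Sinogram(intensities=sino.intensities ** 2.0,
                          angles=sino.angles, geometry=sino.geometry)
        rec2 = pci_sim.reconstruct_fbp(scaled)
        assert np.allclose(rec2.values, 2.0 * rec1.values, atol=1e-5)

    def test_point_reconstructs_at_true_location(self):
        vol = np.zeros((1, 63, 63), dtype=np.float32)
        vol[0, 40, 25] = 1.0
        beam = BeamConfig(n_projections=45)
        angles = beam.angles()
        proj = np.stack(
            [pci_sim.line_integral_pair(vol, vol, a)[0] for a in angles])
        sino = Sinogram(intensities=np.exp(-proj), angles=angles,
                        geometry=beam)
        recon = pci_sim.reconstruct_fbp(sino)
        assert np.unravel_index(np.argmax(recon.values[0]),
                                recon.values[0].shape) == (40, 25)

    def test_too_few_angles_raises(self):
        beam = BeamConfig(n_projections=1)
        sino = Sinogram(intensities=np.ones((1, 2, 8)),
                        angles=beam.angles(), geometry=beam)
        with pytest.raises(GeometryError):
            pci_sim.reconstruct_fbp(sino)


class TestSerialisation:
    def test_sinogram_roundtrip(self, tmp_path):
        mat = cylinder_materials(radius=10.0, beta=5e-9)
        sino = pci_sim.acquire(mat, BeamConfig(n_projections=5))
        pci_sim.save_sinogram(sino, tmp_path / "s")
        loaded = pci_sim.load_sinogram(tmp_path / "s")
        assert np.allclose(loaded.intensities, sino.intensities, atol=1e-7)
        assert loaded.geometry == sino.geometry

    def test_recon_roundtrip(self, tmp_path):
        mat = cylinder_materials(radius=10.0, beta=5e-9)
        recon = pci_sim.reconstruct_fbp(
            pci_sim.acquire(mat, BeamConfig(n_projections=31)))
        pci_sim.save_recon(recon, tmp_path / "r")
        loaded = pci_sim.load_recon(tmp_path / "r")
        assert np.allclose(loaded.values, recon.values)
        assert loaded.provenance == recon.provenance
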