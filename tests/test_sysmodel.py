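"""Forward-model correctness: projector geometry, PSF, attenuation,
subsetting, count scaling and Poisson sampling."""

import numpy as np
import pytest

import fbsempet as fp
from fbsempet.sysmodel import make_normalisation


@pytest.fixture(scope="module")
def grid_geom():
    return fp.ImageGrid(32, 32), fp.ScannerGeometry(48, 48)


@pytest.fixture(scope="module")
def projector(grid_geom):
    return fp.build_projector(*grid_geom)


class TestProjector:
    def test_line_integral_matches_chord_length(self):
        """Uniform disk: a ray's line integral equals its chord length (2%)."""
        grid = fp.ImageGrid(64, 64)
        geom = fp.ScannerGeometry(8, 64)
        proj = fp.build_projector(grid, geom)
        yy, xx = np.mgrid[:64, :64]
        radius_px = 28
        disk = (((xx - 31.5) ** 2 + (yy - 31.5) ** 2) <= radius_px ** 2).astype(float)
        sino = (proj @ disk.ravel()).reshape(geom.n_angles, geom.n_radial_bins)
        r_off = (np.arange(64) - 31.5) * grid.pixel_size_mm
        R = radius_px * grid.pixel_size_mm
        for b in (26, 31, 36):
            chord = 2 * np.sqrt(R ** 2 - r_off[b] ** 2)
            for a in range(8):
                assert abs(sino[a, b] - chord) / chord < 0.02

    def test_zero_image_gives_zero_sinogram(self, projector):
        assert np.all(projector @ np.zeros(projector.shape[1]) == 0)

    def test_impulse_traces_a_narrow_sinusoid(self, grid_geom, projector):
        grid, geom = grid_geom
        img = np.zeros((32, 32))
        img[10, 20] = 1.0
        sino = (projector @ img.ravel()).reshape(geom.n_angles, geom.n_radial_bins)
        assert np.all(sino >= 0)
        hits = (sino > 0).sum(axis=1)
        assert np.all(hits >= 1) and np.all(hits <= 6)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            fp.ScannerGeometry(1, 32)

    def test_adjoint_consistency(self, projector):
        rng = np.random.default_rng(0)
        u = rng.random(projector.shape[1])
        v = rng.random(projector.shape[0])
        lhs = (projector @ u) @ v
        rhs = u @ (projector.T @ v)
        assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_in_fov_pixels_have_positive_column_sum(self, grid_geom, projector):
        grid, _ = grid_geom
        colsum = np.asarray(projector.sum(axis=0)).ravel().reshape(32, 32)
        yy, xx = np.mgrid[:32, :32]
        fov = ((xx - 15.5) ** 2 + (yy - 15.5) ** 2) <= 14 ** 2
        assert np.all(colsum[fov] > 0)


class TestPSF:
    def test_zero_fwhm_is_identity(self):
        grid = fp.ImageGrid(16, 16)
        H = fp.gaussian_psf(0.0, grid)
        x = np.random.default_rng(0).random(256)
        np.testing.assert_array_equal(H @ x, x)

    def test_sigma_conversion(self):
        # 2.5 mm FWHM at 2.08 mm pixels -> sigma ~ 0.5104 px
        sigma = 2.5 / (2 * np.sqrt(2 * np.log(2))) / 2.08
        assert abs(sigma - 0.5104) < 5e-4

    def test_mass_preserving(self):
        grid = fp.ImageGrid(24, 24)
        H = fp.gaussian_psf(4.0, grid)
        x = np.random.default_rng(1).random(576)
        assert abs((H @ x).sum() - x.sum()) / x.sum() < 1e-8

    def test_uniform_image_fixed_in_interior(self):
        grid = fp.ImageGrid(24, 24)
        H = fp.gaussian_psf(2.5, grid)
        out = (H @ np.ones(576)).reshape(24, 24)
        np.testing.assert_allclose(out[4:-4, 4:-4], 1.0, atol=1e-8)

    def test_nonnegativity_preserved(self):
        grid = fp.ImageGrid(16, 16)
        H = fp.gaussian_psf(3.0, grid)
        x = np.random.default_rng(2).random(256)
        assert np.all(H @ x >= -1e-15)


class TestAttenuation:
    def test_zero_mu_gives_unity(self, projector):
        a = fp.attenuation_factors(np.zeros((32, 32)), projector)
        np.testing.assert_array_equal(a, 1.0)

    def test_known_chord_value(self):
        """Uniform mu = 0.0975/cm along a 10 cm chord -> exp(-0.975)."""
        grid = fp.ImageGrid(64, 64, pixel_size_mm=2.08)
        geom = fp.ScannerGeometry(4, 64)
        proj = fp.build_projector(grid, geom)
        yy, xx = np.mgrid[:64, :64]
        R_px = 50.0 / 2.08        # 10 cm diameter disk
        disk = ((xx - 31.5) ** 2 + (yy - 31.5) ** 2) <= R_px ** 2
        mu = np.where(disk, 0.0975, 0.0)
        a = fp.attenuation_factors(mu, proj).reshape(4, 64)
        central = a[0, 31:33].min()
        assert abs(central - np.exp(-0.975)) < 0.01

    def test_monotone_in_mu(self, projector):
        rng = np.random.default_rng(0)
        mu = rng.random((32, 32)) * 0.01
        a1 = fp.attenuation_factors(mu, projector)
        mu2 = mu.copy()
        mu2[16, 16] += 0.05
        a2 = fp.attenuation_factors(mu2, projector)
        assert np.all(a2 <= a1 + 1e-15)

    def test_negative_mu_rejected(self, projector):
        with pytest.raises(ValueError):
            fp.attenuation_factors(np.full((32, 32), -0.1), projector)

    def test_bounds(self, projector):
        mu = np.full((32, 32), 0.0975)
        a = fp.attenuation_factors(mu, projector)
        assert np.all(a > 0) and np.all(a <= 1)


class TestAssemble:
    def test_subsets_disjoint_cover(self, grid_geom, projector):
        grid, geom = grid_geom
        sys = fp.assemble_system(projector, fp.gaussian_psf(0, grid),
                                 np.ones(geom.n_bins), np.ones(geom.n_bins),
                                 6, grid, geom)
        all_rows = np.concatenate(sys.subset_rows)
        assert len(all_rows) == geom.n_bins
        assert len(np.unique(all_rows)) == geom.n_bins
        # 48 angles / 6 subsets -> 8 angles each
        for rows in sys.subset_rows:
            assert len(rows) == 8 * geom.n_radial_bins

    def test_subset_sensitivities_sum_to_global(self, small_system):
        total = small_system.subset_sens.sum(axis=0)
        np.testing.assert_allclose(total, small_system.sens, rtol=1e-10)

    def test_single_subset_sensitivity_is_global(self, small_system_1sub):
        np.testing.assert_allclose(small_system_1sub.subset_sens[0],
                                   small_system_1sub.sens, rtol=1e-12)

    def test_identity_factors_give_geometric_operator(self, grid_geom, projector):
        grid, geom = grid_geom
        sys = fp.assemble_system(projector, fp.gaussian_psf(0, grid),
                                 np.ones(geom.n_bins), np.ones(geom.n_bins),
                                 1, grid, geom)
        d = (sys.P - projector)
        assert abs(d).max() < 1e-12

    def test_too_many_subsets_rejected(self, grid_geom, projector):
        grid, geom = grid_geom
        with pytest.raises(ValueError):
            fp.assemble_system(projector, fp.gaussian_psf(0, grid),
                               np.ones(geom.n_bins), np.ones(geom.n_bins),
                               49, grid, geom)


class TestForwardModel:
    def test_zero_image(self, small_system):
        np.testing.assert_array_equal(
            fp.forward_model(np.zeros(small_system.n_voxels), small_system), 0.0)

    def test_linearity(self, small_system):
        rng = np.random.default_rng(0)
        x1 = rng.random(small_system.n_voxels)
        x2 = rng.random(small_system.n_voxels)
        f = lambda x: fp.forward_model(x, small_system)
        np.testing.assert_allclose(f(x1 + x2), f(x1) + f(x2), rtol=1e-12)

    def test_matches_dense_oracle_on_toy(self, toy_system):
        rng = np.random.default_rng(1)
        x = rng.random(toy_system.n_voxels)
        dense = toy_system.P.toarray()
        np.testing.assert_allclose(fp.forward_model(x, toy_system),
                                   dense @ x, rtol=1e-12, atol=1e-14)

    def test_shape_mismatch(self, small_system):
        with pytest.raises(ValueError):
            fp.forward_model(np.ones(7), small_system)


class TestScaling:
    def test_hits_requested_totals(self, small_system, one_sample):
        ybar = fp.forward_model(one_sample.activity, one_sample.sys)
        for total in (5e5, 1e8):
            scaled, _ = fp.scale_to_counts(ybar, total)
            assert abs(scaled.sum() - total) / total < 1e-9

    def test_identity_and_roundtrip(self, small_system, one_sample):
        ybar = fp.forward_model(one_sample.activity, one_sample.sys)
        same, f = fp.scale_to_counts(ybar, ybar.sum())
        np.testing.assert_allclose(same, ybar, rtol=1e-12)
        assert abs(f - 1) < 1e-12
        up, _ = fp.scale_to_counts(ybar, 123.0)
        back, _ = fp.scale_to_counts(up, ybar.sum())
        np.testing.assert_allclose(back, ybar, rtol=1e-9)

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            fp.scale_to_counts(np.zeros(5), 100.0)


class TestPoisson:
    def test_zero_mean_gives_zero(self):
        assert np.all(fp.sample_poisson(np.zeros(10), 0) == 0)

    def test_seed_reproducibility(self):
        ybar = np.full(100, 7.3)
        np.testing.assert_array_equal(fp.sample_poisson(ybar, 5),
                                      fp.sample_poisson(ybar, 5))

    def test_sample_mean_within_clt_bound(self):
        """10,000 draws per bin on a 10-bin toy: mean within 3 SE of ybar."""
        ybar = np.array([0.5, 1, 2, 3, 5, 8, 12, 20, 50, 100.0])
        draws = fp.sample_poisson(np.tile(ybar, (10000, 1)), 11)
        means = draws.mean(axis=0)
        se = np.sqrt(ybar / 10000)
        assert np.all(np.abs(means - ybar) <= 3 * se)


def test_normalisation_range_and_determinism():
    geom = fp.ScannerGeometry(12, 8)
    n1 = make_normalisation(geom, seed=5)
    n2 = make_normalisation(geom, seed=5)
    np.testing.assert_array_equal(n1, n2)
    assert np.all((n1 >= 0.8) & (n1 <= 1.2))
    assert np.all(make_normalisation(geom, seed=5, enabled=False) == 1.0)


def test_system_model_hdf5_roundtrip(tmp_path, toy_system):
    path = str(tmp_path / "sys.h5")
    toy_system.to_hdf5(path)
    back = fp.SystemModel.from_hdf5(path)
    assert abs(back.P - toy_system.P).max() < 1e-15
    np.testing.assert_allclose(back.sens, toy_system.sens, rtol=1e-14)


def test_sinogram_set_roundtrip(tmp_path):
    import h5py
    y = np.array([1.0, 0, 3])
    ss = fp.SinogramSet(y=y, ybar=np.array([1.1, 0.2, 2.9]))
    with h5py.File(tmp_path / "s.h5", "w") as f:
        ss.to_hdf5(f.create_group("g"))
    with h5py.File(tmp_path / "s.h5", "r") as f:
        back = fp.SinogramSet.from_hdf5(f["g"])
    np.testing.assert_array_equal(back.y, ss.y)
    np.testing.assert_array_equal(back.s_sc, np.zeros(3))
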