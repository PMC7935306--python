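"""Forward projection, air correction and fan-beam FBP."""
import numpy as np
import pytest

from specctmar.phantoms import make_water_phantom
from specctmar.physics import BinConfig, Spectrum
from specctmar.recon import (FanGeometry, air_scan, fbp, forward_project,
                             log_normalize, project_image,
                             water_precorrection, BinSinogram)
from specctmar.pipeline import simulate_scan

MONO = BinConfig((30.0,), 140.0)


@pytest.fixture(scope="module")
def water100(table):
    return make_water_phantom(100.0, shape=256, pixel_size=1.0)


@pytest.fixture(scope="module")
def mono60(table):
    return Spectrum.monochromatic(60.0, 1.0, table)


class TestGeometry:
    def test_default_covers_fov(self):
        geo = FanGeometry()
        assert geo.fov_coverage() >= geo.fov_diameter

    def test_insufficient_fan_rejected(self):
        with pytest.raises(ValueError, match="fan"):
            FanGeometry(n_channels=128)

    def test_scaled_preserves_coverage(self):
        assert FanGeometry().scaled(2).fov_coverage() >= 250.0


class TestForwardProject:
    def test_central_ray_matches_analytic_chord(self, water100, geometry,
                                                mono60, table):
        sino = forward_project(water100, geometry, mono60, MONO)[0]
        air = air_scan(geometry, mono60, MONO)[0]
        p = log_normalize(sino, air)
        mu = table.mu_lin("water")[np.argmin(np.abs(table.energies - 60.0))]
        assert p[0].max() == pytest.approx(100.0 * mu, rel=0.005)

    def test_empty_phantom_equals_air_scan(self, geometry, mono60):
        empty = make_water_phantom(100.0, shape=64, pixel_size=4.0)
        empty.grid[:] = 0
        sinos = forward_project(empty, geometry, mono60, MONO)
        airs = air_scan(geometry, mono60, MONO)
        np.testing.assert_allclose(sinos[0].counts, airs[0].counts)

    def test_seeded_noise_reproducible(self, water100, geometry, mono60):
        a = forward_project(water100, geometry, mono60, MONO, noise=True,
                            seed=3)[0]
        b = forward_project(water100, geometry, mono60, MONO, noise=True,
                            seed=3)[0]
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_oversized_phantom_rejected(self, geometry, mono60):
        from specctmar.phantoms import Composition, DigitalPhantom
        grid = np.ones((64, 64), dtype=np.int16)  # fills the 281-mm grid
        big = DigitalPhantom(grid, {1: Composition({"water": 1.0}, 1.0)},
                             pixel_size=4.4)
        with pytest.raises(ValueError, match="FOV"):
            forward_project(big, geometry, mono60, MONO)

    def test_air_bin_totals_follow_fluence(self, geometry, spectrum, bins):
        airs = air_scan(geometry, spectrum, bins)
        totals = [a.counts[0, 0] for a in airs]
        # bin ordering matches the spectrum's per-bin fluence integrals
        from specctmar.physics import bin_spectrum
        fluences = [s.total for s in bin_spectrum(spectrum, bins)]
        assert np.argsort(totals).tolist() == np.argsort(fluences).tolist()


class TestLogNormalize:
    def test_reference_values(self):
        air = BinSinogram(np.full((4, 4), 100.0), 0)
        obj = BinSinogram(np.full((4, 4), 100.0 / np.e), 0)
        np.testing.assert_allclose(log_normalize(obj, air), 1.0)
        np.testing.assert_allclose(log_normalize(air, air), 0.0)

    def test_monotone_in_counts(self):
        air = BinSinogram(np.full((1, 3), 1000.0), 0)
        obj = BinSinogram(np.array([[500.0, 100.0, 1.0]]), 0)
        p = log_normalize(obj, air)[0]
        assert p[0] < p[1] < p[2]


class TestFBP:
    def test_zero_sinogram_zero_image(self, geometry):
        img = fbp(np.zeros((geometry.n_views, geometry.n_channels)),
                  geometry, 1.0, 64)
        np.testing.assert_allclose(img, 0.0)

    def test_linearity(self, water100, geometry, mono60):
        p = log_normalize(
            forward_project(water100, geometry, mono60, MONO)[0],
            air_scan(geometry, mono60, MONO)[0])
        np.testing.assert_allclose(fbp(2.5 * p, geometry, 1.0, 128),
                                   2.5 * fbp(p, geometry, 1.0, 128),
                                   atol=1e-12)

    def test_water_disk_recovers_mu(self, water100, geometry, mono60, table):
        scan = simulate_scan(water100, geometry, mono60, MONO,
                             water_precorrect=False)
        mu = table.mu_lin("water")[np.argmin(np.abs(table.energies - 60.0))]
        xx, yy = water100.coords()
        interior = xx ** 2 + yy ** 2 < 40.0 ** 2
        img = scan.bin_images[0].mu
        assert img[interior].mean() == pytest.approx(mu, rel=0.02)
        # disk edge at the correct radius: half-max crossing near 50 mm
        profile = img[128]
        inside = np.nonzero(profile > mu / 2)[0]
        assert abs((inside.size / 2.0) - 50.0) < 2.0

    def test_nan_rejected(self, geometry):
        p = np.zeros((geometry.n_views, geometry.n_channels))
        p[0, 0] = np.nan
        with pytest.raises(ValueError):
            fbp(p, geometry, 1.0, 64)


class TestProjectImage:
    def test_zero_and_additivity(self, geometry):
        rng = np.random.default_rng(0)
        a = rng.random((128, 128))
        b = rng.random((128, 128))
        np.testing.assert_allclose(project_image(np.zeros((64, 64)),
                                                 geometry, 1.0), 0.0)
        np.testing.assert_allclose(
            project_image(a + b, geometry, 2.0),
            project_image(a, geometry, 2.0) + project_image(b, geometry, 2.0),
            rtol=1e-10, atol=1e-9)

    def test_impulse_traces_a_sinusoid(self, geometry):
        img = np.zeros((128, 128))
        img[40, 80] = 1.0
        sino = project_image(img, geometry, 2.0)
        hit = sino > 0
        # every view sees the impulse in a narrow channel band
        assert np.all(hit.any(axis=1))
        assert hit.sum(axis=1).max() <= 6
        # channel of maximum support moves smoothly with view angle
        ch = np.argmax(sino, axis=1)
        assert np.abs(np.diff(ch)).max() <= 4

    def test_fbp_project_round_trip(self, geometry):
        x = (np.arange(256) - 127.5) / 60.0
        xx, yy = np.meshgrid(x, x)
        smooth = np.exp(-(xx ** 2 + yy ** 2))
        rec = fbp(project_image(smooth, geometry, 1.0), geometry, 1.0, 256)
        sel = (xx ** 2 + yy ** 2) < 3.0
        rel = (np.sqrt(np.mean((rec[sel] - smooth[sel]) ** 2))
               / np.sqrt(np.mean(smooth[sel] ** 2)))
        assert rel < 0.05


class TestBeamHardening:
    def test_cupping_emerges_and_vanishes(self, geometry, spectrum, table):
        # broad polyenergetic scan of water shows center-vs-edge cupping
        # without precorrection; the monoenergetic scan does not
        ph = make_water_phantom(140.0, shape=128, pixel_size=2.0)
        broad = BinConfig((30.0,), 140.0)
        poly = simulate_scan(ph, geometry, spectrum, broad,
                             water_precorrect=False)
        mono = simulate_scan(ph, geometry,
                             Spectrum.monochromatic(60.0, 1.0, table), broad,
                             water_precorrect=False)
        xx, yy = ph.coords()
        r2 = xx ** 2 + yy ** 2
        center = r2 < 20.0 ** 2
        edge = (r2 > 50.0 ** 2) & (r2 < 62.0 ** 2)

        def cupping(scan):
            img = scan.bin_images[0].mu
            return (img[edge].mean() - img[center].mean()) / img[edge].mean()

        assert cupping(poly) > 0.02
        assert abs(cupping(mono)) < 0.005

    def test_precorrection_flattens_water(self, geometry, spectrum):
        ph = make_water_phantom(140.0, shape=128, pixel_size=2.0)
        broad = BinConfig((30.0,), 140.0)
        scan = simulate_scan(ph, geometry, spectrum, broad,
                             water_precorrect=True)
        hu = scan.broad_hu()
        xx, yy = ph.coords()
        interior = xx ** 2 + yy ** 2 < 55.0 ** 2
        assert abs(hu[interior].mean()) < 2.0
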