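"""Material decomposition, VMI synthesis, iodine quantification, overlays."""
import numpy as np
import pytest

from specctmar.physics import BinConfig, Spectrum, bin_spectrum
from specctmar.recon import BinImage
from specctmar.spectral import (MuMatrix, build_mu_matrix, classify_overlay,
                                decompose, quantify_iodine, synthesize_vmi)

BASIS = ("water", "iodine_cal", "bone")


@pytest.fixture(scope="module")
def matrix(spectrum, bins, table):
    return build_mu_matrix(BASIS, spectrum, bins, table)


def images_from_fractions(matrix, b_maps):
    """Forward-compose bin images from known fractions (the brute-force oracle)."""
    stack = np.einsum("im,mxy->ixy", matrix.matrix, b_maps)
    return [BinImage(stack[i], i, 1.0) for i in range(stack.shape[0])]


class TestMuMatrix:
    def test_iodine_column_decreases_with_bin(self, matrix):
        col = matrix.matrix[:, 1]
        assert col[0] > col[1] > col[2]

    def test_monoenergetic_bins_give_pointwise_mu(self, table):
        # three delta spectra at 40/55/80 keV in one three-bin configuration
        cfg = BinConfig((35.0, 50.0, 70.0), 140.0)
        f = np.zeros_like(table.energies)
        for e in (40.0, 55.0, 80.0):
            f[np.argmin(np.abs(table.energies - e))] = 1.0
        spec = Spectrum(table.energies.copy(), f)
        m = build_mu_matrix(BASIS, spec, cfg, table)
        for i, e in enumerate((40.0, 55.0, 80.0)):
            for j, mat in enumerate(BASIS):
                assert m.matrix[i, j] == pytest.approx(
                    float(table.mu_lin_at(mat, e)), rel=1e-6)

    def test_singular_matrix_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            MuMatrix(np.ones((3, 3)), BASIS)

    def test_ill_conditioned_warns(self):
        m = np.eye(3)
        m[2, 2] = 1e-5
        with pytest.warns(UserWarning, match="condition"):
            MuMatrix(m, BASIS)

    def test_calibration_mode_consistent_with_spectral(self, spectrum, bins,
                                                       table, matrix):
        # regress the matrix from synthetic ROI data made with known fractions
        rng = np.random.default_rng(5)
        fracs = [dict(zip(BASIS, row)) for row in rng.random((6, 3))]
        samples = [(matrix.matrix @ np.array([f[m] for m in BASIS]), f)
                   for f in fracs]
        m_cal = build_mu_matrix(BASIS, spectrum, bins, table,
                                mode="calibration", calibration=samples)
        np.testing.assert_allclose(m_cal.matrix, matrix.matrix, rtol=1e-8)


class TestDecompose:
    def test_water_column_unit_solve(self, matrix):
        imgs = [BinImage(np.full((4, 4), matrix.matrix[i, 0]), i, 1.0)
                for i in range(3)]
        maps = decompose(imgs, matrix)
        np.testing.assert_allclose(maps["water"], 1.0, atol=1e-12)
        np.testing.assert_allclose(maps["iodine_cal"], 0.0, atol=1e-12)

    def test_random_fractions_recovered_exactly(self, matrix):
        rng = np.random.default_rng(7)
        b_true = rng.random((3, 16, 16))
        maps = decompose(images_from_fractions(matrix, b_true), matrix)
        for k, name in enumerate(BASIS):
            np.testing.assert_allclose(maps[name], b_true[k], atol=1e-12)

    def test_air_decomposes_to_zero(self, matrix):
        imgs = [BinImage(np.full((4, 4), 1e-6), i, 1.0) for i in range(3)]
        maps = decompose(imgs, matrix)
        for name in BASIS:
            assert np.all(maps[name] < 1e-3)

    def test_out_of_range_solutions_clipped(self, matrix):
        b_true = np.zeros((3, 2, 2))
        b_true[0] = 1.5  # unphysical water excess
        maps = decompose(images_from_fractions(matrix, b_true), matrix)
        assert np.all(maps["water"] == 1.0)
        assert maps.raw_fractions["water"][0, 0] == pytest.approx(1.5)

    def test_nan_rejected(self, matrix):
        imgs = [BinImage(np.zeros((2, 2)), i, 1.0) for i in range(3)]
        imgs[0].mu[0, 0] = np.nan
        with pytest.raises(ValueError):
            decompose(imgs, matrix)

    def test_round_trip_compose_where_unclipped(self, matrix):
        rng = np.random.default_rng(9)
        b_true = rng.random((3, 8, 8))
        imgs = images_from_fractions(matrix, b_true)
        maps = decompose(imgs, matrix)
        recomposed = np.einsum(
            "im,mxy->ixy", matrix.matrix,
            np.stack([maps[n] for n in BASIS]))
        for i in range(3):
            np.testing.assert_allclose(recomposed[i], imgs[i].mu, atol=1e-12)


class TestVMI:
    def test_pure_water_is_zero_hu_at_any_energy(self, matrix, table):
        maps = decompose([BinImage(np.full((4, 4), matrix.matrix[i, 0]),
                                   i, 1.0) for i in range(3)], matrix)
        for e in (40.0, 70.0, 140.0):
            np.testing.assert_allclose(synthesize_vmi(maps, e, table), 0.0,
                                       atol=1e-9)

    def test_empty_maps_are_air(self, matrix, table):
        maps = decompose([BinImage(np.zeros((4, 4)), i, 1.0)
                          for i in range(3)], matrix)
        np.testing.assert_allclose(synthesize_vmi(maps, 80.0, table), -1000.0,
                                   atol=1e-6)

    def test_energy_outside_table_rejected(self, matrix, table):
        maps = decompose([BinImage(np.zeros((2, 2)), i, 1.0)
                          for i in range(3)], matrix)
        with pytest.raises(ValueError):
            synthesize_vmi(maps, 160.0, table)

    def test_single_material_vmi_matches_bin_mu(self, spectrum, bins, table):
        # a pure-PMMA phantom: the VMI at each bin's (water-matched) effective
        # energy agrees with the bin image's attenuation within 2%
        from specctmar.physics import bin_effective_energy
        m = build_mu_matrix(("pmma", "iodine_cal", "bone"), spectrum, bins,
                            table)
        imgs = [BinImage(np.full((2, 2), m.matrix[i, 0]), i, 1.0)
                for i in range(3)]
        maps = decompose(imgs, m)
        for i in range(3):
            e_eff = bin_effective_energy(spectrum, i, bins, table)
            vmi_mu = (1.0 + synthesize_vmi(maps, e_eff, table)[0, 0]
                      / 1000.0) * float(table.mu_lin_at("water", e_eff))
            assert vmi_mu == pytest.approx(m.matrix[i, 0], rel=0.02)


class TestQuantifyIodine:
    @pytest.mark.parametrize("value,expected", [(1.0, 18.9), (0.0, 0.0),
                                                (0.5, 9.45)])
    def test_linear_calibration_scale(self, value, expected):
        out = quantify_iodine(np.full((2, 2), value), 18.9)
        np.testing.assert_allclose(out, expected)

    def test_invalid_calibration_rejected(self):
        with pytest.raises(ValueError):
            quantify_iodine(np.ones((2, 2)), 0.0)


class TestClassifyOverlay:
    def test_water_region_is_neither(self, spectrum, bins, table):
        m = build_mu_matrix(("water", "iodine_cal", "calcium"), spectrum,
                            bins, table)
        maps = decompose([BinImage(np.full((4, 4), m.matrix[i, 0]), i, 1.0)
                          for i in range(3)], m)
        assert np.all(classify_overlay(maps) == 0)

    def test_basis_permutation_swaps_labels(self, spectrum, bins, table):
        m = build_mu_matrix(("water", "iodine_cal", "calcium"), spectrum,
                            bins, table)
        b_true = np.zeros((3, 2, 2))
        b_true[1, 0, 0] = 0.5   # iodine pixel
        b_true[2, 1, 1] = 0.5   # calcium pixel
        imgs = images_from_fractions(m, b_true)
        maps = decompose(imgs, m)
        labels = classify_overlay(maps)
        assert labels[0, 0] == 1 and labels[1, 1] == 2
        # permuted basis order must classify identically
        m_perm = build_mu_matrix(("calcium", "iodine_cal", "water"), spectrum,
                                 bins, table)
        maps_perm = decompose(imgs, m_perm)
        np.testing.assert_array_equal(classify_overlay(maps_perm), labels)

    def test_missing_basis_rejected(self, matrix):
        maps = decompose([BinImage(np.zeros((2, 2)), i, 1.0)
                          for i in range(3)], matrix)
        with pytest.raises(KeyError):
            classify_overlay(maps)
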