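"""Optical-filter and sensor-simulation forward model."""

import numpy as np
import pytest

from pepperseg.optics import (CameraResponse, ConfigurationError,
                              GridMismatchError, SpectralCube,
                              TransmittanceCurve, apply_filter,
                              default_band_grid, estimate_normalization_bounds,
                              gaussian_csr, initial_filter, load_csr_csv,
                              load_transmittance_csv, normalize_and_clip,
                              save_transmittance_csv, sense_rgb)


def triple_loop_forward(cube, filt, csr):
    """Direct per-pixel, per-band evaluation of the filter + CSR equations."""
    H, W, N = cube.values.shape
    out = np.zeros((3, H, W))
    for y in range(H):
        for x in range(W):
            for k in range(3):
                acc = 0.0
                for i in range(N):
                    acc += csr.sensitivities[k, i] * cube.values[y, x, i] * filt.weights[i]
                out[k, y, x] = acc
    return out


class TestApplyFilter:
    def test_identity_and_opaque_filters(self, small_cube):
        ones = TransmittanceCurve(np.ones(20), small_cube.wavelengths)
        np.testing.assert_array_equal(apply_filter(small_cube, ones).values,
                                      small_cube.values)
        zeros = TransmittanceCurve(np.zeros(20), small_cube.wavelengths)
        assert apply_filter(small_cube, zeros).values.max() == 0.0

    def test_elementwise_product_hand_case(self):
        wl = np.array([500.0, 600.0])
        cube = SpectralCube(np.array([[[2.0, 3.0]]]), wl)
        filt = TransmittanceCurve(np.array([0.5, 0.1]), wl)
        np.testing.assert_allclose(apply_filter(cube, filt).values, [[[1.0, 0.3]]])

    def test_mismatched_grids_rejected(self, small_cube):
        filt = TransmittanceCurve(np.ones(10), np.linspace(400, 700, 10))
        with pytest.raises(GridMismatchError):
            apply_filter(small_cube, filt)

    def test_linearity_in_the_filter(self, small_cube, rng):
        wl = small_cube.wavelengths
        t1 = rng.uniform(0, 1, 20)
        t2 = rng.uniform(0, 1, 20)
        a, b = 0.7, 1.3
        combo = apply_filter(small_cube, TransmittanceCurve(a * t1 + b * t2, wl))
        parts = (a * apply_filter(small_cube, TransmittanceCurve(t1, wl)).values
                 + b * apply_filter(small_cube, TransmittanceCurve(t2, wl)).values)
        np.testing.assert_allclose(combo.values, parts, rtol=1e-12)


class TestSenseRgb:
    def test_selector_row_extracts_band_plane(self, small_cube):
        sens = np.zeros((3, 20))
        sens[:, 4] = 1.0  # every channel selects band 4
        csr = CameraResponse(sens, small_cube.wavelengths)
        raw = sense_rgb(small_cube, csr)
        for k in range(3):
            np.testing.assert_allclose(raw[k], small_cube.values[:, :, 4])

    def test_row_summing_to_one_preserves_constant_cube(self):
        wl = np.linspace(400, 700, 5)
        cube = SpectralCube(np.full((3, 3, 5), 2.5), wl)
        sens = np.full((3, 5), 0.2)
        raw = sense_rgb(cube, CameraResponse(sens, wl))
        np.testing.assert_allclose(raw, 2.5)

    def test_dot_product_hand_case(self):
        wl = np.array([450.0, 550.0, 650.0])
        cube = SpectralCube(np.array([[[1.0, 2.0, 3.0]]]), wl)
        sens = np.tile([0.1, 0.2, 0.3], (3, 1))
        raw = sense_rgb(cube, CameraResponse(sens, wl))
        np.testing.assert_allclose(raw[:, 0, 0], 1.4)

    def test_negative_csr_rejected_at_construction(self):
        wl = np.linspace(400, 700, 4)
        with pytest.raises(ValueError):
            CameraResponse(np.array([[1, -0.1, 0, 0]] * 3, dtype=float), wl)

    def test_composed_path_matches_triple_loop_oracle(self, small_cube,
                                                      small_filter, small_csr):
        fast = sense_rgb(apply_filter(small_cube, small_filter), small_csr)
        slow = triple_loop_forward(small_cube, small_filter, small_csr)
        np.testing.assert_allclose(fast, slow, rtol=1e-6)

    def test_raising_one_weight_never_decreases_any_channel(self, small_cube,
                                                            small_csr, rng):
        w = rng.uniform(0.1, 0.9, 20)
        wl = small_cube.wavelengths
        base = sense_rgb(apply_filter(small_cube, TransmittanceCurve(w, wl)), small_csr)
        for i in (0, 7, 19):
            w2 = w.copy()
            w2[i] += 0.3
            up = sense_rgb(apply_filter(small_cube, TransmittanceCurve(w2, wl)), small_csr)
            assert (up >= base - 1e-12).all()


class TestNormalizeAndClip:
    def test_raw_at_min_gets_epsilon_floor(self):
        raw = np.full((3, 2, 2), 5.0)
        img = normalize_and_clip(raw, norm_min=5.0, norm_max=10.0, epsilon=0.01)
        np.testing.assert_allclose(img.channels, 0.01)

    def test_raw_above_max_saturates_at_one(self):
        raw = np.full((3, 2, 2), 100.0)
        img = normalize_and_clip(raw, 0.0, 1.0)
        np.testing.assert_allclose(img.channels, 1.0)

    def test_midpoint_maps_to_half_plus_epsilon(self):
        raw = np.full((3, 1, 1), 5.0)
        img = normalize_and_clip(raw, 0.0, 10.0, epsilon=0.01)
        np.testing.assert_allclose(img.channels, 0.51)

    def test_output_always_inside_epsilon_one(self, rng):
        raw = rng.normal(0.0, 50.0, (3, 16, 16))
        img = normalize_and_clip(raw, -1.0, 1.0)
        assert img.channels.min() >= 0.01 and img.channels.max() <= 1.0

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            normalize_and_clip(np.zeros((3, 1, 1)), 1.0, 1.0)


class TestNormalizationBounds:
    def test_constant_raw_values_give_degenerate_bounds(self):
        # constant cube + CSR rows with equal sums -> every raw value identical
        wl = np.linspace(400, 700, 20)
        cube = SpectralCube(np.full((4, 4, 20), 0.3), wl)
        csr = CameraResponse(np.full((3, 20), 0.05), wl)
        lo, hi = estimate_normalization_bounds([cube], csr)
        np.testing.assert_allclose([lo, hi], 0.3 * 0.05 * 20)

    def test_percentiles_match_sort_oracle(self, small_cube, small_csr, small_filter):
        lo, hi = estimate_normalization_bounds([small_cube], small_csr,
                                               small_filter, 0.1, 99.9)
        raw = np.sort(sense_rgb(apply_filter(small_cube, small_filter),
                                small_csr).ravel())
        assert raw[0] <= lo <= raw[2]
        assert raw[-3] <= hi <= raw[-1]
        full = estimate_normalization_bounds([small_cube], small_csr,
                                             small_filter, 0, 100)
        np.testing.assert_allclose(full, (raw[0], raw[-1]))

    def test_per_channel_mode_returns_three_bounds(self, small_cube, small_csr):
        lo, hi = estimate_normalization_bounds([small_cube], small_csr,
                                               per_channel=True)
        assert lo.shape == hi.shape == (3,)
        assert (hi > lo).all()

    def test_empty_cube_set_rejected(self, small_csr):
        with pytest.raises(ValueError):
            estimate_normalization_bounds([], small_csr)


class TestConstructionAndCsv:
    def test_default_band_grid_spans_visible_range(self):
        grid = default_band_grid()
        assert grid.size == 103 and grid[0] == 400.0 and grid[-1] == 700.0

    def test_initial_filter_is_strictly_positive_and_seeded(self):
        wl = default_band_grid(30)
        f1 = initial_filter(wl, np.random.default_rng(3))
        f2 = initial_filter(wl, np.random.default_rng(3))
        np.testing.assert_array_equal(f1.weights, f2.weights)
        assert f1.weights.min() > 0
        assert np.abs(f1.weights - 0.5).max() <= 0.05

    def test_transmittance_csv_round_trip(self, tmp_path, small_filter):
        path = tmp_path / "tr.csv"
        save_transmittance_csv(small_filter, path)
        back = load_transmittance_csv(path)
        np.testing.assert_allclose(back.weights, small_filter.weights, rtol=1e-9)
        np.testing.assert_allclose(back.wavelengths, small_filter.wavelengths)

    def test_csr_csv_interpolates_onto_band_grid(self, tmp_path):
        path = tmp_path / "csr.csv"
        path.write_text("wavelength_nm,R,G,B\n400,0,0.2,1\n700,1,0.6,0\n")
        csr = load_csr_csv(path, np.array([400.0, 550.0, 700.0]))
        np.testing.assert_allclose(csr.sensitivities[0], [0.0, 0.5, 1.0])
        np.testing.assert_allclose(csr.sensitivities[1], [0.2, 0.4, 0.6])
        np.testing.assert_allclose(csr.sensitivities[2], [1.0, 0.5, 0.0])

    def test_unit_peak_rescaling(self):
        wl = np.linspace(400, 700, 4)
        curve = TransmittanceCurve(np.array([0.1, 0.4, 0.2, 0.0]), wl)
        scaled = curve.rescaled_to_unit_peak()
        np.testing.assert_allclose(scaled.weights, [0.25, 1.0, 0.5, 0.0])

    def test_gaussian_csr_peaks_at_configured_wavelengths(self):
        wl = default_band_grid(301)
        csr = gaussian_csr(wl)
        peaks = wl[csr.sensitivities.argmax(axis=1)]
        np.testing.assert_allclose(peaks, [610, 540, 465], atol=1.0)
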