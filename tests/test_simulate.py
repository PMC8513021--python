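"""Synthetic-scene generator: spectra, geometry, noise model, determinism."""

import numpy as np
import pytest

from pepperseg.simulate import (SceneSpec, illumination_spectrum,
                                make_endmember_spectra, simulate_dataset,
                                simulate_scene)


def spec_with(**kw):
    base = dict(n_bands=30, height=32, width=32, seed=5)
    base.update(kw)
    return SceneSpec(**base)


class TestEndmemberSpectra:
    def test_zero_contrast_gives_identical_spectra(self):
        pepper, leaf = make_endmember_spectra(spec_with(contrast_delta=0.0))
        np.testing.assert_array_equal(pepper, leaf)

    def test_contrast_ratio_inside_window_only(self):
        spec = spec_with(contrast_delta=0.3, contrast_window=(630.0, 660.0))
        pepper, leaf = make_endmember_spectra(spec)
        w = spec.wavelengths
        inside = (w >= 630) & (w <= 660)
        np.testing.assert_allclose(pepper[inside] / leaf[inside], 1.3)
        np.testing.assert_allclose(pepper[~inside], leaf[~inside])

    def test_spectra_bounded_in_unit_interval(self):
        for delta in (0.0, 0.3, 1.0):
            pepper, leaf = make_endmember_spectra(spec_with(contrast_delta=delta))
            assert 0 <= leaf.min() and pepper.max() <= 1.0

    def test_contrast_pushing_reflectance_above_one_rejected(self):
        # a huge boost across the green reflectance peak exceeds 1.0
        with pytest.raises(ValueError):
            make_endmember_spectra(spec_with(contrast_delta=5.0,
                                             contrast_window=(520.0, 580.0)))

    def test_template_is_green_low_blue_with_red_dip(self):
        spec = spec_with(n_bands=301)
        _, leaf = make_endmember_spectra(spec)
        w = spec.wavelengths
        peak = w[leaf.argmax()]
        assert 520 <= peak <= 580  # green reflectance peak
        assert leaf[w <= 450].max() < leaf.max() / 2  # low blue
        # local minimum near the 650 nm chlorophyll-b absorption
        near650 = leaf[(w > 630) & (w < 670)].min()
        assert near650 < leaf[(w > 590) & (w < 610)].min()

    def test_window_outside_band_range_rejected(self):
        with pytest.raises(ValueError):
            spec_with(contrast_window=(650.0, 750.0))


class TestSimulateScene:
    def test_homogeneous_construction_without_noise_or_shading(self):
        spec = spec_with(noise_sd=0.0, shading_amp=0.0, n_shapes=(1, 1))
        cube, mask = simulate_scene(spec, np.random.default_rng(0))
        pepper_px = cube.values[mask.values == 1]
        assert pepper_px.shape[0] > 0
        assert np.abs(pepper_px - pepper_px[0]).max() == 0.0

    def test_radiance_factorization_recovers_reflectance(self):
        spec = spec_with(noise_sd=0.0)
        cube, mask, illum, shading = simulate_scene(
            spec, np.random.default_rng(1), return_components=True)
        pepper, leaf = make_endmember_spectra(spec)
        recovered = cube.values / (illum[None, None, :] * shading[:, :, None])
        expected = np.where(mask.values[:, :, None] == 1, pepper, leaf)
        np.testing.assert_allclose(recovered, expected, rtol=1e-6)

    def test_zero_contrast_classes_are_statistically_indistinguishable(self):
        # shading off so pixels are exchangeable across the class labels
        # (spatial shading correlates with ellipse placement, not class spectra)
        spec = spec_with(contrast_delta=0.0, height=48, width=48,
                         shading_amp=0.0)
        rng = np.random.default_rng(2)
        cube, mask = simulate_scene(spec, rng)
        means = cube.values.mean(axis=2)  # per-pixel band mean
        a = means[mask.values == 1].ravel()
        b = means[mask.values == 0].ravel()
        a = a[:500]
        b = b[:500]
        observed = abs(a.mean() - b.mean())
        pooled = np.concatenate([a, b])
        perm_stats = []
        for _ in range(200):
            rng.shuffle(pooled)
            perm_stats.append(abs(pooled[:a.size].mean() - pooled[a.size:].mean()))
        p_value = np.mean(np.array(perm_stats) >= observed)
        assert p_value > 0.05

    def test_pepper_fraction_within_ellipse_area_budget(self):
        spec = spec_with(height=64, width=64, n_shapes=(3, 3), axis_range=(6.0, 6.0))
        _, mask = simulate_scene(spec, np.random.default_rng(3))
        # 3 ellipses of fixed semi-axes 6 -> at most 3 * pi * 36 px (less overlap/edges)
        assert 0 < mask.values.sum() <= 3 * np.pi * 36 + 1

    def test_white_reference_patch_is_brightest_and_unlabeled(self):
        spec = spec_with(white_reference=True, noise_sd=0.0)
        cube, mask = simulate_scene(spec, np.random.default_rng(4))
        assert mask.values[:2, :2].max() == 0
        band_mean = cube.values.mean(axis=2)
        assert band_mean[:2, :2].mean() > 1.5 * band_mean[8:, 8:].mean()

    def test_cube_is_nonnegative_and_on_spec_grid(self):
        cube, _ = simulate_scene(spec_with(), np.random.default_rng(5))
        assert cube.values.min() >= 0
        assert cube.n_bands == 30 and cube.height == cube.width == 32


class TestIllumination:
    def test_spd_is_smooth_positive_and_mean_one(self):
        spd = illumination_spectrum(spec_with(n_bands=100))
        assert spd.min() > 0
        assert spd.mean() == pytest.approx(1.0)
        assert np.abs(np.diff(spd, 2)).max() < 1e-3  # no jumps

    def test_warmer_temperature_shifts_power_toward_red(self):
        spec_warm = spec_with(illum_temperature=3000)
        spec_cool = spec_with(illum_temperature=8000)
        w = spec_warm.wavelengths
        warm = illumination_spectrum(spec_warm)
        cool = illumination_spectrum(spec_cool)
        red = w > 600
        assert warm[red].sum() > cool[red].sum()


class TestSimulateDataset:
    def test_split_counts_and_shared_grid(self):
        scenes = simulate_dataset(4, 2, 2, spec_with(), seed=9)
        assert {k: len(v) for k, v in scenes.items()} == \
            {"train": 4, "val": 2, "test": 2}
        for cube, mask in scenes["train"] + scenes["val"] + scenes["test"]:
            np.testing.assert_array_equal(cube.wavelengths, spec_with().wavelengths)
            assert mask.values.shape == (32, 32)

    def test_same_seed_reproduces_identical_scenes(self):
        a = simulate_dataset(2, 1, 1, spec_with(), seed=11)
        b = simulate_dataset(2, 1, 1, spec_with(), seed=11)
        for split in a:
            for (ca, ma), (cb, mb) in zip(a[split], b[split]):
                np.testing.assert_array_equal(ca.values, cb.values)
                np.testing.assert_array_equal(ma.values, mb.values)

    def test_different_seeds_differ(self):
        a = simulate_dataset(1, 1, 1, spec_with(), seed=1)
        b = simulate_dataset(1, 1, 1, spec_with(), seed=2)
        assert not np.array_equal(a["train"][0][0].values, b["train"][0][0].values)

    def test_scenes_within_one_dataset_are_distinct(self):
        scenes = simulate_dataset(2, 1, 1, spec_with(), seed=3)
        c0, c1 = scenes["train"][0][0], scenes["train"][1][0]
        assert not np.array_equal(c0.values, c1.values)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            simulate_dataset(0, 1, 1, spec_with(), seed=0)

    def test_written_dataset_round_trips_through_disk(self, tmp_path):
        from pepperseg.io import load_dataset

        spec = spec_with()
        manifest = simulate_dataset(2, 1, 1, spec, seed=13, out_dir=tmp_path)
        assert (tmp_path / "manifest.json").exists()
        assert manifest.spec_hash == spec.hash()
        back = load_dataset(tmp_path)
        reference = simulate_dataset(2, 1, 1, spec, seed=13)
        for split in reference:
            for (cd, md), (cr, mr) in zip(back[split], reference[split]):
                # cubes are stored as float32 on disk
                np.testing.assert_allclose(cd.values, cr.values, rtol=1e-6)
                np.testing.assert_array_equal(md.values, mr.values)
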