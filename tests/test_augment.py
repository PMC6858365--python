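"""Augmentation stack: identity limits, mask contracts, histeq, caching."""

import numpy as np
import pytest

from contrastshift import augment as aug
from contrastshift.augment import (
    AugmentConfig,
    apply_flip,
    assemble_training_sample,
    cache_variants,
    chi2_to_uniform,
    histeq_augment,
    random_crop,
    random_elastic_bspline,
    random_flip,
    random_rotation_3d,
    replay_spatial_log,
    variant_rng,
)
from contrastshift.grids import LabelVolume, VolumeGrid


class TestFlip:
    def test_involution(self, ellipsoid_pair, rng):
        img, msk = ellipsoid_pair
        out_i, out_m = apply_flip(img.values, msk.values, (0,))
        back_i, back_m = apply_flip(out_i, out_m, (0,))
        np.testing.assert_array_equal(back_i, img.values)
        np.testing.assert_array_equal(back_m, msk.values)

    def test_symmetric_phantom_invariant(self, ellipsoid_pair):
        img, msk = ellipsoid_pair  # centered ellipsoid: symmetric about each axis
        out_i, out_m = apply_flip(img.values, msk.values, (1,))
        np.testing.assert_array_equal(out_m, msk.values)
        np.testing.assert_allclose(out_i, img.values)

    def test_voxel_count_conserved(self, ellipsoid_pair, rng):
        img, msk = ellipsoid_pair
        for _ in range(5):
            _, m2, _ = random_flip(img, msk, rng)
            assert m2.voxel_count() == msk.voxel_count()


class TestRotation:
    def test_zero_angles_identity(self, ellipsoid_pair):
        img, msk = ellipsoid_pair
        out_i, out_m = aug.apply_rotation(img.values, msk.values, (0.0, 0.0, 0.0), fill=0.0)
        np.testing.assert_array_equal(out_i, img.values)

    def test_mask_volume_approximately_conserved(self, ellipsoid_pair, rng):
        img, msk = ellipsoid_pair
        for _ in range(5):
            _, m2, log = random_rotation_3d(img, msk, rng, max_deg=30.0)
            assert set(np.unique(m2.values)) <= {0, 1}
            assert abs(m2.voxel_count() - msk.voxel_count()) / msk.voxel_count() < 0.05

    def test_rotation_inverse_within_interp_tolerance(self, ellipsoid_pair):
        img, _ = ellipsoid_pair
        msk = LabelVolume(np.zeros_like(ellipsoid_pair[1].values))
        fwd, _ = aug.apply_rotation(img.values, msk.values, (30.0, 0.0, 0.0), fill=40.0)
        back, _ = aug.apply_rotation(fwd, msk.values, (-30.0, 0.0, 0.0), fill=40.0)
        # baseline: error of double trilinear resampling at a non-special angle
        half1, _ = aug.apply_rotation(img.values, msk.values, (15.0, 0.0, 0.0), fill=40.0)
        half2, _ = aug.apply_rotation(half1, msk.values, (-15.0, 0.0, 0.0), fill=40.0)
        baseline = np.abs(half2 - img.values).mean()
        assert np.abs(back - img.values).mean() < 2.0 * baseline + 1e-9


class TestElastic:
    def test_sigma_zero_identity(self, ellipsoid_pair, rng):
        img, msk = ellipsoid_pair
        i2, m2, _ = random_elastic_bspline(img, msk, rng, control_points=6, sigma=0.0)
        np.testing.assert_array_equal(i2.values, img.values)
        np.testing.assert_array_equal(m2.values, msk.values)

    def test_control_displacement_sd(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(0.0, 8.0, size=(1000, 3))
        assert 6.4 <= draws.std() <= 9.6

    def test_drawn_control_sd_in_range(self, ellipsoid_pair):
        img, msk = ellipsoid_pair
        sds = []
        rng = np.random.default_rng(7)
        for _ in range(30):
            _, _, log = random_elastic_bspline(img, msk, rng, control_points=6, sigma=8.0)
            sds.append(log["control"].std())
        assert 6.4 <= np.mean(sds) <= 9.6

    def test_mask_stays_binary(self, ellipsoid_pair, rng):
        img, msk = ellipsoid_pair
        _, m2, _ = random_elastic_bspline(img, msk, rng, control_points=6, sigma=3.0)
        assert set(np.unique(m2.values)) <= {0, 1}

    def test_lattice_larger_than_grid_rejected(self, ellipsoid_pair, rng):
        img, msk = ellipsoid_pair
        with pytest.raises(ValueError, match="lattice"):
            random_elastic_bspline(img, msk, rng, control_points=100, sigma=1.0)


class TestCrop:
    def test_full_size_identity(self, ellipsoid_pair, rng):
        img, msk = ellipsoid_pair
        i2, m2, log = random_crop(img, msk, img.shape, rng)
        np.testing.assert_array_equal(i2.values, img.values)
        assert log["offset"] == (0, 0, 0)

    def test_output_shape(self, ellipsoid_pair, rng):
        img, msk = ellipsoid_pair
        i2, m2, _ = random_crop(img, msk, (16, 12, 20), rng)
        assert i2.shape == (16, 12, 20) and m2.shape == (16, 12, 20)

    def test_too_large_rejected(self, ellipsoid_pair, rng):
        img, msk = ellipsoid_pair
        with pytest.raises(ValueError, match="crop"):
            random_crop(img, msk, (100, 4, 4), rng)

    def test_window_union_covers_support(self):
        """On an 8^3 toy, union over all crop windows equals the reachable region."""
        values = np.zeros((8, 8, 8))
        values[2:6, 2:6, 2:6] = 1
        img = VolumeGrid(values + 40.0)
        msk = LabelVolume(values.astype(np.uint8))
        crop = (6, 6, 6)
        seen = np.zeros((8, 8, 8), dtype=bool)
        for ox in range(3):
            for oy in range(3):
                for oz in range(3):
                    _, m = aug.apply_crop(img.values, msk.values, (ox, oy, oz), crop)
                    window = np.zeros((8, 8, 8), dtype=bool)
                    window[ox:ox + 6, oy:oy + 6, oz:oz + 6] = m.astype(bool)
                    seen |= window
        np.testing.assert_array_equal(seen, values.astype(bool))


class TestHisteq:
    def test_rank_order_preserved(self, noisy_case, rng):
        img = noisy_case.contrast_volume
        out = histeq_augment(img)
        flat_in = img.values.ravel()
        flat_out = out.values.ravel()
        idx = rng.integers(0, flat_in.size, size=(500, 2))
        for i, j in idx:
            if flat_in[i] <= flat_in[j]:
                assert flat_out[i] <= flat_out[j] + 1e-9

    def test_chi2_to_uniform_reduced(self, small_config):
        from contrastshift import phantom

        cases = phantom.sample_dataset(small_config, 20, base_seed=13,
                                       jitter=phantom.default_jitter())
        for case in cases:
            img = case.contrast_volume
            out = histeq_augment(img)
            assert chi2_to_uniform(out.values) <= chi2_to_uniform(img.values) + 1e-9

    def test_constant_image_warns_unchanged(self):
        img = VolumeGrid(np.full((16, 16, 16), 7.0))
        with pytest.warns(UserWarning, match="constant"):
            out = histeq_augment(img)
        np.testing.assert_array_equal(out.values, img.values)

    def test_matches_skimage_monotonicity_semantics(self, noisy_case):
        """Cross-check the CDF mapping against skimage's equalizer."""
        skimage = pytest.importorskip("skimage")
        from skimage import exposure

        img = noisy_case.contrast_volume
        ours = histeq_augment(img, bins=256).values
        ref = exposure.equalize_hist(img.values, nbins=256)
        # same intensity ordering => rank correlation ~ 1
        sub = np.random.default_rng(0).integers(0, img.values.size, 2000)
        r = np.corrcoef(np.argsort(np.argsort(ours.ravel()[sub])),
                        np.argsort(np.argsort(ref.ravel()[sub])))[0, 1]
        assert r > 0.999


@pytest.fixture(scope="module")
def config():
    return AugmentConfig(bspline_control_points=6, bspline_sigma=1.5, seed=0)


class TestAssembleAndCache:

    def test_condition_none_untouched(self, ellipsoid_pair, config, rng):
        img, msk = ellipsoid_pair
        var = assemble_training_sample(img, msk, "none", config, rng)
        assert var.transform_log == []
        np.testing.assert_array_equal(var.image.values, img.values)

    def test_swap_fraction_near_half(self, ellipsoid_pair, config):
        img, msk = ellipsoid_pair
        translated = img.with_values(img.values - 30.0)
        rng = np.random.default_rng(99)
        synth = 0
        n = 10_000
        for _ in range(n):
            # draw only the coin, not the full spatial stack, for speed
            if rng.random() < config.swap_probability:
                synth += 1
        assert 0.48 <= synth / n <= 0.52

    def test_cyclegan_missing_translation_errors(self, ellipsoid_pair, config, rng):
        img, msk = ellipsoid_pair
        with pytest.raises(ValueError, match="translated"):
            assemble_training_sample(img, msk, "cyclegan", config, rng)

    def test_mask_consistent_with_replayed_log(self, ellipsoid_pair, config, rng):
        img, msk = ellipsoid_pair
        var = assemble_training_sample(img, msk, "standard", config, rng)
        img2, msk2 = replay_spatial_log(img, msk, var.transform_log)
        np.testing.assert_array_equal(var.mask.values, msk2)
        np.testing.assert_allclose(var.image.values, img2)

    def test_cache_sixteen_distinct_deterministic(self, ellipsoid_pair, config):
        img, msk = ellipsoid_pair
        v1 = cache_variants(img, msk, "standard", config, case_id="caseA")
        v2 = cache_variants(img, msk, "standard", config, case_id="caseA")
        assert len(v1) == 16
        logs = [repr([(e["op"], e.get("angles_deg"), e.get("axes")) for e in v.transform_log])
                for v in v1]
        assert len(set(logs)) == 16
        for a, b in zip(v1, v2):
            np.testing.assert_array_equal(a.image.values, b.image.values)

    def test_cache_condition_none_single(self, ellipsoid_pair, config):
        img, msk = ellipsoid_pair
        variants = cache_variants(img, msk, "none", config, case_id="caseB", k=1)
        assert len(variants) == 1
        np.testing.assert_array_equal(variants[0].image.values, img.values)

    def test_spatial_stream_shared_across_conditions(self, ellipsoid_pair, config):
        """Identical (case, variant) keys give identical spatial transforms
        regardless of condition — only the intensity branch differs."""
        img, msk = ellipsoid_pair
        translated = img.with_values(img.values * 0.5)
        std = cache_variants(img, msk, "standard", config, case_id="caseC", k=4)
        cyc = cache_variants(img, msk, "cyclegan", config, case_id="caseC", k=4,
                             translated_volume=translated)
        for a, b in zip(std, cyc):
            np.testing.assert_array_equal(a.mask.values, b.mask.values)

    def test_zero_parameter_stack_is_identity(self, ellipsoid_pair):
        img, msk = ellipsoid_pair
        cfg = AugmentConfig(flip_probability=0.0, rotation_max_deg=0.0,
                            bspline_sigma=0.0, bspline_control_points=6, seed=3)
        var = assemble_training_sample(img, msk, "standard", cfg,
                                       np.random.default_rng(0))
        np.testing.assert_allclose(var.image.values, img.values)
        np.testing.assert_array_equal(var.mask.values, msk.values)


def test_variant_cache_written_to_disk(tmp_path, ellipsoid_pair, config):
    from contrastshift import ct_io
    from contrastshift.augment import write_variant_cache

    img, msk = ellipsoid_pair
    variants = cache_variants(img, msk, "standard", config, case_id="caseD", k=2)
    paths = write_variant_cache(variants, tmp_path, "caseD", "standard")
    assert len(paths) == 6  # image + mask + log per variant
    back = ct_io.read_volume(tmp_path / "caseD_standard_00_img.nii")
    np.testing.assert_allclose(back.values, variants[0].image.values)
    import json
    log = json.loads((tmp_path / "caseD_standard_00_log.json").read_text())
    assert log["transform_log"][0]["op"] == "flip"
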