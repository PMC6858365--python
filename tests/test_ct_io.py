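"""I/O round trips, HU preprocessing, fat-noise estimation, curation gates."""

import numpy as np
import pytest

from contrastshift import ct_io, phantom
from contrastshift.ct_io import CurationRecord, curate_translator_pools
from contrastshift.grids import HU, NORMALIZED, VolumeGrid


class TestNiftiIO:
    def test_roundtrip_bit_exact(self, tmp_path, noisy_case):
        p = tmp_path / "vol.nii"
        ct_io.write_volume(noisy_case.contrast_volume, p)
        back = ct_io.read_volume(p)
        np.testing.assert_array_equal(back.values, noisy_case.contrast_volume.values)

    def test_anisotropic_spacing_preserved(self, tmp_path):
        grid = VolumeGrid(np.zeros((8, 8, 8)) + 1.0, (1.0, 1.0, 3.0), HU)
        ct_io.write_volume(grid, tmp_path / "a.nii")
        back = ct_io.read_volume(tmp_path / "a.nii")
        assert back.spacing_mm == pytest.approx((1.0, 1.0, 3.0))

    def test_non_3d_rejected(self, tmp_path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4, 2)), np.eye(4)), str(tmp_path / "b.nii"))
        with pytest.raises(ValueError, match="3D"):
            ct_io.read_volume(tmp_path / "b.nii")


class TestPreprocessing:
    @pytest.mark.parametrize("value,expected", [(500.0, 300.0), (-350.0, -200.0), (40.0, 40.0)])
    def test_clip_values(self, value, expected):
        grid = VolumeGrid(np.full((16, 16, 16), value), intensity_kind=HU)
        assert ct_io.clip_hu(grid).values[0, 0, 0] == expected

    def test_clip_requires_hu(self, noisy_case):
        norm = ct_io.preprocess(noisy_case.contrast_volume)
        with pytest.raises(ValueError):
            ct_io.clip_hu(norm)

    def test_normalize_contract(self, noisy_case):
        out = ct_io.preprocess(noisy_case.contrast_volume)
        assert abs(out.values.mean()) < 1e-6
        assert abs(out.values.std() - 1.0) < 1e-6
        assert out.intensity_kind == NORMALIZED

    def test_affine_invariance(self, noisy_case):
        base = ct_io.clip_hu(noisy_case.contrast_volume)
        a = ct_io.normalize_zmuv(base)
        scaled = base.with_values(base.values * 2.5 + 17.0)
        b = ct_io.normalize_zmuv(scaled)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_normalize_idempotent(self, noisy_case):
        once = ct_io.preprocess(noisy_case.contrast_volume)
        twice = ct_io.normalize_zmuv(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-6)

    def test_constant_volume_rejected(self):
        grid = VolumeGrid(np.zeros((16, 16, 16)), intensity_kind=HU)
        with pytest.raises(ValueError, match="constant"):
            ct_io.normalize_zmuv(grid)


class TestFatNoise:
    def test_recovers_noise_sd(self, small_config):
        case = phantom.make_phantom(small_config, case_seed=9)
        est = ct_io.estimate_fat_noise(case.noncontrast_volume)
        assert 8.0 <= est <= 12.0

    def test_noise_free_is_zero(self, noisefree_case):
        assert ct_io.estimate_fat_noise(noisefree_case.noncontrast_volume) == 0.0

    def test_no_fat_errors(self):
        grid = VolumeGrid(np.full((16, 16, 16), 40.0), intensity_kind=HU)
        with pytest.raises(ValueError, match="voxels"):
            ct_io.estimate_fat_noise(grid)

    def test_invariant_to_outside_window(self, small_config):
        case = phantom.make_phantom(small_config, case_seed=9)
        est1 = ct_io.estimate_fat_noise(case.noncontrast_volume)
        shifted = case.noncontrast_volume.values.copy()
        shifted[shifted > 0] += 500.0  # perturb only non-fat voxels
        est2 = ct_io.estimate_fat_noise(case.noncontrast_volume.with_values(shifted))
        assert est1 == pytest.approx(est2)


class TestCuration:
    def test_hand_filtered_pools(self):
        recs = [
            CurationRecord("scan1", 0.9, 5.0),
            CurationRecord("scan2", 0.5, 5.0),
            CurationRecord("scan3", 0.1, 5.0),
        ]
        pool_c, pool_n = curate_translator_pools(recs)
        assert [r.scan_id for r in pool_c] == ["scan1"]
        assert [r.scan_id for r in pool_n] == ["scan3"]
        assert recs[1].accepted_as == "rejected"

    @pytest.mark.parametrize(
        "prob,noise,expected",
        [
            (0.8, 5.0, "rejected"),    # boundary: strict inequality
            (0.2, 5.0, "rejected"),
            (0.1, 20.0, "rejected"),   # noisy non-contrast gated out
            (0.1, 15.0, "rejected"),   # noise boundary is strict too
            (0.81, 99.0, "contrast"),  # noise gate only applies to non-contrast
            (0.19, 14.9, "noncontrast"),
        ],
    )
    def test_gate_edges(self, prob, noise, expected):
        recs = [
            CurationRecord("edge", prob, noise),
            CurationRecord("anchor_c", 0.95, 5.0),
            CurationRecord("anchor_n", 0.05, 5.0),
        ]
        curate_translator_pools(recs)
        assert recs[0].accepted_as == expected

    def test_order_independent(self, rng):
        recs = [CurationRecord(f"s{i}", float(p), float(n))
                for i, (p, n) in enumerate(zip(rng.random(30), rng.random(30) * 30))]
        curate_translator_pools(recs)
        labels = {r.scan_id: r.accepted_as for r in recs}
        shuffled = [recs[i] for i in rng.permutation(30)]
        for r in shuffled:
            r.accepted_as = "pending"
        curate_translator_pools(shuffled)
        assert {r.scan_id: r.accepted_as for r in shuffled} == labels

    def test_empty_pool_errors(self):
        recs = [CurationRecord("a", 0.5, 5.0), CurationRecord("b", 0.9, 5.0)]
        with pytest.raises(ValueError, match="empty pool"):
            curate_translator_pools(recs)


@pytest.fixture(scope="module")
def volumes(small_config):
    cases = phantom.sample_dataset(small_config, 40, base_seed=21,
                                   jitter=phantom.default_jitter())
    labeled = [(c.contrast_volume, "contrast") for c in cases[:20]]
    labeled += [(c.noncontrast_volume, "noncontrast") for c in cases[:20]]
    held = [(c.contrast_volume, 1) for c in cases[20:]]
    held += [(c.noncontrast_volume, 0) for c in cases[20:]]
    return labeled, held


class TestContrastClassifier:

    def test_accuracy_on_held_out(self, volumes):
        labeled, held = volumes
        clf = ct_io.train_contrast_classifier(labeled)
        probs = [clf.contrast_probability(v) for v, _ in held]
        preds = [int(p > 0.5) for p in probs]
        acc = np.mean([p == y for p, (_, y) in zip(preds, held)])
        assert acc >= 0.95
        assert all(0.0 <= p <= 1.0 for p in probs)

    def test_single_class_rejected(self, volumes):
        labeled, _ = volumes
        contrast_only = [lv for lv in labeled if lv[1] == "contrast"]
        with pytest.raises(ValueError):
            ct_io.train_contrast_classifier(contrast_only)

    def test_no_signal_when_domains_identical(self, noisefree_config):
        import dataclasses

        organs = [dataclasses.replace(o, enhancement_hu=0.0) for o in noisefree_config.organs]
        cfg = dataclasses.replace(noisefree_config, organs=organs, noise_sd_hu=10.0)
        cases = phantom.sample_dataset(cfg, 30, base_seed=4, jitter=phantom.default_jitter())
        labeled = [(c.contrast_volume, "contrast") for c in cases[:15]]
        labeled += [(c.noncontrast_volume, "noncontrast") for c in cases[:15]]
        clf = ct_io.train_contrast_classifier(labeled)
        held = [(c.contrast_volume, 1) for c in cases[15:]] + \
               [(c.noncontrast_volume, 0) for c in cases[15:]]
        acc = np.mean([int(clf.contrast_probability(v) > 0.5) == y for v, y in held])
        assert 0.2 <= acc <= 0.8
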