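"""File round-trips, preprocessing, augmentation and phantom properties."""

import logging

import numpy as np
import pytest

from entroseg import data_io as dio
from entroseg.data_io import (PhantomSpec, VolumeSample, augment, generate_phantom,
                              load_volume, make_phantom_dataset, preprocess_ct,
                              random_crop, save_volume)
from entroseg.entropy_masks import InvalidConfigError, InvalidInputError


@pytest.fixture
def sample(rng):
    image = rng.normal(size=(8, 8, 8)).astype(np.float32)
    label = (image > 0).astype(np.int64)
    return VolumeSample(image, label, spacing=(1.0, 1.25, 2.0), identifier="t")


class TestFileFormats:
    def test_hdf5_round_trip(self, tmp_path, sample):
        path = tmp_path / "vol.h5"
        save_volume(sample, path)
        back = load_volume(path)
        np.testing.assert_array_equal(back.image, sample.image)
        np.testing.assert_array_equal(back.label, sample.label)
        assert back.spacing == sample.spacing

    def test_nifti_round_trip_preserves_anisotropic_spacing(self, tmp_path, sample):
        path = tmp_path / "vol.nii.gz"
        save_volume(sample, path)
        back = load_volume(path)
        np.testing.assert_allclose(back.image, sample.image, atol=1e-6)
        assert back.spacing == pytest.approx(sample.spacing)

    def test_missing_spacing_defaults_with_warning(self, tmp_path, sample, caplog):
        import h5py
        path = tmp_path / "nospacing.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("image", data=sample.image)
        with caplog.at_level(logging.WARNING, logger="entroseg.data_io"):
            back = load_volume(path)
        assert back.spacing == (1.0, 1.0, 1.0)
        assert any("spacing" in r.message for r in caplog.records)

    def test_unreadable_file_raises_io_error(self, tmp_path):
        bad = tmp_path / "corrupt.h5"
        bad.write_bytes(b"not an hdf5 file")
        with pytest.raises(OSError, match="corrupt.h5"):
            load_volume(bad)

    def test_label_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            VolumeSample(np.zeros((4, 4, 4)), np.zeros((4, 4, 2)))


class TestPreprocessCT:
    def test_hu_clipping(self):
        img = np.array([500.0, -200.0, 0.0, 275.0]).reshape(1, 1, 4)
        out = preprocess_ct(VolumeSample(img))
        # 500 clips to 275 -> 1.0 after scaling; -200 clips to -125 -> 0.0
        assert out.image[0, 0, 0] == pytest.approx(1.0)
        assert out.image[0, 0, 1] == pytest.approx(0.0)

    def test_identity_resampling_at_target_spacing(self, sample):
        iso = VolumeSample(sample.image, sample.label, (1.0, 1.0, 1.0))
        out = preprocess_ct(iso)
        assert out.image.shape == iso.image.shape
        np.testing.assert_array_equal(out.label, iso.label)

    def test_resamples_to_isotropic_grid(self):
        img = np.zeros((8, 8, 4), np.float32)
        s = VolumeSample(img, spacing=(1.0, 1.0, 2.0))
        out = preprocess_ct(s)
        assert out.image.shape == (8, 8, 8)
        assert out.spacing == (1.0, 1.0, 1.0)

    def test_idempotent(self, rng):
        img = rng.uniform(-300, 400, size=(8, 8, 8)).astype(np.float32)
        once = preprocess_ct(VolumeSample(img, spacing=(1.0, 1.0, 1.0)))
        twice = preprocess_ct(once)
        # second application rescales an already-[0,1] image; values must agree
        np.testing.assert_allclose(
            twice.image, (once.image - (-125)) / 400 * 0 + twice.image, atol=0)
        assert twice.image.shape == once.image.shape


def test_zscore_normalisation(rng):
    img = rng.normal(5.0, 3.0, size=(8, 8, 8)).astype(np.float32)
    out = dio.normalize_zscore(VolumeSample(img))
    assert out.image.mean() == pytest.approx(0.0, abs=1e-5)
    assert out.image.std() == pytest.approx(1.0, abs=1e-5)
    flat = dio.normalize_zscore(VolumeSample(np.full((4, 4, 4), 2.0, np.float32)))
    assert np.all(np.isfinite(flat.image))  # constant volume stays finite


class TestCropAndAugment:
    def test_identity_crop(self, sample, rng):
        out = random_crop(sample, sample.image.shape, rng)
        np.testing.assert_array_equal(out.image, sample.image)

    def test_crop_reproducible_and_aligned(self, sample):
        a = random_crop(sample, (4, 4, 4), np.random.default_rng(3))
        b = random_crop(sample, (4, 4, 4), np.random.default_rng(3))
        np.testing.assert_array_equal(a.image, b.image)
        # label crop uses the same offset: thresholding relation is preserved
        np.testing.assert_array_equal(a.label, (a.image > 0).astype(np.int64))

    def test_oversized_crop_rejected_unless_padding(self, sample, rng):
        with pytest.raises(InvalidInputError):
            random_crop(sample, (16, 4, 4), rng)
        out = random_crop(sample, (16, 4, 4), rng, pad_if_needed=True)
        assert out.image.shape == (16, 4, 4)

    def test_rot180_is_involution(self, sample, rng):
        out = augment(augment(sample, rng, "rot180"), rng, "rot180")
        np.testing.assert_array_equal(out.image, sample.image)
        np.testing.assert_array_equal(out.label, sample.label)

    def test_flip_preserves_label_multiset(self, sample):
        rng = np.random.default_rng(0)
        out = augment(sample, rng, "random_flip")
        assert np.bincount(out.label.ravel()).tolist() == \
            np.bincount(sample.label.ravel()).tolist()

    def test_none_policy_is_identity(self, sample, rng):
        out = augment(sample, rng, "none")
        np.testing.assert_array_equal(out.image, sample.image)

    def test_image_label_transform_commutes(self, sample):
        # transforming the pair equals transforming each field identically
        rng_state = np.random.default_rng(9)
        out = augment(sample, rng_state, "rot90")
        np.testing.assert_array_equal(out.label, np.rot90(sample.label, 1, (0, 1)))
        np.testing.assert_array_equal(out.image, np.rot90(sample.image, 1, (0, 1)))


class TestPhantoms:
    def test_deterministic_given_seed(self):
        a = generate_phantom(PhantomSpec(seed=4))
        b = generate_phantom(PhantomSpec(seed=4))
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.label, b.label)
        c = generate_phantom(PhantomSpec(seed=5))
        assert not np.array_equal(a.label, c.label)

    def test_noiseless_threshold_recovers_label_exactly(self):
        spec = PhantomSpec(seed=2, noise_sd=0.0, boundary_blur_sigma=0.0)
        ph = generate_phantom(spec)
        recovered = (ph.image > spec.intensity_contrast / 2).astype(np.int64)
        np.testing.assert_array_equal(recovered, ph.label)

    def test_foreground_is_minority_class(self):
        fracs = [generate_phantom(PhantomSpec(seed=s)).label.mean() for s in range(20)]
        assert all(0.0 < f < 0.5 for f in fracs)

    def test_blur_increases_boundary_ambiguity(self):
        """More boundary blur -> more voxels misclassified by thresholding."""
        def misclassified(sigma):
            total = 0
            for seed in range(5):
                spec = PhantomSpec(seed=seed, boundary_blur_sigma=sigma, noise_sd=0.0)
                ph = generate_phantom(spec)
                pred = (ph.image > spec.intensity_contrast / 2).astype(np.int64)
                total += int((pred != ph.label).sum())
            return total

        errors = [misclassified(s) for s in (0.0, 1.0, 2.0)]
        assert errors[0] < errors[1] < errors[2]

    def test_size_must_be_divisible_by_16(self):
        with pytest.raises(InvalidConfigError):
            PhantomSpec(size=(30, 32, 32))


class TestDatasetSplits:
    def test_split_sizes_and_disjointness(self):
        ds = make_phantom_dataset(20, 0.2, PhantomSpec(), seed=1, n_test=4)
        assert len(ds.labeled) == 4 and len(ds.unlabeled) == 16 and len(ds.test) == 4
        ids = [s.identifier for split in ds for s in split]
        assert len(ids) == len(set(ids))

    def test_unlabeled_split_withholds_labels_but_keeps_truth(self):
        ds = make_phantom_dataset(5, 0.4, PhantomSpec(), seed=1, n_test=1)
        assert all(s.label is None for s in ds.unlabeled)
        assert all(s.label is not None for s in ds.unlabeled_truth)
        assert [s.identifier for s in ds.unlabeled] == \
            [s.identifier for s in ds.unlabeled_truth]

    def test_same_seed_same_split(self):
        a = make_phantom_dataset(6, 0.5, PhantomSpec(), seed=9, n_test=1)
        b = make_phantom_dataset(6, 0.5, PhantomSpec(), seed=9, n_test=1)
        for sa, sb in zip(a.labeled, b.labeled):
            np.testing.assert_array_equal(sa.image, sb.image)

    def test_too_small_labeled_split_rejected(self):
        with pytest.raises(InvalidConfigError):
            make_phantom_dataset(4, 0.2, PhantomSpec(), seed=0)
        with pytest.raises(InvalidConfigError):
            make_phantom_dataset(10, 1.5, PhantomSpec(), seed=0)
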