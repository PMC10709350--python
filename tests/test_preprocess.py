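"""NIfTI IO, resampling, resizing, and leakage-safe standardization."""

import nibabel as nib
import numpy as np
import pytest

from flairmatch.preprocess import (
    VolumePair,
    VolumeStandardizer,
    apply_standardizer,
    coregister_resample,
    fit_standardizer,
    load_cohort_csv,
    load_pair,
    resize_to_grid,
)

RNG = np.random.default_rng(17)


def _write(tmp_path, name, data, affine=None):
    path = tmp_path / name
    nib.save(nib.Nifti1Image(np.asarray(data, np.float32),
                             np.eye(4) if affine is None else affine), path)
    return path


class TestLoadPair:
    def test_roundtrip_exact(self, tmp_path):
        dwi = RNG.normal(size=(8, 8, 4)).astype(np.float32)
        flair = RNG.normal(size=(8, 8, 4)).astype(np.float32)
        pair = load_pair(_write(tmp_path, "d.nii.gz", dwi),
                         _write(tmp_path, "f.nii.gz", flair), patient_id="p1")
        np.testing.assert_allclose(pair.dwi, dwi, rtol=1e-6)
        np.testing.assert_allclose(pair.flair, flair, rtol=1e-6)
        assert pair.patient_id == "p1"

    def test_mismatched_grids_accepted_at_load(self, tmp_path):
        pair = load_pair(_write(tmp_path, "d.nii.gz", np.zeros((8, 8, 4))),
                         _write(tmp_path, "f.nii.gz", np.zeros((6, 6, 3))))
        assert pair.dwi.shape != pair.flair.shape

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_pair(tmp_path / "absent.nii.gz", tmp_path / "absent2.nii.gz")

    def test_4d_image_rejected(self, tmp_path):
        p4 = _write(tmp_path, "x.nii.gz", np.zeros((4, 4, 2, 3)))
        p3 = _write(tmp_path, "y.nii.gz", np.zeros((4, 4, 2)))
        with pytest.raises(ValueError, match="3D"):
            load_pair(p4, p3)

    def test_unreadable_header(self, tmp_path):
        bad = tmp_path / "bad.nii"
        bad.write_bytes(b"not a nifti file at all")
        good = _write(tmp_path, "g.nii.gz", np.zeros((4, 4, 2)))
        with pytest.raises(ValueError, match="header"):
            load_pair(bad, good)


class TestCoregisterResample:
    def test_identity_backend_passthrough(self):
        pair = VolumePair(dwi=np.ones((4, 4, 2)), flair=np.ones((4, 4, 2)),
                          spacing=(1, 1, 1))
        assert coregister_resample(pair, "identity") is pair

    def test_identity_backend_rejects_mismatch(self):
        pair = VolumePair(dwi=np.ones((4, 4, 2)), flair=np.ones((6, 6, 2)),
                          spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="matching grids"):
            coregister_resample(pair, "identity")

    def test_coarse_flair_resampled_to_dwi_grid(self, tmp_path):
        dwi = RNG.normal(size=(8, 8, 4)).astype(np.float32)
        flair = RNG.normal(size=(4, 4, 2)).astype(np.float32)
        # FLAIR voxels twice as large => same physical extent
        pair = load_pair(_write(tmp_path, "d.nii.gz", dwi),
                         _write(tmp_path, "f.nii.gz", flair, np.diag([2, 2, 2, 1])))
        out = coregister_resample(pair, "rigid-resample")
        assert out.flair.shape == dwi.shape

    def test_constant_image_stays_constant(self, tmp_path):
        dwi = np.zeros((6, 6, 3), np.float32)
        flair = np.full((6, 6, 3), 3.5, np.float32)
        pair = load_pair(_write(tmp_path, "d.nii.gz", dwi),
                         _write(tmp_path, "f.nii.gz", flair))
        out = coregister_resample(pair, "rigid-resample")
        np.testing.assert_allclose(out.flair, 3.5, rtol=1e-6)

    def test_unknown_backend(self):
        pair = VolumePair(dwi=np.ones((2, 2, 2)), flair=np.ones((2, 2, 2)),
                          spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="backend"):
            coregister_resample(pair, "deformable")


class TestResize:
    def test_noop_when_already_on_target(self):
        pair = VolumePair(dwi=RNG.normal(size=(8, 8, 4)),
                          flair=RNG.normal(size=(8, 8, 4)), spacing=(1, 1, 1))
        out = resize_to_grid(pair, (8, 8, 4))
        np.testing.assert_array_equal(out.dwi, pair.dwi)

    def test_default_target_is_clinical_grid(self):
        import inspect
        sig = inspect.signature(resize_to_grid)
        assert sig.parameters["target"].default == (192, 192, 50)

    def test_shapes_and_constant_preserved(self):
        pair = VolumePair(dwi=np.full((10, 10, 6), 2.0),
                          flair=np.full((10, 10, 6), -1.0), spacing=(2, 2, 2))
        out = resize_to_grid(pair, (16, 16, 8))
        assert out.dwi.shape == (16, 16, 8)
        np.testing.assert_allclose(out.dwi, 2.0, rtol=1e-6)
        np.testing.assert_allclose(out.flair, -1.0, rtol=1e-6)
        # spacing shrinks as the grid grows
        assert out.spacing[0] < pair.spacing[0]


class TestStandardization:
    def test_training_set_becomes_zero_mean_unit_std(self):
        X = RNG.normal(3.0, 2.0, size=(6, 2, 8, 8, 4)).astype(np.float32)
        stats = fit_standardizer(list(X))
        Z = apply_standardizer(X, stats)
        for c in range(2):
            assert abs(Z[:, c].mean()) < 1e-5
            assert abs(Z[:, c].std() - 1.0) < 1e-5

    def test_test_set_keeps_its_shift(self):
        """Applying training stats must NOT recenter shifted test data — the
        leakage guard."""
        Xtr = RNG.normal(0, 1, size=(5, 2, 8, 8, 4)).astype(np.float32)
        Xte = Xtr + 2.0
        stats = fit_standardizer(list(Xtr))
        Zte = apply_standardizer(Xte, stats)
        assert Zte.mean() > 1.5

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_standardizer([np.zeros((2, 4, 4, 2))])

    def test_per_channel_vs_joint_differ_on_anisotropic_scales(self):
        """DWI and FLAIR on different scales: per-channel and joint stats
        disagree (checked against direct recomputation)."""
        X = np.stack([np.stack([RNG.normal(0, 1, (6, 6, 3)),
                                RNG.normal(10, 5, (6, 6, 3))]) for _ in range(4)])
        per = fit_standardizer(list(X), per_channel=True)
        joint = fit_standardizer(list(X), per_channel=False)
        np.testing.assert_allclose(per.mean, X.mean(axis=(0, 2, 3, 4)), rtol=1e-6)
        np.testing.assert_allclose(joint.mean, np.full(2, X.mean()), rtol=1e-6)
        assert not np.allclose(per.mean, joint.mean)
        assert not np.allclose(per.std, joint.std)

    def test_transformer_interface(self):
        X = RNG.normal(2.0, 3.0, size=(4, 2, 6, 6, 4)).astype(np.float32)
        std = VolumeStandardizer().fit(X)
        Z = std.transform(X)
        assert abs(Z.mean()) < 1e-5
        with pytest.raises(RuntimeError):
            VolumeStandardizer().transform(X)


def test_load_cohort_csv_roundtrip(tmp_path):
    from flairmatch.synthetic import PhantomConfig, generate_cohort

    cfg = PhantomConfig(shape=(16, 16, 8), n_labeled=3, n_unlabeled=1,
                        lesion_radius_xy=(3.0, 4.0), lesion_radius_z=(1.5, 2.5), seed=2)
    cohort = generate_cohort(cfg, out_dir=tmp_path)
    X, table = load_cohort_csv(tmp_path / "cohort.csv")
    assert X.shape == (4, 2, 16, 16, 8)
    np.testing.assert_allclose(X, cohort.volumes, rtol=1e-5)
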