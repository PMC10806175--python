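import numpy as np
import pytest
from scipy import stats

from radcrt.preprocess import (
    CTVolume,
    EmptyMaskError,
    GridMismatchError,
    VOIMask,
    crop_to_voi,
    quantize,
    read_case,
    resample_isotropic,
    write_case,
)

from conftest import make_mask, make_volume


def _ball(n=20, r=7, spacing=(1.0, 1.0, 1.0)):
    c = (n - 1) / 2
    zz, yy, xx = np.meshgrid(*([np.arange(n)] * 3), indexing="ij")
    return make_mask(((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= r ** 2,
                     spacing)


class TestReadCase:
    def test_write_read_roundtrip_preserves_grid(self, tmp_path, rng):
        vol = make_volume(rng.normal(0, 50, (8, 10, 12)), spacing=(2.5, 0.976, 0.976))
        flags = np.zeros((8, 10, 12), dtype=np.uint8)
        flags[2:6, 3:8, 4:9] = 1
        mask = VOIMask(flags, vol.spacing)
        write_case(tmp_path / "i.nii.gz", vol, tmp_path / "m.nii.gz", mask)
        v2, m2 = read_case(tmp_path / "i.nii.gz", tmp_path / "m.nii.gz")
        assert v2.shape == vol.shape
        assert np.allclose(v2.spacing, vol.spacing, atol=1e-4)
        assert np.array_equal(m2.flags, mask.flags)
        assert np.allclose(v2.values, vol.values, atol=1e-3)  # float32 on disk

    def test_all_zero_mask_raises(self, tmp_path):
        vol = make_volume(np.zeros((5, 5, 5)))
        flags = np.zeros((5, 5, 5), dtype=np.uint8)
        flags[2, 2, 2] = 1
        write_case(tmp_path / "i.nii.gz", vol, tmp_path / "m.nii.gz",
                   VOIMask(flags, vol.spacing))
        import SimpleITK as sitk
        zero = sitk.GetImageFromArray(np.zeros((5, 5, 5), dtype=np.uint8))
        sitk.WriteImage(zero, str(tmp_path / "z.nii.gz"))
        with pytest.raises(EmptyMaskError):
            read_case(tmp_path / "i.nii.gz", tmp_path / "z.nii.gz")

    def test_multilabel_mask_binarized_preserving_foreground(self, tmp_path):
        import SimpleITK as sitk
        vol = make_volume(np.zeros((5, 5, 5)))
        labels = np.zeros((5, 5, 5), dtype=np.uint8)
        labels[1:3, 1:3, 1:3] = 2
        write_case(tmp_path / "i.nii.gz", vol, tmp_path / "dummy.nii.gz",
                   VOIMask((labels > 0).astype(np.uint8), vol.spacing))
        sitk.WriteImage(sitk.GetImageFromArray(labels), str(tmp_path / "m.nii.gz"))
        _, mask = read_case(tmp_path / "i.nii.gz", tmp_path / "m.nii.gz")
        assert set(np.unique(mask.flags)) == {0, 1}
        assert mask.voxel_count == int((labels > 0).sum())

    def test_grid_mismatch_raises(self, tmp_path):
        va = make_volume(np.zeros((5, 5, 5)))
        vb = make_volume(np.zeros((6, 5, 5)))
        m = np.zeros((6, 5, 5), dtype=np.uint8)
        m[1, 1, 1] = 1
        write_case(tmp_path / "a.nii.gz", va, tmp_path / "bm.nii.gz",
                   VOIMask(m, vb.spacing))
        with pytest.raises(GridMismatchError):
            read_case(tmp_path / "a.nii.gz", tmp_path / "bm.nii.gz")


class TestResample:
    def test_identity_when_already_isotropic_at_target(self, rng):
        vals = rng.normal(0, 30, (12, 12, 12))
        vol = make_volume(vals, spacing=(2.0, 2.0, 2.0))
        mask = _ball(12, 4, spacing=(2.0, 2.0, 2.0))
        out_vol, out_mask = resample_isotropic(vol, mask, 2.0)
        assert out_vol.shape == vol.shape
        assert np.allclose(out_vol.values, vals, atol=1e-6)
        assert np.array_equal(out_mask.flags, mask.flags)

    def test_constant_volume_stays_constant(self):
        vol = make_volume(np.full((10, 14, 14), 55.0), spacing=(2.5, 1.0, 1.0))
        mask = _ball(14, 5)
        mask = VOIMask(np.pad(mask.flags[:10], ((0, 0), (0, 0), (0, 0))),
                       vol.spacing)
        out_vol, _ = resample_isotropic(vol, mask, 2.0)
        assert np.allclose(out_vol.values, 55.0, atol=1e-9)

    def test_downsampling_halves_grid_and_preserves_smooth_mean(self, rng):
        n = 40
        zz, yy, xx = np.meshgrid(*([np.linspace(0, 1, n)] * 3), indexing="ij")
        smooth = 100 * np.sin(2 * np.pi * zz) + 50 * yy + 30 * xx  # smooth field
        vol = make_volume(smooth, spacing=(1.0, 1.0, 1.0))
        mask = _ball(n, 14)
        out_vol, out_mask = resample_isotropic(vol, mask, 2.0)
        assert all(abs(s - n // 2) <= 1 for s in out_vol.shape)
        mean_in = vol.values[mask.as_bool()].mean()
        mean_out = out_vol.values[out_mask.as_bool()].mean()
        assert abs(mean_out - mean_in) / abs(mean_in) < 0.02

    def test_mask_volume_approximately_preserved(self):
        mask = _ball(40, 12)
        vol = make_volume(np.zeros((40, 40, 40)))
        _, out_mask = resample_isotropic(vol, mask, 2.0)
        cont = mask.voxel_count * 1.0  # mm^3 at 1 mm spacing
        resampled = out_mask.voxel_count * 8.0
        assert abs(resampled - cont) / cont < 0.10


class TestQuantize:
    def test_bin_edge_arithmetic(self):
        vals = np.zeros((1, 1, 4))
        vals[0, 0] = [0.0, 24.0, 25.0, 50.0]
        mask = make_mask(np.ones((1, 1, 4)))
        q = quantize(make_volume(vals), mask, 25.0)
        assert list(q.levels[0, 0]) == [1, 1, 2, 3]
        assert q.n_levels == 3

    def test_constant_volume_single_level(self):
        q = quantize(make_volume(np.full((3, 3, 3), 7.0)),
                     make_mask(np.ones((3, 3, 3))), 25.0)
        assert q.n_levels == 1
        assert np.all(q.levels == 1)

    def test_uniform_values_fill_levels_evenly(self, rng):
        vals = rng.uniform(0, 250, (50, 50, 40))
        mask = make_mask(np.ones_like(vals))
        q = quantize(make_volume(vals), mask, 25.0)
        assert q.n_levels == 10
        counts = np.bincount(q.levels.ravel())[1:]
        _, p = stats.chisquare(counts)
        assert p > 0.001

    def test_translation_invariance(self, rng):
        vals = rng.normal(0, 40, (6, 6, 6))
        mask = make_mask(rng.integers(0, 2, (6, 6, 6)) | 1)
        qa = quantize(make_volume(vals), mask, 25.0)
        qb = quantize(make_volume(vals + 137.0), mask, 25.0)
        assert np.array_equal(qa.levels, qb.levels)
        assert qa.n_levels == qb.n_levels


class TestCrop:
    def test_crop_keeps_all_foreground_with_pad(self):
        flags = np.zeros((20, 20, 20), dtype=np.uint8)
        flags[8:12, 9:13, 5:9] = 1
        vol = make_volume(np.arange(8000).reshape(20, 20, 20))
        cvol, cmask = crop_to_voi(vol, VOIMask(flags, vol.spacing), pad=3)
        assert cmask.voxel_count == flags.sum()
        assert cvol.shape == (10, 10, 10)

    def test_resample_then_quantize_constant_yields_single_level(self):
        vol = make_volume(np.full((10, 20, 20), -15.0), spacing=(3.0, 0.7, 0.7))
        mask = VOIMask(np.pad(np.ones((6, 12, 12), np.uint8),
                              ((2, 2), (4, 4), (4, 4))), vol.spacing)
        rv, rm = resample_isotropic(vol, mask, 2.0)
        q = quantize(rv, rm, 25.0)
        assert q.n_levels == 1
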