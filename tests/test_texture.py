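import numpy as np
import pytest

from radcrt.preprocess import quantize
from radcrt.texture import (
    DIRECTIONS_13,
    _glrlm_features_single,
    build_glcm,
    build_glrlm,
    build_glszm,
    glcm_features,
    glrlm_features,
    glszm_features,
)

from conftest import make_mask, make_volume
from oracles import (
    glcm_pairs_bruteforce,
    glrlm_runs_bruteforce,
    glszm_zones_bruteforce,
)


def _quantized(values, mask=None, bin_width=1.0):
    values = np.asarray(values, dtype=float)
    mask = np.ones_like(values) if mask is None else np.asarray(mask)
    return quantize(make_volume(values), make_mask(mask), bin_width)


@pytest.fixture
def random_q(rng):
    """Random 6^3 volume with Ng <= 4 and a ragged mask."""
    levels = rng.integers(0, 4, (6, 6, 6)).astype(float)
    mask = rng.random((6, 6, 6)) < 0.8
    mask[0, 0, 0] = True  # non-empty guarantee
    return _quantized(levels, mask)


Z_DIR = DIRECTIONS_13.index((0, 0, 1))


class TestGLCM:
    def test_alternating_line_pair_counts(self):
        q = _quantized(np.array([[[1.0, 2.0, 1.0, 2.0]]]))
        tm = build_glcm(q)
        m = tm.counts[Z_DIR]
        assert m[0, 1] == 3 and m[1, 0] == 3
        assert m[0, 0] == 0 and m[1, 1] == 0

    def test_alternating_line_contrast_is_one(self):
        q = _quantized(np.array([[[1.0, 2.0, 1.0, 2.0]]]))
        f = glcm_features(build_glcm(q))
        assert f["Contrast"] == pytest.approx(1.0)
        assert f["Homogeneity2"] == pytest.approx(0.5)

    def test_constant_region_degenerate_features(self):
        q = _quantized(np.full((4, 4, 4), 3.0))
        f = glcm_features(build_glcm(q))
        assert f["Contrast"] == 0.0
        assert f["MaxProbability"] == 1.0
        assert f["Homogeneity2"] == 1.0
        assert f["Energy"] == 1.0
        # zero marginal sd: correlation-type features flagged missing
        assert np.isnan(f["Correlation"])

    def test_normalized_matrices_sum_to_one(self, random_q):
        tm = build_glcm(random_q)
        probs = tm.normalized()
        for k in range(probs.shape[0]):
            if tm.counts[k].sum() > 0:
                assert probs[k].sum() == pytest.approx(1.0)
                assert np.allclose(probs[k], probs[k].T)  # symmetrized

    def test_counts_match_bruteforce_in_all_directions(self, random_q):
        tm = build_glcm(random_q)
        for k, d in enumerate(DIRECTIONS_13):
            expected = glcm_pairs_bruteforce(
                random_q.levels, random_q.mask.astype(bool), d, random_q.n_levels
            )
            assert np.array_equal(tm.counts[k], expected), f"direction {d}"

    def test_feature_bounds(self, random_q):
        f = glcm_features(build_glcm(random_q))
        assert f["Contrast"] >= 0
        assert 0 < f["MaxProbability"] <= 1


class TestGLRLM:
    def test_single_run_closed_form(self):
        q = _quantized(np.ones((1, 1, 5)))
        tm = build_glrlm(q)
        f = _glrlm_features_single(tm.counts[Z_DIR].astype(float), tm.n_voxels)
        assert f["LRE"] == pytest.approx(25.0)
        assert f["SRE"] == pytest.approx(1 / 25.0)
        assert f["RP"] == pytest.approx(1 / 5.0)

    def test_fully_alternating_line_all_unit_runs(self):
        q = _quantized(np.array([[[1.0, 2.0, 1.0, 2.0]]]))
        tm = build_glrlm(q)
        f = _glrlm_features_single(tm.counts[Z_DIR].astype(float), tm.n_voxels)
        assert f["SRE"] == 1.0 and f["LRE"] == 1.0 and f["RP"] == 1.0

    def test_run_percentage_bounded(self, rng):
        q = _quantized(rng.integers(0, 5, (8, 8, 8)).astype(float))
        tm = build_glrlm(q)
        for k in range(len(DIRECTIONS_13)):
            runs = tm.counts[k].sum()
            assert 0 < runs / tm.n_voxels <= 1

    def test_counts_match_bruteforce_in_all_directions(self, random_q):
        tm = build_glrlm(random_q)
        max_len = tm.counts.shape[2]
        for k, d in enumerate(DIRECTIONS_13):
            expected = glrlm_runs_bruteforce(
                random_q.levels, random_q.mask.astype(bool), d,
                random_q.n_levels, max_len,
            )
            assert np.array_equal(tm.counts[k], expected), f"direction {d}"


class TestGLSZM:
    def test_single_zone_closed_form(self):
        q = _quantized(np.full((2, 3, 4), 9.0))
        f = glszm_features(build_glszm(q))
        n = 24
        assert f["ZP"] == pytest.approx(1 / n)
        assert f["LZE"] == pytest.approx(n ** 2)

    def test_checkerboard_matches_flood_fill_oracle(self):
        zz, yy, xx = np.meshgrid(*([np.arange(4)] * 3), indexing="ij")
        board = ((zz + yy + xx) % 2 + 1).astype(float)
        q = _quantized(board)
        tm = build_glszm(q)
        zones = glszm_zones_bruteforce(q.levels, q.mask.astype(bool), q.n_levels)
        # same-level diagonal neighbors are 26-connected, so each level
        # merges into a single zone rather than 32 singletons
        assert len(zones) == int(tm.counts.sum())
        rebuilt = sorted(
            (g + 1, s + 1)
            for (g, s) in zip(*np.nonzero(tm.counts))
            for _ in range(tm.counts[g, s])
        )
        assert rebuilt == zones

    def test_zone_histogram_conserves_total_zone_count(self, random_q):
        tm = build_glszm(random_q)
        zones = glszm_zones_bruteforce(
            random_q.levels, random_q.mask.astype(bool), random_q.n_levels
        )
        assert int(tm.counts.sum()) == len(zones)
        rebuilt = sorted(
            (g + 1, s + 1)
            for (g, s) in zip(*np.nonzero(tm.counts))
            for _ in range(tm.counts[g, s])
        )
        assert rebuilt == zones


class TestInvariances:
    def test_rotation_leaves_direction_averaged_features_unchanged(self, rng):
        vals = rng.integers(0, 4, (7, 7, 7)).astype(float)
        mask = (rng.random((7, 7, 7)) < 0.85)
        mask[3, 3, 3] = True
        q = _quantized(vals, mask)
        vals_r = np.rot90(vals, k=1, axes=(1, 2)).copy()
        mask_r = np.rot90(mask, k=1, axes=(1, 2)).copy()
        q_r = _quantized(vals_r, mask_r)
        for build, feats in ((build_glcm, glcm_features),
                             (build_glrlm, glrlm_features),
                             (build_glszm, glszm_features)):
            fa = feats(build(q))
            fb = feats(build(q_r))
            for name in fa:
                if np.isnan(fa[name]):
                    assert np.isnan(fb[name])
                else:
                    assert fa[name] == pytest.approx(fb[name], rel=1e-9), name

    def test_intensity_shift_leaves_texture_unchanged(self, rng):
        vals = rng.normal(0, 60, (6, 6, 6))
        qa = _quantized(vals, bin_width=25.0)
        qb = _quantized(vals + 333.0, bin_width=25.0)
        fa = glcm_features(build_glcm(qa))
        fb = glcm_features(build_glcm(qb))
        for name in fa:
            if not np.isnan(fa[name]):
                assert fa[name] == pytest.approx(fb[name], rel=1e-12), name

    def test_emphasis_features_finite_with_two_levels(self):
        vals = np.zeros((3, 3, 3))
        vals[0] = 1.0
        q = _quantized(vals)
        assert all(np.isfinite(v) for v in glrlm_features(build_glrlm(q)).values())
        assert all(np.isfinite(v) for v in glszm_features(build_glszm(q)).values())
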