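"""Quantization, GLCM and GLSZM against hand counts and brute-force oracles."""

import numpy as np
import pytest

from bcsradiomics.errors import BcsRadiomicsError, EmptyMaskError
from bcsradiomics.phantom import ClassParams, generate_mask, generate_series
from bcsradiomics.texture import (
    compute_glcm,
    compute_glszm,
    glcm_features,
    glszm_features,
    quantize,
    Glcm,
    Glszm,
)

from _oracles import brute_force_glcm, flood_fill_zones, zones_to_matrix


def _roi(values, n_levels=16):
    values = np.asarray(values, dtype=float)
    return quantize(values, np.ones(values.shape, dtype=bool), n_levels=n_levels)


class TestQuantize:
    def test_one_value_per_bin(self):
        q = _roi(np.arange(16.0).reshape(1, 4, 4))
        assert sorted(np.unique(q.levels[q.mask])) == list(range(1, 17))

    def test_constant_roi_is_level_one(self):
        q = _roi(np.full((2, 2, 2), 3.3))
        assert (q.levels == 1).all()

    def test_two_level_split(self):
        q = _roi(np.array([0.0, 1.0, 2.0, 3.0]).reshape(1, 1, 4), n_levels=2)
        assert q.levels.ravel().tolist() == [1, 1, 2, 2]

    def test_monotone_and_range_anchored(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            v = rng.normal(size=(4, 5, 3)) * rng.uniform(0.5, 100)
            q = _roi(v)
            flat_v = v.ravel()
            flat_l = q.levels.ravel()
            order = np.argsort(flat_v)
            assert (np.diff(flat_l[order]) >= 0).all()
            assert flat_l[np.argmin(flat_v)] == 1
            assert flat_l[np.argmax(flat_v)] == 16

    def test_only_in_mask_voxels_quantized(self):
        v = np.zeros((3, 3, 3))
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        q = quantize(v, mask)
        assert q.levels[1, 1, 1] == 1 and q.levels.sum() == 1

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            quantize(np.zeros((2, 2, 2)), np.zeros((2, 2, 2), dtype=bool))


class TestGlcm:
    def test_constant_roi_all_mass_on_diagonal(self):
        g = compute_glcm(_roi(np.zeros((2, 2, 2))))
        assert g.p[0, 0] == 1.0 and g.p.sum() == 1.0

    def test_alternating_strip_hand_count(self):
        # 3 adjacent pairs, all discordant, symmetrized
        g = compute_glcm(_roi(np.array([0.0, 1.0, 0.0, 1.0]).reshape(1, 1, 4), n_levels=2))
        assert g.p[0, 1] == 0.5 and g.p[1, 0] == 0.5 and g.p[0, 0] == 0.0

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            shape = tuple(rng.integers(2, [7, 7, 6]))
            v = rng.normal(size=shape)
            mask = rng.random(shape) > 0.2
            if mask.sum() < 2:
                continue
            q = quantize(v, mask, n_levels=int(rng.integers(2, 9)))
            try:
                g = compute_glcm(q)
            except BcsRadiomicsError:
                continue
            oracle = brute_force_glcm(q.levels)
            L = oracle.shape[0]
            np.testing.assert_array_equal(g.p[:L, :L], oracle)
            assert g.p[L:, :].sum() == 0

    def test_symmetry_normalization_axis_relabeling(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(5, 6, 4))
        mask = rng.random((5, 6, 4)) > 0.3
        q = quantize(v, mask)
        g = compute_glcm(q)
        assert np.allclose(g.p, g.p.T)
        assert g.p.sum() == pytest.approx(1.0, abs=1e-9)
        qt = quantize(np.transpose(v, (2, 0, 1)), np.transpose(mask, (2, 0, 1)))
        np.testing.assert_allclose(compute_glcm(qt).p, g.p)

    def test_isolated_voxels_raise(self):
        v = np.zeros((5, 5, 5))
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0, 0, 0] = mask[4, 4, 4] = True
        with pytest.raises(BcsRadiomicsError):
            compute_glcm(quantize(v, mask))


class TestGlcmFeatures:
    def test_point_mass(self):
        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        f = glcm_features(Glcm(p=p))
        assert f == {"energy": 1.0, "entropy": 0.0, "homogeneity": 1.0, "contrast": 0.0}

    def test_two_cell_symmetric(self):
        p = np.zeros((4, 4))
        p[0, 1] = p[1, 0] = 0.5
        f = glcm_features(Glcm(p=p))
        assert f["energy"] == 0.5
        assert f["entropy"] == pytest.approx(1.0)
        assert f["homogeneity"] == pytest.approx(0.5)
        assert f["contrast"] == pytest.approx(1.0)

    def test_uniform_entropy_is_log2_of_cells(self):
        p = np.full((16, 16), 1 / 256)
        assert glcm_features(Glcm(p=p))["entropy"] == pytest.approx(8.0)


class TestGlszm:
    def test_constant_roi_single_zone(self):
        z = compute_glszm(_roi(np.zeros((2, 2, 2))))
        assert z.n_zones == 1 and z.n_voxels == 8
        assert z.counts[0, 7] == 1

    def test_two_runs_in_strip(self):
        z = compute_glszm(_roi(np.array([0.0, 0.0, 1.0, 1.0]).reshape(1, 1, 4), n_levels=2))
        assert z.counts[0, 1] == 1 and z.counts[1, 1] == 1 and z.n_zones == 2

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(13)
        for _ in range(100):
            shape = tuple(rng.integers(2, [6, 6, 5]))
            v = rng.normal(size=shape)
            mask = rng.random(shape) > 0.25
            if not mask.any():
                continue
            q = quantize(v, mask, n_levels=int(rng.integers(2, 6)))
            z = compute_glszm(q, connectivity=connectivity)
            oracle = zones_to_matrix(flood_fill_zones(q.levels, connectivity), q.n_levels)
            np.testing.assert_array_equal(z.counts, oracle)

    def test_voxel_conservation(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            v = rng.normal(size=(6, 5, 5))
            mask = rng.random((6, 5, 5)) > 0.4
            if not mask.any():
                continue
            z = compute_glszm(quantize(v, mask))
            j = np.arange(1, z.counts.shape[1] + 1)
            assert int((z.counts * j).sum()) == z.n_voxels == int(mask.sum())
            assert int(z.counts.sum()) == z.n_zones


class TestGlszmFeatures:
    def test_single_zone(self):
        z = compute_glszm(_roi(np.zeros((2, 2, 2))))
        f = glszm_features(z)
        assert f["LZE"] == 64.0 and f["SZE"] == 1 / 64
        assert f["ZP"] == 1 / 8 and f["HILZE"] == 64.0

    def test_two_zone_hand_computation(self):
        counts = np.zeros((2, 2), dtype=np.int64)
        counts[0, 1] = 1  # level 1, size 2
        counts[1, 1] = 1  # level 2, size 2
        f = glszm_features(Glszm(counts=counts, n_zones=2, n_voxels=4))
        assert f["GLN"] == 1.0 and f["ZSN"] == 2.0
        assert f["LIZE"] == pytest.approx(0.625)

    def test_all_singleton_zones(self):
        # strictly increasing voxel values: every voxel its own level and zone
        v = np.arange(8.0).reshape(2, 2, 2)
        z = compute_glszm(_roi(v, n_levels=16))
        f = glszm_features(z)
        assert f["SZE"] == 1.0 and f["LZE"] == 1.0 and f["ZP"] == 1.0

    def test_zero_zones_raise(self):
        with pytest.raises(BcsRadiomicsError):
            glszm_features(Glszm(counts=np.zeros((2, 2), dtype=np.int64),
                                 n_zones=0, n_voxels=0))


class TestTextureOnPhantoms:
    def test_longer_correlation_length_grows_zones(self):
        """Smoothing scale controls mean zone size, hence LZE (directional)."""
        deltas = []
        for seed in range(5):
            lze = {}
            for sigma in (0.8, 2.0):
                params = ClassParams(
                    solidity_target=0.9, irregularity=0.0, skew_shape=0.0,
                    enhancement_curve=(1, 2, 2, 2), texture_corr_length=sigma,
                )
                mask = generate_mask(params, (40, 40, 40), seed)
                vol = generate_series(mask, params, seed)["post1"]
                z = compute_glszm(quantize(vol, mask))
                lze[sigma] = glszm_features(z)["LZE"]
            deltas.append(lze[2.0] - lze[0.8])
        assert np.mean(deltas) > 0
        assert sum(d > 0 for d in deltas) >= 4
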