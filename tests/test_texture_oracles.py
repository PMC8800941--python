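"""Every texture feature is checked against an explicit brute-force
pair/run/zone counter on tiny grids."""

import numpy as np
import pytest

import oracles
from radsig.features import texture
from radsig.features.manifest import (
    GLDZM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
)
from radsig.features.preprocess import QuantizedImage

from conftest import random_quantized

GRIDS = [
    random_quantized(seed=0, shape=(4, 4, 4), ng=4, mask_fraction=0.8),
    random_quantized(seed=1, shape=(5, 5, 5), ng=6, mask_fraction=0.6),
    random_quantized(seed=2, shape=(5, 4, 3), ng=3, mask_fraction=0.9),
    random_quantized(seed=3, shape=(3, 5, 5), ng=5, mask_fraction=0.5),
]


@pytest.mark.parametrize("q", GRIDS, ids=range(len(GRIDS)))
class TestOracleEquivalence:
    def test_glcm_matrices_and_features(self, q):
        for off in texture.DIRECTIONS_13:
            oracle_p = oracles.glcm_matrix(q.levels, q.mask, off, q.n_levels)
            if oracle_p is None:
                with pytest.raises(ValueError):
                    texture.glcm_matrix(q, off)
                continue
            p = texture.glcm_matrix(q, off)
            assert np.allclose(p, oracle_p, atol=1e-12)
            got = texture.glcm_features_single(p)
            expected = oracles.glcm_features(oracle_p)
            for name in expected:
                assert got[name] == pytest.approx(expected[name], abs=1e-10), name

    def test_glrlm_runs_and_features(self, q):
        n_vox = int(q.mask.sum())
        per_dir = []
        for off in texture.DIRECTIONS_13:
            runs = oracles.glrlm_runs(q.levels, q.mask, off)
            m_impl = texture.glrlm_matrix(q, off)
            m_oracle = oracles.rl_matrix_from_pairs(
                runs, q.n_levels, m_impl.shape[1]
            )
            assert np.allclose(m_impl, m_oracle)
            per_dir.append(
                oracles.run_zone_features(m_oracle, n_vox, GLRLM_FEATURES)
            )
        got = texture.glrlm_features(q)
        for name in GLRLM_FEATURES:
            expected = np.mean([d[name] for d in per_dir])
            assert got[f"glrlm_{name}"] == pytest.approx(expected, abs=1e-10)

    def test_zone_features(self, q):
        zones = oracles.zones_26(q.levels, q.mask)
        n_vox = int(q.mask.sum())
        max_s = max(z[1] for z in zones)
        max_d = max(z[2] for z in zones)
        szm = [[0.0] * max_s for _ in range(q.n_levels)]
        dzm = [[0.0] * max_d for _ in range(q.n_levels)]
        for g, s, d in zones:
            szm[g - 1][s - 1] += 1
            dzm[g - 1][d - 1] += 1
        exp_sz = oracles.run_zone_features(szm, n_vox, GLSZM_FEATURES)
        exp_dz = oracles.run_zone_features(dzm, n_vox, GLDZM_FEATURES)
        got_sz = texture.glszm_features(q)
        got_dz = texture.gldzm_features(q)
        for name in GLSZM_FEATURES:
            assert got_sz[f"glszm_{name}"] == pytest.approx(
                exp_sz[name], abs=1e-10
            )
        for name in GLDZM_FEATURES:
            assert got_dz[f"gldzm_{name}"] == pytest.approx(
                exp_dz[name], abs=1e-10
            )

    def test_ngtdm_features(self, q):
        expected = oracles.ngtdm_features(q.levels, q.mask, q.n_levels)
        got = texture.ngtdm_features(q)
        for name, v in expected.items():
            assert got[f"ngtdm_{name}"] == pytest.approx(v, abs=1e-10), name

    def test_gldm_features(self, q):
        expected = oracles.gldm_features(q.levels, q.mask, q.n_levels)
        got = texture.gldm_features(q)
        for name, v in expected.items():
            assert got[f"gldm_{name}"] == pytest.approx(v, abs=1e-10), name


class TestKnownGrids:
    def test_checkerboard_contrast_and_correlation(self):
        # alternating two-level 4x4x1 plane: axial neighbours always differ
        xx, yy = np.meshgrid(np.arange(4), np.arange(4), indexing="ij")
        levels = ((xx + yy) % 2 + 1)[:, :, None]
        q = QuantizedImage(levels, np.ones_like(levels, bool), 2)
        for off in [(1, 0, 0), (0, 1, 0)]:
            feats = texture.glcm_features_single(texture.glcm_matrix(q, off))
            assert feats["contrast"] == pytest.approx(1.0)  # max for 2 levels
            assert feats["correlation"] <= 0

    def test_constant_grid_degenerate(self):
        q = QuantizedImage(np.ones((3, 3, 3), int), np.ones((3, 3, 3), bool), 4)
        feats = texture.glcm_features(q)
        assert feats["glcm_joint_entropy"] == 0.0
        assert feats["glcm_angular_second_moment"] == 1.0

    def test_matrix_normalization(self):
        q = random_quantized(seed=5, shape=(4, 4, 4), ng=4)
        for off in texture.DIRECTIONS_13:
            p = texture.glcm_matrix(q, off)
            assert p.sum() == pytest.approx(1.0)
            assert (p >= 0).all()

    def test_single_voxel_mask_fails(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        levels = np.where(mask, 1, 0)
        with pytest.raises(ValueError):
            texture.glcm_features(QuantizedImage(levels, mask, 2))

    def test_single_run_grid(self):
        # one 1x1x3 line of equal level: one run of length 3 along z
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, :] = True
        levels = np.where(mask, 2, 0)
        q = QuantizedImage(levels, mask, 2)
        m = texture.glrlm_matrix(q, (0, 0, 1))
        assert m[1, 2] == 1.0 and m.sum() == 1.0
        m_axial = texture.glrlm_matrix(q, (1, 0, 0))
        assert m_axial[1, 0] == 3.0  # three length-1 runs across the line
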