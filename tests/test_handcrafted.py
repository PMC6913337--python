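"""Handcrafted texture/shape features against brute-force oracles.

The oracles enumerate co-occurrences, runs, zones and neighbourhood
differences directly with Python loops on small ROIs, independently of
the vectorised implementations.
"""

import itertools

import numpy as np
import pytest

import gliorad as g
from gliorad.handcrafted import (
    DIRECTIONS_13,
    STAT_NAMES,
    FeatureTable,
    default_grid,
    glcm_matrix,
    glcm_stats,
    glrlm_matrix,
    glrlm_stats,
    glszm_matrix,
    glszm_stats,
    global_stats,
    ngtdm_stats,
    ngtdm_vectors,
    nontexture_features,
    small_grid,
)

from conftest import make_roi

ALL_26 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_glcm(levels, mask, n_gray):
    counts = np.zeros((n_gray, n_gray))
    shape = levels.shape
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        for d in ALL_26:
            j = tuple(i + s for i, s in zip(idx, d))
            if all(0 <= a < b for a, b in zip(j, shape)) and mask[j]:
                counts[levels[idx] - 1, levels[j] - 1] += 1
    return counts / counts.sum()


def oracle_glrlm(levels, mask, n_gray):
    max_len = max(levels.shape) * 2
    counts = np.zeros((n_gray, max_len))
    shape = levels.shape
    for d in DIRECTIONS_13:
        for idx in np.ndindex(shape):
            if not mask[idx]:
                continue
            prev = tuple(i - s for i, s in zip(idx, d))
            if (
                all(0 <= a < b for a, b in zip(prev, shape))
                and mask[prev]
                and levels[prev] == levels[idx]
            ):
                continue  # not a run start
            length, cur = 1, tuple(i + s for i, s in zip(idx, d))
            while (
                all(0 <= a < b for a, b in zip(cur, shape))
                and mask[cur]
                and levels[cur] == levels[idx]
            ):
                length += 1
                cur = tuple(i + s for i, s in zip(cur, d))
            counts[levels[idx] - 1, length - 1] += 1
    return counts


def oracle_glszm(levels, mask, n_gray):
    n_vox = int(mask.sum())
    counts = np.zeros((n_gray, n_vox))
    seen = set()
    for start in map(tuple, np.argwhere(mask)):
        if start in seen:
            continue
        zone, stack, gl = {start}, [start], levels[start]
        while stack:
            cur = stack.pop()
            for d in ALL_26:
                nxt = tuple(i + s for i, s in zip(cur, d))
                if (
                    all(0 <= a < b for a, b in zip(nxt, levels.shape))
                    and nxt not in zone
                    and mask[nxt]
                    and levels[nxt] == gl
                ):
                    zone.add(nxt)
                    stack.append(nxt)
        seen |= zone
        counts[gl - 1, len(zone) - 1] += 1
    return counts


def oracle_ngtdm(levels, mask, n_gray):
    n_g = np.zeros(n_gray)
    s_g = np.zeros(n_gray)
    for idx in np.ndindex(levels.shape):
        if not mask[idx]:
            continue
        nbrs = [
            levels[tuple(i + s for i, s in zip(idx, d))]
            for d in ALL_26
            if all(0 <= i + s < b for i, s, b in zip(idx, d, levels.shape))
            and mask[tuple(i + s for i, s in zip(idx, d))]
        ]
        if not nbrs:
            continue
        gl = levels[idx]
        n_g[gl - 1] += 1
        s_g[gl - 1] += abs(gl - np.mean(nbrs))
    return n_g, s_g


# ---------------------------------------------------------------------------
# matrix constructions vs oracles
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(6))
def test_glcm_matrix_matches_enumeration(seed):
    levels, mask = make_roi(seed)
    np.testing.assert_allclose(
        glcm_matrix(levels, mask, 3), oracle_glcm(levels, mask, 3), atol=1e-12
    )


@pytest.mark.parametrize("seed", range(6))
def test_glrlm_matrix_matches_enumeration(seed):
    levels, mask = make_roi(seed)
    got = glrlm_matrix(levels, mask, 3)
    want = oracle_glrlm(levels, mask, 3)
    L = min(got.shape[1], want.shape[1])
    assert got[:, L:].sum() == 0 and want[:, L:].sum() == 0
    np.testing.assert_allclose(got[:, :L], want[:, :L], atol=1e-12)


@pytest.mark.parametrize("seed", range(6))
def test_glszm_matrix_matches_enumeration(seed):
    levels, mask = make_roi(seed)
    np.testing.assert_allclose(
        glszm_matrix(levels, mask, 3), oracle_glszm(levels, mask, 3), atol=1e-12
    )


@pytest.mark.parametrize("seed", range(6))
def test_ngtdm_vectors_match_enumeration(seed):
    levels, mask = make_roi(seed)
    n_got, s_got = ngtdm_vectors(levels, mask, 3)
    n_want, s_want = oracle_ngtdm(levels, mask, 3)
    np.testing.assert_allclose(n_got, n_want, atol=1e-12)
    np.testing.assert_allclose(s_got, s_want, atol=1e-9)


# ---------------------------------------------------------------------------
# hand-checked statistic values
# ---------------------------------------------------------------------------

def _solid(levels_value, shape):
    levels = np.full(shape, levels_value, dtype=np.int64)
    return levels, np.ones(shape, bool)


class TestGlcm:
    def test_constant_roi(self):
        levels, mask = _solid(2, (3, 3, 3))
        s = glcm_stats(levels, mask, 4)
        assert s["Energy"] == pytest.approx(1.0)
        assert s["Contrast"] == pytest.approx(0.0)
        assert s["Entropy"] == pytest.approx(0.0)

    def test_two_voxel_pair(self):
        levels = np.array([[[1, 2]]])
        mask = np.ones_like(levels, bool)
        P = glcm_matrix(levels, mask, 2)
        np.testing.assert_allclose(P, [[0, 0.5], [0.5, 0]])
        assert glcm_stats(levels, mask, 2)["Contrast"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_symmetric_and_normalized(self, seed):
        levels, mask = make_roi(seed)
        P = glcm_matrix(levels, mask, 3)
        np.testing.assert_allclose(P, P.T)
        assert P.sum() == pytest.approx(1.0)


class TestGlrlm:
    def test_collinear_three_voxels(self):
        # merged matrix: one run of length 3 plus 36 singleton runs in the
        # off-axis directions; HGRE is g^2 = 4 throughout
        levels, mask = _solid(2, (3, 1, 1))
        s = glrlm_stats(levels, mask, 2)
        assert s["HGRE"] == pytest.approx(4.0)
        R = glrlm_matrix(levels, mask, 2)
        assert R[1, 2] == 1 and R[1, 0] == 36

    def test_all_singleton_runs(self):
        # every voxel its own gray level: runs of length 1 in all directions
        levels = np.arange(1, 28).reshape(3, 3, 3)
        mask = np.ones_like(levels, bool)
        s = glrlm_stats(levels, mask, 27)
        assert s["SRE"] == pytest.approx(1.0)
        assert s["LRE"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_run_percentage_in_unit_interval(self, seed):
        levels, mask = make_roi(seed)
        rp = glrlm_stats(levels, mask, 3)["RP"]
        assert 0 < rp <= 1


class TestGlszm:
    def test_single_zone(self):
        levels, mask = _solid(3, (1, 2, 2))  # one level-3 zone of size 4
        s = glszm_stats(levels, mask, 3)
        assert s["HGZE"] == pytest.approx(9.0)
        assert s["SZHGE"] == pytest.approx(9.0 / 16.0)
        assert s["ZP"] == pytest.approx(0.25)

    def test_checkerboard_zones_in_2d_plane(self):
        # 6-connected checkerboard would split, but zones are 26-connected:
        # use a strided pattern so every zone is a single voxel
        levels = np.array([[[1, 2, 1], [2, 1, 2]]]) * 0 + 1
        levels[0, 0, 1] = levels[0, 1, 0] = levels[0, 1, 2] = 2
        mask = np.zeros_like(levels, bool)
        mask[0, 0, 1] = True  # isolated voxels only
        s = glszm_stats(levels, mask, 2)
        assert s["SZE"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_zone_sizes_partition_the_mask(self, seed):
        levels, mask = make_roi(seed)
        S = glszm_matrix(levels, mask, 3)
        total = (S * np.arange(1, S.shape[1] + 1)[None, :]).sum()
        assert total == mask.sum()


class TestNgtdm:
    def test_constant_roi_contrast_zero(self):
        levels, mask = _solid(2, (3, 3, 3))
        assert ngtdm_stats(levels, mask, 3)["Contrast"] == pytest.approx(0.0)

    def test_three_voxel_line_hand_case(self):
        levels = np.array([[[1]], [[2]], [[1]]])
        mask = np.ones_like(levels, bool)
        n_g, s_g = ngtdm_vectors(levels, mask, 2)
        # each end sees only the centre (A = 2); the centre sees both ends
        # (A = 1): s(1) = 2*|1-2|, s(2) = |2-1|
        np.testing.assert_allclose(n_g, [2, 1])
        np.testing.assert_allclose(s_g, [2.0, 1.0])

    @pytest.mark.parametrize("seed", range(3))
    def test_coarseness_finite_positive(self, seed):
        levels, mask = make_roi(seed)
        c = ngtdm_stats(levels, mask, 3)["Coarseness"]
        assert np.isfinite(c) and c > 0

    def test_isolated_voxels_error(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[0, 0, 0] = mask[4, 4, 4] = True
        with pytest.raises(ValueError, match="isolated"):
            ngtdm_stats(np.ones((5, 5, 5), np.int64), mask, 2)


class TestGlobalStats:
    def test_population_variance(self):
        assert global_stats([1, 1, 2, 2])["Variance"] == pytest.approx(0.25)

    def test_symmetric_skewness_zero(self):
        assert global_stats([1, 2, 3, 4, 5])["Skewness"] == pytest.approx(0.0)

    def test_constant_imputed(self):
        s = global_stats([3, 3, 3])
        assert s == {"Variance": 0.0, "Skewness": 0.0, "Kurtosis": 0.0}


class TestNontexture:
    def test_single_voxel(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        f = nontexture_features(mask, (1, 1, 1))
        assert f == {"Volume": 1.0, "Size": 0.0, "Solidity": 1.0,
                     "Eccentricity": 0.0}

    def test_solid_cube(self):
        mask = np.zeros((12, 12, 12), bool)
        mask[1:11, 1:11, 1:11] = True
        f = nontexture_features(mask, (1, 1, 1))
        assert f["Volume"] == pytest.approx(1000.0)
        assert f["Eccentricity"] == pytest.approx(0.0, abs=1e-9)
        assert f["Solidity"] == pytest.approx(1.0)

    def test_block_size_is_max_pairwise_distance(self):
        mask = np.zeros((12, 6, 6), bool)
        mask[1:11, 1:5, 1:5] = True  # 10 x 4 x 4 block
        f = nontexture_features(mask, (1, 1, 1))
        # exhaustive oracle: max distance between voxel centers
        coords = np.argwhere(mask).astype(float)
        d = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1)).max()
        assert f["Size"] == pytest.approx(d)
        assert f["Size"] == pytest.approx(np.sqrt(9**2 + 3**2 + 3**2))

    def test_anisotropic_spacing_scales_volume(self):
        mask = np.ones((4, 4, 4), bool)
        f = nontexture_features(mask, (1, 2, 3))
        assert f["Volume"] == pytest.approx(64 * 6.0)


class TestExtraction:
    def test_small_grid_feature_count(self, phantom_pair):
        feats = g.extract_handcrafted(phantom_pair[0], grid=small_grid())
        grid = small_grid()
        assert len(feats) == 4 + 4 * grid.features_per_modality

    def test_grid_count_contract(self):
        grid = default_grid()
        assert len(grid.params) == 240
        assert grid.features_per_modality == 240 * 43
        assert len(STAT_NAMES) == 43

    def test_deterministic(self, phantom_pair):
        a = g.extract_handcrafted(phantom_pair[1], grid=small_grid())
        b = g.extract_handcrafted(phantom_pair[1], grid=small_grid())
        assert a == b

    def test_shift_invariance_under_equal_quantization(self):
        # quantile bins ignore intensity shifts, so matrix statistics from
        # Equal-quantized ROIs are shift-invariant
        rng = np.random.default_rng(8)
        vol = rng.standard_normal((6, 6, 6))
        mask = np.ones((6, 6, 6), bool)
        lv1 = np.zeros_like(vol, np.int64)
        lv2 = np.zeros_like(vol, np.int64)
        lv1[mask] = g.quantize(vol[mask], "Equal", 4)
        lv2[mask] = g.quantize(vol[mask] + 57.0, "Equal", 4)
        assert glcm_stats(lv1, mask, 4) == glcm_stats(lv2, mask, 4)

    def test_degenerate_scale_imputed_not_fatal(self):
        # a lesion far smaller than the coarsest scale must not abort
        cfg = g.PhantomConfig(grid_shape=(12, 12, 12), lesion_radius=1.2, seed=1)
        study = g.generate_phantom(cfg, 0)
        grid = g.TextureGrid(
            params=[g.ExtractionParams(scale_mm=6.0, n_gray=8)]
        )
        feats = g.extract_handcrafted(study, grid=grid, modalities=["T1"])
        assert len(feats) == 4 + 43


class TestFeatureTableContainer:
    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            FeatureTable(ids=["a", "b"], names=["x", "x"],
                         X=np.zeros((2, 2)), y=[0, 1])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            FeatureTable(ids=["a", "b"], names=["x", "y"],
                         X=np.array([[1.0, np.nan], [0, 1]]), y=[0, 1])

    def test_concat_requires_shared_patients(self, informative_table):
        other = g.generate_feature_table(
            g.TableSpec(n_pos=10, n_neg=10, p_features=3, seed=0)
        )
        with pytest.raises(ValueError, match="share patients"):
            FeatureTable.concat(informative_table, other)
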