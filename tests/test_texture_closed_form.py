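"""Texture families on regions with hand-derivable answers."""

from __future__ import annotations

import math

import numpy as np
import pytest

import _oracles as orc
from conftest import full_mask, mask_from_bits, volume_from_array
from fairomics.features import (
    gldm_features,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from fairomics.features.glcm import glcm_features_single, glcm_matrices
from fairomics.features.gldm import gldm_matrix
from fairomics.features.glrlm import glrlm_matrix, size_matrix_features
from fairomics.features.glszm import glszm_matrix
from fairomics.preprocess import DiscretizedRegion, discretize_fbw


def region_from_levels(levels, mask=None):
    lg = np.asarray(levels, dtype=np.int64)
    mask = np.ones(lg.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    grid = np.where(mask, lg, 0)
    return DiscretizedRegion(level_grid=grid, mask=mask, ng=int(grid.max()),
                             voxel_volume=1.0, spacing=(1.0, 1.0, 1.0))


def constant_region(shape=(3, 3, 3)):
    return region_from_levels(np.ones(shape, dtype=int))


class TestGLCM:
    def test_constant_region_degenerate_values(self):
        f = {x.name: x.value for x in glcm_features(constant_region())}
        assert f["Joint Entropy"] == 0.0
        assert f["Maximum Probability"] == 1.0
        assert f["Contrast"] == 0.0
        assert f["Joint Energy"] == 1.0

    def test_three_by_three_example_matches_pair_enumeration_oracle(self):
        levels = np.array([[[1, 1, 2], [1, 2, 2], [3, 3, 3]]])
        d = region_from_levels(levels)
        mats = glcm_matrices(d)
        for angle, mat in zip(orc.ANGLES_13, mats):
            expected = orc.glcm_counts(d.level_grid, d.mask, angle, d.ng)
            assert np.array_equal(mat, expected), angle
        # Joint Entropy per direction agrees with the longhand formula
        for mat in mats:
            if mat.sum() == 0:
                continue
            ours = glcm_features_single(mat)["Joint Entropy"]
            theirs = orc.glcm_features_from_counts(mat)["Joint Entropy"]
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_checkerboard_correlation_is_minus_one_in_plane(self):
        k, r, c = np.meshgrid(*[np.arange(4)] * 3, indexing="ij")
        d = region_from_levels((k + r + c) % 2 + 1)
        mats = dict(zip(map(tuple, orc.ANGLES_13), glcm_matrices(d)))
        for axis in ((0, 0, 1), (0, 1, 0)):
            f = glcm_features_single(mats[axis])
            assert f["Correlation"] == pytest.approx(-1.0, abs=1e-12)

    def test_isolated_voxels_have_no_pairs_and_yield_nan(self):
        lg = np.zeros((1, 1, 3), dtype=int)
        mask = np.array([[[True, False, True]]])
        lg[0, 0, 0] = lg[0, 0, 2] = 1
        f = glcm_features(region_from_levels(lg, mask))
        assert all(math.isnan(x.value) for x in f)


class TestGLRLM:
    def test_single_axis_run_of_four(self):
        d = region_from_levels(np.ones((1, 1, 4), dtype=int))
        mat = glrlm_matrix(d, (0, 0, 1))
        assert mat.shape == (1, 4)
        assert mat[0, 3] == 1 and mat.sum() == 1
        assert size_matrix_features(mat, d.n_voxels)["small"] == pytest.approx(1 / 16)

    def test_all_distinct_levels_give_run_percentage_one(self):
        d = region_from_levels(np.arange(1, 28).reshape(3, 3, 3))
        f = {x.name: x.value for x in glrlm_features(d)}
        assert f["Run Percentage"] == 1.0

    def test_constant_line_runs_along_each_direction(self):
        d = region_from_levels(np.ones((3, 3, 3), dtype=int))
        # along an axis direction: 9 runs of length 3
        mat = glrlm_matrix(d, (0, 0, 1))
        assert mat[0, 2] == 9 and mat.sum() == 9
        # along the main space diagonal: 3+...: runs of lengths 1,2,3
        mat = glrlm_matrix(d, (1, 1, 1))
        assert mat.sum() == sum(1 for _ in orc.run_list(d.level_grid, d.mask, (1, 1, 1)))


class TestGLSZM:
    def test_constant_cube_is_one_zone_of_27(self):
        mat = glszm_matrix(constant_region())
        assert mat.shape == (1, 27)
        assert mat[0, 26] == 1 and mat.sum() == 1

    def test_two_disjoint_blobs_of_same_level(self):
        lg = np.zeros((1, 5, 5), dtype=int)
        lg[0, 0:2, 0:2] = 1  # 4 voxels
        lg[0, 3:5, 3:5] = 1  # 4 voxels, diagonal gap > 26-connectivity? touching corners!
        lg[0, 4, 4] = 1
        mask = lg > 0
        zones = orc.zone_list(lg, mask)
        mat = glszm_matrix(region_from_levels(lg, mask))
        assert mat.sum() == len(zones)

    def test_all_single_voxel_zones_zone_percentage_one(self):
        d = region_from_levels(np.arange(1, 9).reshape(2, 2, 2))
        f = {x.name: x.value for x in glszm_features(d)}
        assert f["Zone Percentage"] == 1.0


class TestGLDM:
    def test_constant_cube_center_has_dependence_26(self):
        mat = gldm_matrix(constant_region(), alpha=0)
        assert mat.shape[1] == 27
        assert mat[0, 26] == 1  # the center voxel
        assert mat.sum() == 27

    def test_single_voxel_has_dependence_zero_only(self):
        d = region_from_levels(np.ones((1, 1, 1), dtype=int))
        mat = gldm_matrix(d)
        assert mat.shape == (1, 1) and mat[0, 0] == 1

    def test_alpha_relaxes_the_level_match(self):
        d = region_from_levels(np.array([[[1, 2, 3]]]))
        strict = {x.name: x.value for x in gldm_features(d, alpha=0)}
        loose = {x.name: x.value for x in gldm_features(d, alpha=1)}
        assert strict["Large Dependence Emphasis"] < loose["Large Dependence Emphasis"]


class TestNGTDM:
    def test_constant_region_coarseness_capped(self):
        f = {x.name: x.value for x in ngtdm_features(constant_region())}
        assert f["Contrast"] == 0.0
        assert f["Coarseness"] == pytest.approx(1e6)
        assert f["Busyness"] == 0.0

    def test_single_voxel_region_is_nan(self):
        d = region_from_levels(np.ones((1, 1, 1), dtype=int))
        assert all(math.isnan(x.value) for x in ngtdm_features(d))

    def test_two_level_checkerboard_matches_hand_computed_table(self):
        k, r, c = np.meshgrid(*[np.arange(3)] * 3, indexing="ij")
        lg = (k + r + c) % 2 + 1
        d = region_from_levels(lg)
        from fairomics.features.ngtdm import ngtdm_table

        table = ngtdm_table(d)
        n, p, s, nvp = orc.ngtdm_table(lg, d.mask, 2)
        assert table[:, 0].tolist() == n
        assert np.allclose(table[:, 2], s)
        assert nvp == 27


class TestEntropyRelabelInvariance:
    def test_entropy_type_features_survive_level_permutation(self):
        rng = np.random.default_rng(11)
        lg = rng.integers(1, 5, (4, 4, 4))
        d = region_from_levels(lg)
        perm = np.array([0, 3, 1, 4, 2])  # bijection on {1..4}
        d2 = region_from_levels(perm[lg])
        # only equality-based entropies are relabel-invariant; difference/sum
        # entropies depend on level arithmetic and may legitimately change
        targets = {
            glcm_features: "Joint Entropy",
            glrlm_features: "Run Entropy",
            glszm_features: "Zone Entropy",
        }
        for fam, name in targets.items():
            a = {x.name: x.value for x in fam(d)}
            b = {x.name: x.value for x in fam(d2)}
            assert a[name] == pytest.approx(b[name], abs=1e-9), name
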