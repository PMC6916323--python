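"""Re-segmentation, resampling and gray-level discretization."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import full_mask, mask_from_bits, volume_from_array
from fairomics.preprocess import (
    ExtractionConfig,
    discretize_fbc,
    discretize_fbw,
    resample,
    resegment,
)


class TestResegment:
    def test_unbounded_range_keeps_mask(self):
        vol = volume_from_array(np.full((2, 3, 3), 7.0))
        m = full_mask(vol)
        assert resegment(vol, m, (-np.inf, np.inf)).voxel_count == m.voxel_count

    def test_range_excluding_all_values_empties_mask(self):
        vol = volume_from_array(np.full((2, 3, 3), 7.0))
        assert resegment(vol, full_mask(vol), (0.0, 5.0)).voxel_count == 0

    def test_sphere_foreground_count_matches_analytic_classification(self):
        # fg=100 inside radius, bg=-50 outside; range [0, 200] keeps fg only
        shape, center, radius = (9, 15, 15), np.array([7.0, 7.0, 4.0]), 5.0
        idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
        centers_xyz = idx[..., ::-1].astype(float)  # spacing 1, x=col, y=row, z=slice
        inside = np.linalg.norm(centers_xyz - center, axis=-1) <= radius
        vol = volume_from_array(np.where(inside, 100.0, -50.0))
        kept = resegment(vol, full_mask(vol), (0.0, 200.0))
        assert kept.voxel_count == int(inside.sum())


class TestResample:
    def test_identity_spacing_preserves_voxels(self):
        rng = np.random.default_rng(0)
        vol = volume_from_array(rng.integers(0, 100, (4, 8, 8)).astype(float))
        m = full_mask(vol)
        vol2, m2 = resample(vol, m, (1.0, 1.0, 1.0))
        assert np.allclose(vol2.voxels, vol.voxels)
        assert np.array_equal(m2.bits, m.bits)

    def test_constant_image_stays_constant_at_any_spacing(self):
        vol = volume_from_array(np.full((4, 8, 8), 3.5))
        vol2, _ = resample(vol, full_mask(vol), (0.6, 1.7, 0.9))
        assert np.allclose(vol2.voxels, 3.5)

    def test_gradient_downsampled_matches_affine_evaluation_at_new_centers(self):
        # value = 2*k + 3*r + 5*c is affine in position, hence trilinear-exact
        k, r, c = np.meshgrid(*[np.arange(n) for n in (8, 8, 8)], indexing="ij")
        vol = volume_from_array((2 * k + 3 * r + 5 * c).astype(float))
        vol2, _ = resample(vol, full_mask(vol), (2.0, 2.0, 2.0))
        k2, r2, c2 = np.meshgrid(*[np.arange(n) for n in vol2.shape], indexing="ij")
        expected = 2 * (2 * k2) + 3 * (2 * r2) + 5 * (2 * c2)
        assert np.allclose(vol2.voxels, expected, atol=1e-9)

    def test_empty_new_grid_is_an_error(self):
        vol = volume_from_array(np.zeros((2, 4, 4)))
        with pytest.raises(ValueError):
            resample(vol, full_mask(vol), (0.0, 1.0, 1.0))


class TestDiscretize:
    def test_fbw_floor_rule_hand_example(self):
        vol = volume_from_array(np.array([[[0.0, 24.0, 25.0, 50.0]]]))
        d = discretize_fbw(vol, full_mask(vol), 25.0)
        assert d.levels.tolist() == [1, 1, 2, 3]
        assert d.ng == 3

    def test_fbw_constant_region_is_single_level(self):
        vol = volume_from_array(np.full((2, 2, 2), 42.0))
        d = discretize_fbw(vol, full_mask(vol), 25.0)
        assert d.ng == 1 and set(d.levels.tolist()) == {1}

    def test_fbw_uniform_0_to_199_gives_eight_equal_bins(self):
        vol = volume_from_array(np.arange(200.0).reshape(2, 10, 10))
        d = discretize_fbw(vol, full_mask(vol), 25.0)
        assert d.ng == 8
        assert d.histogram().tolist() == [25] * 8

    def test_fbc_single_bin_collapses_everything(self):
        vol = volume_from_array(np.arange(8.0).reshape(2, 2, 2))
        assert discretize_fbc(vol, full_mask(vol), 1).ng == 1

    def test_fbc_maximum_maps_to_top_bin_not_overflow(self):
        vol = volume_from_array(np.arange(8.0).reshape(2, 2, 2))
        d = discretize_fbc(vol, full_mask(vol), 4)
        assert d.levels.max() == 4

    def test_fbc_uniform_0_to_99_gives_equal_quartiles(self):
        vol = volume_from_array(np.arange(100.0).reshape(1, 10, 10))
        d = discretize_fbc(vol, full_mask(vol), 4)
        assert d.histogram().tolist() == [25, 25, 25, 25]

    def test_empty_mask_is_an_error(self):
        vol = volume_from_array(np.zeros((2, 2, 2)))
        m = mask_from_bits(vol, np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            discretize_fbw(vol, m, 25.0)

    @given(
        st.lists(st.integers(min_value=-500, max_value=500), min_size=2, max_size=27),
        st.integers(min_value=-1000, max_value=1000),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_levels_are_shift_invariant(self, values, shift):
        arr = np.array(values, dtype=float).reshape(1, 1, -1)
        vol_a, vol_b = volume_from_array(arr), volume_from_array(arr + shift)
        ma, mb = full_mask(vol_a), full_mask(vol_b)
        for disc, arg in ((discretize_fbw, 25.0), (discretize_fbc, 4)):
            da, db = disc(vol_a, ma, arg), disc(vol_b, mb, arg)
            assert da.levels.tolist() == db.levels.tolist()

    @given(st.lists(st.floats(min_value=-1e3, max_value=1e3), min_size=1, max_size=27))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_histogram_accounts_for_every_masked_voxel(self, values):
        arr = np.array(values, dtype=float).reshape(1, 1, -1)
        vol = volume_from_array(arr)
        d = discretize_fbw(vol, full_mask(vol), 7.3)
        assert int(d.histogram().sum()) == d.n_voxels
        p = d.histogram() / d.n_voxels
        assert abs(p.sum() - 1.0) < 1e-12
        assert d.levels.min() == 1 and d.levels.max() == d.ng


class TestConfig:
    def test_exactly_one_discretization_mode(self):
        with pytest.raises(ValueError):
            ExtractionConfig(bin_width=25.0, bin_count=16)
        with pytest.raises(ValueError):
            ExtractionConfig(bin_width=None, bin_count=None)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "bin_count: 16\nreseg_range: [-100, 300]\nenabled_families: [firstorder, glcm]\n"
        )
        cfg = ExtractionConfig.from_yaml(path)
        assert cfg.bin_count == 16 and cfg.bin_width is None
        assert cfg.reseg_range == (-100, 300)
        assert cfg.enabled_families == ("firstorder", "glcm")

    def test_fingerprint_tracks_settings(self):
        a, b = ExtractionConfig(), ExtractionConfig(bin_width=50.0)
        assert a.fingerprint() == ExtractionConfig().fingerprint()
        assert a.fingerprint() != b.fingerprint()
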