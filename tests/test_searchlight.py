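"""Tests of searchlight similarity metrics against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from dediff import searchlight as sl
from dediff.synthetic import (
    BetaSeries,
    SignalParams,
    default_affine,
    generate_betas,
    generate_design,
)

import _oracles as bf
from conftest import small_design_spec


class TestGeometry:
    @pytest.mark.parametrize("radius,voxel,expected", [
        (4.0, 2.0, 33), (2.0, 2.0, 7), (0.0, 2.0, 1), (3.0, 1.5, 33),
    ])
    def test_offset_counts_match_enumeration(self, radius, voxel, expected):
        spec = sl.SearchlightSpec(radius_mm=radius, voxel_size_mm=voxel)
        got = sl.sphere_offsets(spec)
        assert len(got) == expected
        assert sorted(map(tuple, got)) == bf.bf_sphere(radius, voxel)

    def test_negative_radius_raises(self):
        with pytest.raises(ValueError):
            sl.sphere_offsets(sl.SearchlightSpec(radius_mm=-1))


class TestFisherZ:
    def test_fixed_points_and_oddness(self):
        assert sl.fisher_z(0.0) == 0.0
        assert sl.fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
        for r in (0.3, 0.77, 0.999):
            assert sl.fisher_z(-r) == -sl.fisher_z(r)

    def test_clipping_keeps_z_finite(self):
        assert np.isfinite(sl.fisher_z(1.0))
        assert sl.fisher_z(1.0) == pytest.approx(np.arctanh(1 - 1e-7))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            sl.fisher_z(1.5)


def _toy_subject(n_objects=4, n_scenes=2, n_vox=48, seed=0, a_cat=0.2,
                 b_item=0.3, grid=None, td2_equals_td1=False):
    """Small synthetic subject with a 1-voxel-thick grid so every
    searchlight question can be brute-forced."""
    from dediff.synthetic import DesignSpec

    spec = DesignSpec(
        n_objects=n_objects, n_object_targets=0, n_paired=n_objects,
        n_baseline=0, n_scenes=n_scenes, n_scene_targets=0,
        n_object_runs_phase1=2, n_object_runs_phase2=2,
        retrieval_counts={"old_match": n_objects, "old_mismatch": 0,
                          "old_new_scene": 0, "new_objects": 2},
        seed=seed)
    design = generate_design(spec)
    grid = grid or (n_vox, 1, 1)
    params = SignalParams(a_cat=a_cat, b_item=b_item, grid_shape=grid)
    betas = generate_betas(design, params, seed=seed + 1)
    if td2_equals_td1:
        d = design
        td1 = d[(d.phase == "td1") & (d.category == "object")]
        td2 = d[d.phase == "td2"]
        data = betas.data.copy()
        for stim in td1.stimulus_id:
            r1 = betas.rows_for(td1.loc[td1.stimulus_id == stim, "trial_id"])[0]
            r2 = betas.rows_for(td2.loc[td2.stimulus_id == stim, "trial_id"])[0]
            data[r2] = data[r1]
        betas = BetaSeries(data=data, mask=betas.mask, grid_shape=grid,
                           affine=betas.affine, trial_ids=betas.trial_ids)
    return design, betas


def _patterns(betas, frame, vox):
    return betas.data[betas.rows_for(frame["trial_id"])][:, vox].astype(float)


class TestOracleEquality:
    """Package maps must equal an independent O(n^2) double-loop
    implementation to 1e-12 on small instances."""

    def setup_method(self):
        self.design, self.betas = _toy_subject(n_objects=6, n_scenes=2,
                                               grid=(4, 4, 3), seed=2)
        self.spec = sl.SearchlightSpec(radius_mm=2.0, voxel_size_mm=2.0,
                                       min_voxels=1)

    def _frames(self):
        d = self.design
        obj1 = d[(d.phase == "td1") & (d.category == "object")].reset_index(drop=True)
        scn = d[(d.phase == "td1") & (d.category == "scene")].reset_index(drop=True)
        td2 = d[d.phase == "td2"]
        obj2 = td2.set_index("stimulus_id").loc[obj1.stimulus_id].reset_index()
        return obj1, obj2, scn

    def test_item_maps_equal_bruteforce_everywhere(self):
        maps = sl.item_distinctiveness(self.betas, self.design, self.spec)
        obj1, obj2, _ = self._frames()
        grid = self.betas.grid_shape
        for center in np.argwhere(np.ones(grid, bool)):
            vox = bf.bf_neighbors(tuple(center), grid, self.betas.mask, 2.0, 2.0)
            w, b = bf.bf_item_metrics(_patterns(self.betas, obj1, vox),
                                      _patterns(self.betas, obj2, vox))
            flat = np.ravel_multi_index(tuple(center), grid)
            assert maps.within_item[flat] == pytest.approx(w, abs=1e-12)
            assert maps.between_item[flat] == pytest.approx(b, abs=1e-12)
            assert maps.item_diff[flat] == pytest.approx(w - b, abs=1e-12)

    def test_category_maps_equal_bruteforce_everywhere(self):
        maps = sl.category_distinctiveness(self.betas, self.design, self.spec)
        obj1, _, scn = self._frames()
        grid = self.betas.grid_shape
        for center in np.argwhere(np.ones(grid, bool)):
            vox = bf.bf_neighbors(tuple(center), grid, self.betas.mask, 2.0, 2.0)
            w, b = bf.bf_category_metrics(
                _patterns(self.betas, obj1, vox), obj1.run.to_numpy(),
                _patterns(self.betas, scn, vox))
            flat = np.ravel_multi_index(tuple(center), grid)
            assert maps.within_category[flat] == pytest.approx(w, abs=1e-12)
            assert maps.between_category[flat] == pytest.approx(b, abs=1e-12)

    def test_scene_controls_equal_bruteforce(self):
        res = sl.scene_pairing_controls(self.betas, self.design, self.spec)
        assert not res.empty
        obj1, obj2, _ = self._frames()
        keep = obj1.paired_scene_id.notna().to_numpy()
        o1, o2 = obj1[keep].reset_index(drop=True), obj2[keep].reset_index(drop=True)
        grid = self.betas.grid_shape
        for center in np.argwhere(np.ones(grid, bool))[::5]:
            vox = bf.bf_neighbors(tuple(center), grid, self.betas.mask, 2.0, 2.0)
            c1 = bf.bf_scene_contrast(_patterns(self.betas, o1, vox),
                                      o1.run.to_numpy(),
                                      o1.paired_scene_id.to_numpy(float))
            c2 = bf.bf_scene_contrast(_patterns(self.betas, o2, vox),
                                      o2.run.to_numpy(),
                                      o2.paired_scene_id.to_numpy(float))
            flat = np.ravel_multi_index(tuple(center), grid)
            assert res.td1_contrast[flat] == pytest.approx(c1, abs=1e-12)
            assert res.contrast[flat] == pytest.approx(c2 - c1, abs=1e-12)

    def test_trialwise_values_equal_bruteforce(self):
        mask = np.zeros(self.betas.mask.size, bool)
        mask[:30] = True
        obj1, obj2, scn = self._frames()
        vox = np.flatnonzero(mask)
        got_item = sl.trialwise_distinctiveness(self.betas, self.design,
                                                mask, level="item")
        want = bf.bf_trialwise_item(_patterns(self.betas, obj1, vox),
                                    _patterns(self.betas, obj2, vox))
        np.testing.assert_allclose(got_item.to_numpy(), want, atol=1e-12)
        got_cat = sl.trialwise_distinctiveness(self.betas, self.design,
                                               mask, level="category")
        want_cat = bf.bf_trialwise_category(
            _patterns(self.betas, obj1, vox), obj1.run.to_numpy(),
            _patterns(self.betas, scn, vox))
        np.testing.assert_allclose(got_cat.to_numpy(), want_cat, atol=1e-12)


class TestMetricBehavior:
    def test_identical_td2_patterns_maximize_within_item(self):
        design, betas = _toy_subject(n_objects=6, n_vox=40, b_item=0.0,
                                     a_cat=0.0, td2_equals_td1=True, seed=4)
        mask = np.ones(betas.mask.size, bool)
        d = sl.trialwise_distinctiveness(betas, design, mask, level="item")
        assert (d > 5).all()  # z(1 - 1e-7) - small between term

    def test_independent_phases_give_null_item_diff(self):
        design, betas = _toy_subject(n_objects=30, n_vox=60, b_item=0.0,
                                     a_cat=0.0, seed=5)
        mask = np.ones(betas.mask.size, bool)
        d = sl.trialwise_distinctiveness(betas, design, mask, level="item")
        assert abs(d.mean()) < 0.1

    def test_objects_identical_to_scenes_null_category_diff(self):
        design, betas = _toy_subject(n_objects=8, n_scenes=4, n_vox=50,
                                     a_cat=0.0, b_item=0.0, seed=6)
        # same generative distribution for both categories -> expect ~0
        spec = sl.SearchlightSpec(radius_mm=50.0, min_voxels=1)
        maps = sl.category_distinctiveness(betas, design, spec)
        assert abs(np.nanmean(maps.category_diff)) < 0.15

    def test_trial_order_invariance(self, small_subject):
        design, betas, _ = small_subject
        spec = sl.SearchlightSpec()
        a = sl.distinctiveness_maps(betas, design, spec)
        perm = np.random.default_rng(0).permutation(betas.n_trials)
        betas_p = BetaSeries(data=betas.data[perm], mask=betas.mask,
                             grid_shape=betas.grid_shape, affine=betas.affine,
                             trial_ids=betas.trial_ids[perm])
        design_p = design.sample(frac=1.0, random_state=1)
        b = sl.distinctiveness_maps(betas_p, design_p, spec)
        for m in a.METRICS:
            np.testing.assert_allclose(getattr(a, m), getattr(b, m),
                                       atol=1e-12, equal_nan=True)

    def test_min_voxels_invalidates_isolated_centers(self):
        design, betas = _toy_subject(n_objects=4, grid=(5, 5, 5), seed=7)
        mask = np.zeros((5, 5, 5), bool)
        mask[0, 0, 0] = True       # isolated voxel
        mask[2:5, 2:5, 2:5] = True
        betas = BetaSeries(data=betas.data, mask=mask.reshape(-1),
                           grid_shape=(5, 5, 5), affine=betas.affine,
                           trial_ids=betas.trial_ids)
        spec = sl.SearchlightSpec(radius_mm=2.0, min_voxels=5)
        maps = sl.item_distinctiveness(betas, design, spec)
        assert not maps.valid_mask[0]
        center = np.ravel_multi_index((3, 3, 3), (5, 5, 5))
        assert maps.valid_mask[center]

    def test_trialwise_mean_matches_map_at_matching_neighborhood(self):
        design, betas = _toy_subject(n_objects=6, grid=(4, 4, 4), seed=8)
        spec = sl.SearchlightSpec(radius_mm=2.0, min_voxels=1)
        maps = sl.item_distinctiveness(betas, design, spec)
        center = (2, 2, 2)
        vox = bf.bf_neighbors(center, (4, 4, 4), betas.mask, 2.0, 2.0)
        mask = np.zeros(betas.mask.size, bool)
        mask[vox] = True
        d = sl.trialwise_distinctiveness(betas, design, mask, level="item")
        flat = np.ravel_multi_index(center, (4, 4, 4))
        assert d.mean() == pytest.approx(maps.item_diff[flat], abs=1e-10)

    def test_group_valid_mask_is_intersection(self):
        design, betas = _toy_subject(n_objects=4, grid=(4, 4, 4), seed=9)
        spec = sl.SearchlightSpec(radius_mm=2.0, min_voxels=1)
        m1 = sl.item_distinctiveness(betas, design, spec)
        m2 = sl.item_distinctiveness(betas, design, spec)
        m2.valid_mask = m2.valid_mask.copy()
        m2.valid_mask[5] = False
        inter = sl.group_valid_mask([m1, m2])
        assert not inter[5]
        assert inter.sum() == m1.valid_mask.sum() - 1

    def test_scene_control_null_when_pairing_agnostic(self):
        # generator ties nothing to the pairing, so the expected contrast
        # is zero; check the map mean is small
        design, betas = _toy_subject(n_objects=12, n_scenes=4, n_vox=64,
                                     a_cat=0.3, b_item=0.2, seed=10)
        spec = sl.SearchlightSpec(radius_mm=50.0, min_voxels=1)
        res = sl.scene_pairing_controls(betas, design, spec)
        assert abs(np.nanmean(res.contrast)) < 0.1

    def test_control_variant_with_no_qualifying_scenes_flags_empty(self):
        design, betas = _toy_subject(n_objects=4, n_scenes=2, seed=11)
        # no retrieval outcomes -> no correctly remembered pairs
        res = sl.scene_pairing_controls(betas, design,
                                        sl.SearchlightSpec(min_voxels=1),
                                        variant="pair_correct_only")
        assert res.empty
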