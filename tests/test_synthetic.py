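"""Tests of the study-design and voxel-signal generators."""

import numpy as np
import pandas as pd
import pytest

from dediff.synthetic import (
    DesignError,
    DesignSpec,
    MemoryModel,
    SignalParams,
    _sigmoid,
    estimate_signal_fractions,
    generate_betas,
    generate_cohort,
    generate_design,
    generate_memory,
    region_trial_distinctiveness,
)

from conftest import small_design_spec


class TestDesign:
    def test_default_structure_matches_study(self):
        d = generate_design(DesignSpec())
        td1_obj = d[(d.phase == "td1") & (d.category == "object")]
        assert td1_obj.groupby("run").size().tolist() == [106, 107, 107]
        assert int(td1_obj.is_target.sum()) == 20
        ret = d[d.phase == "retrieval"]
        counts = ret.retrieval_condition.value_counts()
        assert (counts["old_match"], counts["old_mismatch"],
                counts["old_new_scene"]) == (100, 100, 50)
        assert counts["new"] == 150
        # 250 paired objects carry a scene pairing
        paired = td1_obj[td1_obj.paired_scene_id.notna()]
        assert len(paired) == 250
        scenes = d[(d.phase == "td1") & (d.category == "scene")]
        assert len(scenes) == 60 and int(scenes.is_target.sum()) == 10

    def test_smallest_even_split(self):
        spec = DesignSpec(
            n_objects=4, n_object_targets=0, n_paired=4, n_baseline=0,
            n_scenes=2, n_scene_targets=0,
            n_object_runs_phase1=2, n_object_runs_phase2=2,
            retrieval_counts={"old_match": 2, "old_mismatch": 1,
                              "old_new_scene": 1, "new_objects": 2},
            seed=0)
        d = generate_design(spec)
        td1 = d[(d.phase == "td1") & (d.category == "object")]
        assert td1.groupby("run").size().tolist() == [2, 2]
        td2 = d[d.phase == "td2"]
        assert set(td1.stimulus_id) == set(td2.stimulus_id) == {0, 1, 2, 3}

    def test_structural_invariants(self, small_design):
        d = small_design
        nontarget = d[(d.phase == "td1") & (d.category == "object")
                      & ~d.is_target].stimulus_id
        td2 = d[d.phase == "td2"]
        # every TD1 object (non-target and target alike) reappears once in TD2
        assert td2.stimulus_id.value_counts().max() == 1
        assert set(nontarget) <= set(td2.stimulus_id)
        assert (d[d.category == "scene"].phase == "td1").all()
        # run labels unique across phases
        by_phase = d.groupby("phase")["run"].unique()
        all_runs = np.concatenate(list(by_phase))
        assert len(all_runs) == len(set(all_runs))
        # targets carry no memory outcome
        assert (d[d.is_target].item_outcome == "none").all()

    def test_deterministic_given_seed(self):
        a = generate_design(small_design_spec(seed=5))
        b = generate_design(small_design_spec(seed=5))
        pd.testing.assert_frame_equal(a, b)
        c = generate_design(small_design_spec(seed=6))
        assert not a.stimulus_id.equals(c.stimulus_id)

    def test_inconsistent_counts_raise(self):
        with pytest.raises(DesignError, match="n_objects"):
            DesignSpec(n_objects=10, n_object_targets=2, n_paired=5,
                       n_baseline=5).validate()
        with pytest.raises(DesignError, match="n_paired"):
            DesignSpec(retrieval_counts={"old_match": 1, "old_mismatch": 1,
                                         "old_new_scene": 1,
                                         "new_objects": 1}).validate()


class TestBetas:
    def _mean_corrs(self, a_cat, b_item, n_vox, seed=0):
        spec = small_design_spec()
        d = generate_design(spec)
        shape = (n_vox, 1, 1)
        p = SignalParams(a_cat=a_cat, b_item=b_item, grid_shape=shape)
        b = generate_betas(d, p, seed=seed)
        a_hat, b_hat = estimate_signal_fractions(b, d, p.region_indices())
        return a_hat, b_hat

    def test_pure_item_signal_gives_perfect_stability(self, small_design):
        p = SignalParams(a_cat=0.0, b_item=1.0, grid_shape=(50, 1, 1))
        b = generate_betas(small_design, p, seed=1)
        a_hat, b_hat = estimate_signal_fractions(b, small_design,
                                                 p.region_indices())
        assert a_hat == pytest.approx(0.0, abs=0.05)
        # atanh clipping caps z at ~8.3; tanh of that is 1 to float precision
        assert a_hat + b_hat == pytest.approx(1.0, abs=1e-6)

    def test_pure_noise_gives_zero_correlations(self):
        a_hat, b_hat = self._mean_corrs(0.0, 0.0, 20000)
        assert a_hat == pytest.approx(0.0, abs=0.02)
        assert b_hat == pytest.approx(0.0, abs=0.02)

    def test_variance_fractions_set_expected_correlations(self):
        # same-category r -> a_cat, same-item r -> a_cat + b_item
        a_hat, b_hat = self._mean_corrs(0.3, 0.2, 100000)
        assert a_hat == pytest.approx(0.30, abs=0.02)
        assert a_hat + b_hat == pytest.approx(0.50, abs=0.02)

    def test_parameter_recovery_at_5000_voxels(self):
        a_hat, b_hat = self._mean_corrs(0.25, 0.15, 5000, seed=2)
        assert a_hat == pytest.approx(0.25, abs=0.03)
        assert b_hat == pytest.approx(0.15, abs=0.03)

    def test_stability_parameter_lowers_within_item_similarity(self, small_design):
        shared = dict(a_cat=0.1, b_item=0.5, grid_shape=(5000, 1, 1))
        stable = SignalParams(**shared, stability=1.0)
        unstable = SignalParams(**shared, stability=0.5)
        bs = generate_betas(small_design, stable, seed=3)
        bu = generate_betas(small_design, unstable, seed=3)
        _, b_s = estimate_signal_fractions(bs, small_design, stable.region_indices())
        _, b_u = estimate_signal_fractions(bu, small_design, stable.region_indices())
        # expected within-item shared variance drops from b to rho*b
        assert b_u == pytest.approx(0.5 * b_s, abs=0.03)

    def test_invalid_fractions_raise(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            SignalParams(a_cat=0.7, b_item=0.5).validate()

    def test_out_of_region_voxels_are_pure_noise(self, small_subject):
        design, betas, params = small_subject
        outside = np.setdiff1d(np.arange(betas.mask.size),
                               params.region_indices())[:500]
        a_hat, b_hat = estimate_signal_fractions(betas, design, outside)
        assert abs(a_hat) < 0.1 and abs(b_hat) < 0.15


class TestMemory:
    def _distinctiveness(self, design, rng, sd=1.0):
        paired = design[(design.phase == "retrieval")
                        & design.retrieval_condition.astype(str).str.startswith("old")]
        idx = pd.Index(sorted(paired.stimulus_id), name="stimulus_id")
        return pd.DataFrame({"d_item": sd * rng.standard_normal(len(idx)),
                             "d_cat": sd * rng.standard_normal(len(idx))},
                            index=idx)

    def test_null_model_hit_rate_near_half(self):
        spec = DesignSpec(seed=1)
        design = generate_design(spec)
        d = self._distinctiveness(design, np.random.default_rng(0))
        out = generate_memory(design, d, MemoryModel(beta0=0.0, seed=4))
        old = out[(out.phase == "retrieval")
                  & out.item_outcome.isin(["hit", "miss"])]
        rate = (old.item_outcome == "hit").mean()
        se = np.sqrt(0.25 / len(old))
        assert abs(rate - 0.5) < 3 * se

    def test_saturated_intercept_gives_all_hits(self, small_design):
        d = self._distinctiveness(small_design, np.random.default_rng(0))
        out = generate_memory(small_design, d,
                              MemoryModel(beta0=50.0, seed=0))
        old = out[(out.phase == "retrieval")
                  & out.item_outcome.isin(["hit", "miss"])]
        assert (old.item_outcome == "hit").all()

    def test_category_slope_separates_outcome_groups(self):
        # Monte-Carlo oracle at n = 1e5: P(hit) = sigmoid(2 d), d ~ N(0,1)
        rng = np.random.default_rng(11)
        n = 100_000
        d = rng.standard_normal(n)
        hits = rng.random(n) < _sigmoid(2.0 * d)
        oracle_gap = d[hits].mean() - d[~hits].mean()
        assert abs(hits.mean() - 0.5) < 0.01  # symmetric around chance

        spec = DesignSpec(seed=2)
        design = generate_design(spec)
        dd = self._distinctiveness(design, rng)
        out = generate_memory(design, dd,
                              MemoryModel(beta1_cat=2.0, seed=5))
        old = out[(out.phase == "retrieval")
                  & out.item_outcome.isin(["hit", "miss"])]
        merged = old.merge(dd, left_on="stimulus_id", right_index=True)
        gap = (merged.loc[merged.item_outcome == "hit", "d_cat"].mean()
               - merged.loc[merged.item_outcome == "miss", "d_cat"].mean())
        # 250 trials: compare to the large-n oracle loosely
        assert gap == pytest.approx(oracle_gap, abs=0.35)
        assert gap > 0.3

    def test_missing_distinctiveness_raises(self, small_design):
        d = self._distinctiveness(small_design, np.random.default_rng(0)).iloc[:3]
        with pytest.raises(ValueError, match="missing distinctiveness"):
            generate_memory(small_design, d, MemoryModel())


class TestCohort:
    def _group_params(self, grid=(6, 6, 6)):
        return {
            "young": SignalParams(a_cat=0.1, b_item=0.1, grid_shape=grid),
            "old": SignalParams(a_cat=0.05, b_item=0.05, grid_shape=grid),
        }

    def test_group_sizes(self):
        subs = generate_cohort(3, 4, self._group_params(), seed=1,
                               design_spec=small_design_spec())
        assert len(subs) == 7
        assert sum(s.group == "young" for s in subs) == 3
        assert sum(s.group == "old" for s in subs) == 4
        subs0 = generate_cohort(0, 2, self._group_params(), seed=1,
                                design_spec=small_design_spec())
        assert {s.group for s in subs0} == {"old"}

    def test_same_master_seed_bit_identical(self):
        kwargs = dict(design_spec=small_design_spec(),
                      memory_model=MemoryModel(beta1_item=2.0),
                      param_jitter=0.03)
        a = generate_cohort(2, 2, self._group_params(), seed=9, **kwargs)
        b = generate_cohort(2, 2, self._group_params(), seed=9, **kwargs)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.betas.data, sb.betas.data)
            pd.testing.assert_frame_equal(sa.design, sb.design)

    def test_memory_outcomes_coupled_to_distinctiveness(self):
        grid = (8, 8, 8)
        reg = np.zeros(grid, bool)
        reg[2:6, 2:6, 2:6] = True
        gp = {g: SignalParams(a_cat=0.15, b_item=0.15, grid_shape=grid,
                              signal_region=np.flatnonzero(reg.reshape(-1)))
              for g in ("young", "old")}
        subs = generate_cohort(
            2, 2, gp, seed=3, design_spec=small_design_spec(),
            memory_model=MemoryModel(beta0=0.0, beta1_item=8.0))
        gaps = []
        for s in subs:
            d = region_trial_distinctiveness(s.betas, s.design,
                                             gp["young"].region_indices())
            old = s.design[(s.design.phase == "retrieval")
                           & s.design.item_outcome.isin(["hit", "miss"])]
            merged = old.merge(d, left_on="stimulus_id", right_index=True)
            if merged.item_outcome.nunique() == 2:
                gaps.append(
                    merged.loc[merged.item_outcome == "hit", "d_item"].mean()
                    - merged.loc[merged.item_outcome == "miss", "d_item"].mean())
        assert np.mean(gaps) > 0
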