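"""End-to-end driver: simulate a cohort, run searchlight similarity,
group cluster statistics, cluster back-projection, PLSC and the
distinctiveness-memory analyses, emitting one machine-readable report.

Every stochastic stage draws from an explicit seed in the configuration,
so an identical config yields a byte-identical report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, clusterperm, plsc as plsc_mod, searchlight
from .io import PipelineConfig, to_jsonable
from .synthetic import (
    DesignSpec,
    MemoryModel,
    SignalParams,
    generate_cohort,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


def _design_spec(cfg: PipelineConfig) -> DesignSpec:
    return DesignSpec(
        n_objects=cfg.n_objects, n_object_targets=cfg.n_object_targets,
        n_paired=cfg.n_paired, n_baseline=cfg.n_baseline,
        n_scenes=cfg.n_scenes, n_scene_targets=cfg.n_scene_targets,
        retrieval_counts=dict(cfg.retrieval_counts),
    )


def _group_params(cfg: PipelineConfig) -> dict[str, SignalParams]:
    region = cfg.region_indices()
    common = dict(grid_shape=tuple(cfg.grid_shape),
                  voxel_size_mm=cfg.voxel_size_mm,
                  signal_region=region, stability=cfg.stability)
    return {
        "young": SignalParams(a_cat=cfg.a_cat_young, b_item=cfg.b_item_young,
                              **common),
        "old": SignalParams(a_cat=cfg.a_cat_old, b_item=cfg.b_item_old,
                            **common),
    }


def _cluster_table(result: clusterperm.ClusterResult) -> list[dict]:
    return [
        {"size": c.size, "mass": c.mass, "sign": c.sign,
         "peak_voxel": c.peak_voxel, "p_mc": c.p_mc,
         "significant": c.significant}
        for c in result.clusters
    ]


def _stack(maps_list, metric):
    return np.vstack([getattr(m, metric) for m in maps_list])


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> dict:
    """Execute the full analysis on a synthetic cohort; returns (and
    optionally writes) the JSON-ready report."""
    report: dict = {"config": json.loads(cfg.to_json()), "stages": {}}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    def checkpoint(stage: str, payload: dict):
        report["stages"][stage] = to_jsonable(payload)
        if out_path is not None:
            (out_path / "report.json").write_text(
                json.dumps(to_jsonable(report), indent=2, sort_keys=True) + "\n")

    # --- simulate -----------------------------------------------------
    try:
        model = MemoryModel(
            beta0=cfg.memory_beta0, beta1_item=cfg.memory_beta1_item,
            beta1_cat=cfg.memory_beta1_cat,
            specificity=cfg.memory_specificity, seed=cfg.seeds.memory)
        subjects = generate_cohort(
            cfg.n_young, cfg.n_old, _group_params(cfg), seed=cfg.seeds.betas,
            design_spec=replace(_design_spec(cfg), seed=cfg.seeds.design),
            memory_model=model, param_jitter=cfg.param_jitter)
    except Exception as exc:
        raise StageError(f"simulate: {exc}") from exc

    # --- behavior -----------------------------------------------------
    try:
        scores = {s.subject_id: behavior.memory_scores(s.design) for s in subjects}
        behav = pd.DataFrame([
            {"subject": s.subject_id, "group": s.group,
             "pr_item": scores[s.subject_id].pr_item,
             "pr_pair": scores[s.subject_id].pr_pair,
             "bias": scores[s.subject_id].bias,
             "above_chance": scores[s.subject_id].above_chance}
            for s in subjects
        ])
        checkpoint("behavior", {
            "chance_level": scores[subjects[0].subject_id].chance,
            "per_subject": behav.to_dict(orient="records"),
            "group_means": behav.groupby("group")[["pr_item", "pr_pair"]]
                                .mean().to_dict(),
        })
    except Exception as exc:
        raise StageError(f"behavior: {exc}") from exc

    # --- searchlight --------------------------------------------------
    try:
        spec = searchlight.SearchlightSpec(
            radius_mm=cfg.radius_mm, voxel_size_mm=cfg.voxel_size_mm,
            min_voxels=cfg.min_voxels)
        maps = [searchlight.distinctiveness_maps(s.betas, s.design, spec,
                                                 s.subject_id)
                for s in subjects]
        gmask = searchlight.group_valid_mask(maps)
        checkpoint("searchlight", {"n_valid_group_voxels": int(gmask.sum())})
    except Exception as exc:
        raise StageError(f"searchlight: {exc}") from exc

    # --- group cluster statistics ------------------------------------
    try:
        grid = tuple(cfg.grid_shape)
        young = [m for m, s in zip(maps, subjects) if s.group == "young"]
        old = [m for m, s in zip(maps, subjects) if s.group == "old"]
        within_group = {}
        for gname, gmaps in (("young", young), ("old", old)):
            for level, (w, b) in {
                "item": ("within_item", "between_item"),
                "category": ("within_category", "between_category"),
            }.items():
                res = clusterperm.cluster_permutation_test(
                    _stack(gmaps, w), _stack(gmaps, b),
                    clusterperm.DEPENDENT, grid, alpha=cfg.alpha,
                    min_size=cfg.min_size, connectivity=cfg.connectivity,
                    n_perm=cfg.n_perm, seed=cfg.seeds.permutation)
                within_group[f"{gname}_{level}"] = _cluster_table(res)
        age_results = {}
        for level, metric in (("item", "item_diff"),
                              ("category", "category_diff")):
            age_results[level] = clusterperm.cluster_permutation_test(
                _stack(young, metric), _stack(old, metric),
                clusterperm.INDEPENDENT, grid, alpha=cfg.alpha,
                min_size=cfg.min_size, connectivity=cfg.connectivity,
                n_perm=cfg.n_perm, seed=cfg.seeds.permutation)
        checkpoint("cluster_stats", {
            "within_group": within_group,
            "age_item": _cluster_table(age_results["item"]),
            "age_category": _cluster_table(age_results["category"]),
        })
    except Exception as exc:
        raise StageError(f"cluster_stats: {exc}") from exc

    # --- cluster masks for extraction ---------------------------------
    # up to two item-level and one category-level age clusters; fall back
    # to the largest cluster, then to the configured signal region, so the
    # downstream analyses always run
    def pick_masks(result, n):
        chosen = [c for c in result.significant_clusters if c.size >= 5][:n]
        if not chosen:
            # largest non-significant cluster still usable as a pattern mask
            big = [c for c in result.clusters if c.size >= 5]
            if big:
                chosen = [max(big, key=lambda c: c.size)]
        return [result.cluster_mask(result.clusters.index(c)) for c in chosen]

    region_mask = np.zeros(int(np.prod(cfg.grid_shape)), dtype=bool)
    region_mask[cfg.region_indices()] = True
    item_masks = pick_masks(age_results["item"], 2) or [region_mask]
    cat_masks = pick_masks(age_results["category"], 1) or [region_mask]
    cluster_masks = ([("item", i, m) for i, m in enumerate(item_masks)]
                     + [("category", i, m) for i, m in enumerate(cat_masks)])

    # --- PLSC ----------------------------------------------------------
    try:
        neural_cols = {}
        for level, i, mask in cluster_masks:
            metric = "item_diff" if level == "item" else "category_diff"
            neural_cols[f"{level}_cluster{i + 1}"] = [
                searchlight.mask_mean(getattr(m, metric), mask) for m in maps]
        frame = behav.copy()
        for name, vals in neural_cols.items():
            frame[name] = vals
        inp = plsc_mod.plsc_input_from_frame(
            frame, ["pr_item", "pr_pair"], list(neural_cols), "group")
        pres = plsc_mod.plsc_analysis(
            inp, n_perm=cfg.n_perm, n_boot=cfg.n_boot,
            seed=cfg.seeds.bootstrap,
            standardize_within_group=cfg.standardize_within_group)
        checkpoint("plsc", {
            "singular_values": pres.singular_values,
            "p_perm": pres.p_perm,
            "neural_saliences_lv1": dict(zip(pres.x_names,
                                             pres.neural_saliences[:, 0])),
            "behavior_saliences_lv1": dict(zip(pres.y_names,
                                               pres.behavior_saliences[:, 0])),
            "bootstrap_ratios": dict(zip(pres.x_names, pres.bootstrap_ratios)),
            "group_latent_correlations": pres.group_latent_correlations,
        })
    except Exception as exc:
        raise StageError(f"plsc: {exc}") from exc

    # --- trial-wise distinctiveness-memory association -----------------
    try:
        assoc = {}
        trial_frames = {}
        for level, i, mask in cluster_masks:
            rows = []
            for s in subjects:
                d = searchlight.trialwise_distinctiveness(
                    s.betas, s.design, mask, level=level)
                ret = s.design[(s.design["phase"] == "retrieval")
                               & s.design["item_outcome"].isin(["hit", "miss"])]
                for stim, outcome in zip(ret["stimulus_id"], ret["item_outcome"]):
                    if stim in d.index:
                        rows.append({
                            "subject": s.subject_id, "group": s.group,
                            "stimulus_id": int(stim),
                            "distinctiveness": float(d.loc[stim]),
                            "memory": 1.0 if outcome == "hit" else 0.0,
                        })
            name = f"{level}_cluster{i + 1}"
            trial_frames[name] = pd.DataFrame(rows)
            ts = behavior.twostage_association(
                trial_frames[name], "distinctiveness", "memory", binary=True)
            assoc[name] = {
                "mean_slope": ts.mean_slope, "t_main": ts.t_main,
                "p_main": ts.p_main, "t_group": ts.t_group,
                "p_group": ts.p_group, "n_clipped": ts.n_clipped,
            }
        checkpoint("trialwise_memory", assoc)
    except Exception as exc:
        raise StageError(f"trialwise_memory: {exc}") from exc

    # --- item ~ category across levels ---------------------------------
    try:
        item_mask = item_masks[0]
        cat_mask = cat_masks[0]
        rows = []
        for s in subjects:
            di = searchlight.trialwise_distinctiveness(
                s.betas, s.design, item_mask, level="item")
            dc = searchlight.trialwise_distinctiveness(
                s.betas, s.design, cat_mask, level="category")
            common = di.index.intersection(dc.index)
            for stim in common:
                rows.append({"subject": s.subject_id, "group": s.group,
                             "d_item": float(di.loc[stim]),
                             "d_cat": float(dc.loc[stim])})
        levels_frame = pd.DataFrame(rows)
        ts = behavior.twostage_association(
            levels_frame, "d_cat", "d_item", binary=False)
        checkpoint("levels_association", {
            "mean_slope": ts.mean_slope, "t_main": ts.t_main,
            "p_main": ts.p_main, "t_group": ts.t_group, "p_group": ts.p_group,
        })
    except Exception as exc:
        raise StageError(f"levels_association: {exc}") from exc

    # --- subsequent-memory split ---------------------------------------
    if cfg.memory_split:
        try:
            split_rem, split_forg, kept = [], [], []
            for s in subjects:
                try:
                    sm = behavior.subsequent_memory_maps(
                        s.betas, s.design, spec, s.subject_id)
                except behavior.SubsetTooSmall as exc:
                    logger.info("memory split: %s", exc)
                    continue
                split_rem.append(sm.remembered)
                split_forg.append(sm.forgotten)
                kept.append(s)
            sm_report = {"n_subjects": len(kept)}
            if len(kept) >= 4:
                res = clusterperm.cluster_permutation_test(
                    _stack(split_rem, "category_diff"),
                    _stack(split_forg, "category_diff"),
                    clusterperm.DEPENDENT, grid, alpha=cfg.alpha,
                    min_size=cfg.min_size, connectivity=cfg.connectivity,
                    n_perm=cfg.n_perm, seed=cfg.seeds.permutation)
                sm_report["category_memory_effect"] = _cluster_table(res)
                diffs = (_stack(split_rem, "category_diff")
                         - _stack(split_forg, "category_diff"))
                g = np.array([s.group for s in kept])
                if (g == "young").sum() >= 2 and (g == "old").sum() >= 2:
                    res_age = clusterperm.cluster_permutation_test(
                        diffs[g == "young"], diffs[g == "old"],
                        clusterperm.INDEPENDENT, grid, alpha=cfg.alpha,
                        min_size=cfg.min_size, connectivity=cfg.connectivity,
                        n_perm=cfg.n_perm, seed=cfg.seeds.permutation)
                    sm_report["age_difference"] = _cluster_table(res_age)
            checkpoint("memory_split", sm_report)
        except Exception as exc:
            raise StageError(f"memory_split: {exc}") from exc

    report["seeds"] = to_jsonable(json.loads(json.dumps(
        report["config"]["seeds"])))
    final = to_jsonable(report)
    if out_path is not None:
        (out_path / "report.json").write_text(
            json.dumps(final, indent=2, sort_keys=True) + "\n")
    return final
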