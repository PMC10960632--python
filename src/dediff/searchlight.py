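"""Searchlight pattern-similarity maps of item- and category-level
distinctiveness.

All similarity values are Fisher z-transformed Pearson correlations
between trial patterns over the voxels of a small spherical searchlight
(or over an explicit mask for trial-wise extraction).  Similarity is only
assessed between trials from different runs, which controls for
within-run temporal autocorrelation of the hemodynamic signal:

* item level (cross-phase): within-item = z(r) of the same object's TD1
  and TD2 patterns; between-item = mean z over all TD1-object x
  TD2-object pairs excluding the same-object pairs; distinctiveness is
  the difference.
* category level (TD1 only): within-category = mean z over object-object
  pairs from different TD1 runs; between-category = mean z over all
  object-scene pairs; distinctiveness is the difference.

Target-detection trials are excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic import TD1, TD2, BetaSeries

R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class SearchlightSpec:
    """Spherical searchlight geometry on an isotropic voxel grid."""

    radius_mm: float = 4.0
    voxel_size_mm: float = 2.0
    min_voxels: int = 5


def sphere_offsets(spec: SearchlightSpec) -> np.ndarray:
    """All integer voxel displacements within radius_mm of the center.

    Returns an (n, 3) int array; the center (0,0,0) is always included.
    """
    if spec.radius_mm < 0:
        raise ValueError("radius_mm must be non-negative")
    r_vox = spec.radius_mm / spec.voxel_size_mm
    m = int(np.floor(r_vox))
    axis = np.arange(-m, m + 1)
    dx, dy, dz = np.meshgrid(axis, axis, axis, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= r_vox**2 + 1e-9
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


def fisher_z(r):
    """Fisher z transform atanh(r), with r clipped at +/-(1 - 1e-7).

    Accepts scalars or arrays; raises on |r| > 1 beyond float tolerance.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-9):
        raise ValueError("correlation outside [-1, 1]")
    out = np.arctanh(np.clip(arr, -R_CLIP, R_CLIP))
    return out if arr.ndim else float(out)


def _normalize_rows(X: np.ndarray) -> np.ndarray:
    """Center and unit-norm each row, so X @ X.T gives Pearson r."""
    X = np.asarray(X, dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return X / norms


def pairwise_z(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Fisher-z Pearson correlations between rows of A and rows of B.

    Rows are patterns over a common voxel set.  NaN voxels are handled by
    pairwise-complete deletion (a voxel is dropped for a pair if missing
    in either trial); rows missing more than half of the voxels yield NaN
    against every partner.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValueError("pattern length mismatch")
    if not (np.isnan(A).any() or np.isnan(B).any()):
        return np.arctanh(np.clip(_normalize_rows(A) @ _normalize_rows(B).T,
                                  -R_CLIP, R_CLIP))
    k = A.shape[1]
    bad_a = np.isnan(A).sum(axis=1) > 0.5 * k
    bad_b = np.isnan(B).sum(axis=1) > 0.5 * k
    Z = np.full((A.shape[0], B.shape[0]), np.nan)
    for i in range(A.shape[0]):
        if bad_a[i]:
            continue
        for j in range(B.shape[0]):
            if bad_b[j]:
                continue
            ok = ~(np.isnan(A[i]) | np.isnan(B[j]))
            if ok.sum() < 3:
                continue
            a, b = A[i, ok], B[j, ok]
            a = a - a.mean()
            b = b - b.mean()
            denom = np.linalg.norm(a) * np.linalg.norm(b)
            if denom == 0:
                continue
            Z[i, j] = np.arctanh(np.clip(a @ b / denom, -R_CLIP, R_CLIP))
    return Z


@dataclass
class DistinctivenessMaps:
    """Per-subject voxel maps of mean similarity and their differences.

    Flat arrays over the grid; NaN at invalid centers.  item_diff =
    within_item - between_item, category_diff likewise, wherever valid.
    """

    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    subject_id: str = ""
    valid_mask: np.ndarray | None = None
    within_item: np.ndarray | None = None
    between_item: np.ndarray | None = None
    item_diff: np.ndarray | None = None
    within_category: np.ndarray | None = None
    between_category: np.ndarray | None = None
    category_diff: np.ndarray | None = None

    METRICS = ("within_item", "between_item", "item_diff",
               "within_category", "between_category", "category_diff")

    def volume(self, metric: str) -> np.ndarray:
        arr = getattr(self, metric)
        return arr.reshape(self.grid_shape)


# ---------------------------------------------------------------------------
# trial selection helpers
# ---------------------------------------------------------------------------

def _select(design: pd.DataFrame, phase: str, category: str) -> pd.DataFrame:
    sel = design[(design["phase"] == phase) & (design["category"] == category)
                 & (~design["is_target"])]
    return sel.reset_index(drop=True)


def _aligned_object_trials(design: pd.DataFrame,
                           objects: Sequence[int] | None = None):
    """Non-target object trials of TD1 and TD2, TD2 reordered to match
    TD1's stimulus order.  Optionally restricted to a stimulus subset."""
    obj1 = _select(design, TD1, "object")
    obj2 = _select(design, TD2, "object")
    if objects is not None:
        keep = set(int(o) for o in objects)
        obj1 = obj1[obj1["stimulus_id"].isin(keep)].reset_index(drop=True)
        obj2 = obj2[obj2["stimulus_id"].isin(keep)].reset_index(drop=True)
    if set(obj1["stimulus_id"]) != set(obj2["stimulus_id"]):
        raise ValueError("every non-target object must appear in TD1 and TD2")
    obj2 = obj2.set_index("stimulus_id").loc[obj1["stimulus_id"]].reset_index()
    return obj1, obj2


def _neighborhoods(betas: BetaSeries, spec: SearchlightSpec):
    """Per in-mask center: flat indices of in-mask neighbors.

    Returns (centers, neighbor_lists, valid) where invalid centers have
    fewer than ``min_voxels`` usable neighbors.
    """
    shape = betas.grid_shape
    mask3 = betas.mask.reshape(shape)
    offsets = sphere_offsets(spec)
    centers = np.argwhere(mask3)
    nbr_lists, valid = [], []
    for c in centers:
        pts = c[None, :] + offsets
        ok = np.all((pts >= 0) & (pts < np.array(shape)), axis=1)
        pts = pts[ok]
        ok2 = mask3[pts[:, 0], pts[:, 1], pts[:, 2]]
        pts = pts[ok2]
        flat = np.ravel_multi_index((pts[:, 0], pts[:, 1], pts[:, 2]), shape)
        nbr_lists.append(flat)
        valid.append(len(flat) >= spec.min_voxels)
    return centers, nbr_lists, np.asarray(valid, dtype=bool)


def _sweep(betas: BetaSeries, spec: SearchlightSpec, row_groups: dict,
           reducers: dict) -> dict:
    """Generic searchlight sweep.

    ``row_groups`` maps group name -> BetaSeries row indices; ``reducers``
    maps output name -> callable(patterns: dict of normalized (n, k)
    blocks) -> scalar or tuple.  Returns object arrays (None at invalid
    centers) plus '_valid' (flat boolean).
    """
    n_vox = betas.mask.size
    centers, nbr_lists, valid = _neighborhoods(betas, spec)
    out = {name: np.full(n_vox, None, dtype=object) for name in reducers}
    valid_flat = np.zeros(n_vox, dtype=bool)
    data = betas.data.astype(float)
    shape = betas.grid_shape
    for idx, (c, nbrs) in enumerate(zip(centers, nbr_lists)):
        if not valid[idx]:
            continue
        flat_c = np.ravel_multi_index(tuple(c), shape)
        blocks = {}
        skip = False
        for name, rows in row_groups.items():
            X = data[rows][:, nbrs]
            if np.isnan(X).any():
                frac = np.isnan(X).mean(axis=1)
                if np.all(frac > 0.5):
                    skip = True
                    break
                blocks[name] = X
            else:
                blocks[name] = _normalize_rows(X)
        if skip:
            continue
        valid_flat[flat_c] = True
        for name, fn in reducers.items():
            out[name][flat_c] = fn(blocks)
    out["_valid"] = valid_flat
    return out


def _zblock(blocks: dict, a: str, b: str) -> np.ndarray:
    A, B = blocks[a], blocks[b]
    if np.isnan(A).any() or np.isnan(B).any():
        return pairwise_z(A, B)
    return np.arctanh(np.clip(A @ B.T, -R_CLIP, R_CLIP))


def item_distinctiveness(
    betas: BetaSeries,
    design: pd.DataFrame,
    spec: SearchlightSpec = SearchlightSpec(),
    objects: Sequence[int] | None = None,
) -> DistinctivenessMaps:
    """Searchlight maps of within-item / between-item similarity and their
    difference.  All pairs are TD1 x TD2, hence cross-run by design."""
    obj1, obj2 = _aligned_object_trials(design, objects)
    n = len(obj1)
    if n < 2:
        raise ValueError("need at least two objects for between-item pairs")
    rows = {
        "td1": betas.rows_for(obj1["trial_id"]),
        "td2": betas.rows_for(obj2["trial_id"]),
    }

    def reduce_maps(blocks):
        Z = _zblock(blocks, "td1", "td2")
        within = np.nanmean(np.diag(Z))
        off = Z.copy()
        np.fill_diagonal(off, np.nan)
        return within, np.nanmean(off)

    res = _sweep(betas, spec, rows, {"pair": reduce_maps})
    within = np.full(betas.mask.size, np.nan)
    between = np.full(betas.mask.size, np.nan)
    ok = res["_valid"]
    for i in np.flatnonzero(ok):
        within[i], between[i] = res["pair"][i]
    maps = DistinctivenessMaps(
        grid_shape=betas.grid_shape, affine=betas.affine,
        valid_mask=ok, within_item=within, between_item=between,
        item_diff=within - between,
    )
    return maps


def category_distinctiveness(
    betas: BetaSeries,
    design: pd.DataFrame,
    spec: SearchlightSpec = SearchlightSpec(),
    objects: Sequence[int] | None = None,
) -> DistinctivenessMaps:
    """Searchlight maps of within-category (object-object, different TD1
    runs) and between-category (object-scene) similarity and their
    difference."""
    obj1 = _select(design, TD1, "object")
    if objects is not None:
        keep = set(int(o) for o in objects)
        obj1 = obj1[obj1["stimulus_id"].isin(keep)].reset_index(drop=True)
    scn = _select(design, TD1, "scene")
    if len(scn) == 0:
        raise ValueError("no scene trials in TD1")
    runs = obj1["run"].to_numpy()
    diff_run = runs[:, None] != runs[None, :]
    if not diff_run.any():
        raise ValueError("all objects share one run: no valid within-category pairs")
    rows = {
        "obj": betas.rows_for(obj1["trial_id"]),
        "scn": betas.rows_for(scn["trial_id"]),
    }

    def reduce_maps(blocks):
        Zoo = _zblock(blocks, "obj", "obj")
        within = np.nanmean(Zoo[diff_run])
        Zos = _zblock(blocks, "obj", "scn")
        return within, np.nanmean(Zos)

    res = _sweep(betas, spec, rows, {"pair": reduce_maps})
    within = np.full(betas.mask.size, np.nan)
    between = np.full(betas.mask.size, np.nan)
    for i in np.flatnonzero(res["_valid"]):
        within[i], between[i] = res["pair"][i]
    return DistinctivenessMaps(
        grid_shape=betas.grid_shape, affine=betas.affine,
        valid_mask=res["_valid"], within_category=within,
        between_category=between, category_diff=within - between,
    )


def distinctiveness_maps(
    betas: BetaSeries,
    design: pd.DataFrame,
    spec: SearchlightSpec = SearchlightSpec(),
    subject_id: str = "",
    objects: Sequence[int] | None = None,
) -> DistinctivenessMaps:
    """Item and category metrics in one result (shared valid mask)."""
    item = item_distinctiveness(betas, design, spec, objects)
    cat = category_distinctiveness(betas, design, spec, objects)
    valid = item.valid_mask & cat.valid_mask
    maps = DistinctivenessMaps(
        grid_shape=betas.grid_shape, affine=betas.affine,
        subject_id=subject_id, valid_mask=valid,
        within_item=item.within_item, between_item=item.between_item,
        item_diff=item.item_diff, within_category=cat.within_category,
        between_category=cat.between_category, category_diff=cat.category_diff,
    )
    for m in maps.METRICS:
        arr = getattr(maps, m)
        arr[~valid] = np.nan
    return maps


# ---------------------------------------------------------------------------
# Scene-pairing control contrasts
# ---------------------------------------------------------------------------

@dataclass
class ControlMaps:
    """Scene-pairing control contrast: (within-scene - between-scene)
    object-pair similarity per phase, then TD2 minus TD1."""

    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    td1_contrast: np.ndarray | None = None
    td2_contrast: np.ndarray | None = None
    contrast: np.ndarray | None = None
    valid_mask: np.ndarray | None = None
    empty: bool = False
    variant: str = "all"


def _strong_memory_scenes(design: pd.DataFrame, lo: int = 3, hi: int = 5) -> set:
    """Scenes whose object-scene pairs were correctly remembered lo-hi
    times (strong); weak scenes are 0-2."""
    ret = design[(design["phase"] == "retrieval")
                 & design["paired_scene_id"].notna()]
    counts = (ret.assign(ok=ret["pair_outcome"] == "correct")
              .groupby("paired_scene_id")["ok"].sum())
    return set(counts[(counts >= lo) & (counts <= hi)].index.astype(int))


def scene_pairing_controls(
    betas: BetaSeries,
    design: pd.DataFrame,
    spec: SearchlightSpec = SearchlightSpec(),
    variant: str = "all",
) -> ControlMaps:
    """Control contrast for carry-over of the object-scene association.

    For each phase, within-scene similarity (object pairs sharing a
    paired scene, different runs) minus between-scene similarity (object
    pairs with different paired scenes, different runs); the reported
    contrast is TD2 minus TD1, so session artifacts cancel.  Variants
    restrict the object set: ``pair_correct_only`` keeps objects with a
    correct subsequent pair response; ``strong_memory_scenes`` keeps
    objects paired to scenes with 3-5 correctly remembered pairs.
    """
    if variant not in ("all", "pair_correct_only", "strong_memory_scenes"):
        raise ValueError(f"unknown variant {variant!r}")
    obj1, obj2 = _aligned_object_trials(design)
    paired = obj1["paired_scene_id"].notna().to_numpy()
    keep = paired.copy()
    if variant == "pair_correct_only":
        keep &= (obj1["pair_outcome"] == "correct").to_numpy()
    elif variant == "strong_memory_scenes":
        strong = _strong_memory_scenes(design)
        keep &= obj1["paired_scene_id"].isin(strong).to_numpy()
    obj1 = obj1[keep].reset_index(drop=True)
    obj2 = obj2[keep].reset_index(drop=True)

    scene_of = obj1["paired_scene_id"].to_numpy(dtype=float)
    same_scene = scene_of[:, None] == scene_of[None, :]
    np.fill_diagonal(same_scene, False)
    out = ControlMaps(grid_shape=betas.grid_shape, affine=betas.affine,
                      variant=variant)
    masks = {}
    for tag, frame in (("td1", obj1), ("td2", obj2)):
        runs = frame["run"].to_numpy()
        diff_run = runs[:, None] != runs[None, :]
        masks[tag + "_w"] = same_scene & diff_run
        masks[tag + "_b"] = (~same_scene) & diff_run
        np.fill_diagonal(masks[tag + "_b"], False)
    if len(obj1) == 0 or not all(m.any() for m in masks.values()):
        out.empty = True
        return out

    rows = {"td1": betas.rows_for(obj1["trial_id"]),
            "td2": betas.rows_for(obj2["trial_id"])}

    def reduce_maps(blocks):
        res = []
        for tag in ("td1", "td2"):
            Z = _zblock(blocks, tag, tag)
            res.append(np.nanmean(Z[masks[tag + "_w"]])
                       - np.nanmean(Z[masks[tag + "_b"]]))
        return tuple(res)

    res = _sweep(betas, spec, rows, {"pair": reduce_maps})
    n_vox = betas.mask.size
    td1c = np.full(n_vox, np.nan)
    td2c = np.full(n_vox, np.nan)
    for i in np.flatnonzero(res["_valid"]):
        td1c[i], td2c[i] = res["pair"][i]
    out.td1_contrast = td1c
    out.td2_contrast = td2c
    out.contrast = td2c - td1c
    out.valid_mask = res["_valid"]
    return out


# ---------------------------------------------------------------------------
# Trial-wise extraction within a mask
# ---------------------------------------------------------------------------

def trialwise_distinctiveness(
    betas: BetaSeries,
    design: pd.DataFrame,
    mask: np.ndarray,
    level: str = "item",
) -> pd.Series:
    """Per-object distinctiveness over an explicit voxel mask.

    The whole mask is treated as one pattern (no searchlight), mirroring
    cluster back-projection.  Item level: z(r(TD1_i, TD2_i)) minus the
    mean z of object i's TD1 pattern to every other object's TD2 pattern.
    Category level: mean z to other TD1 objects from different runs minus
    mean z to all scenes.  Returns a Series indexed by stimulus_id; NaN
    where no eligible partner exists.
    """
    mask = np.asarray(mask, dtype=bool).reshape(-1)
    if not mask.any():
        raise ValueError("mask is empty")
    vox = np.flatnonzero(mask & betas.mask)
    if len(vox) == 0:
        raise ValueError("mask has no overlap with the analysis mask")
    obj1, obj2 = _aligned_object_trials(design)
    A = betas.data[betas.rows_for(obj1["trial_id"])][:, vox].astype(float)
    if level == "item":
        B = betas.data[betas.rows_for(obj2["trial_id"])][:, vox].astype(float)
        Z = pairwise_z(A, B)
        within = np.diag(Z).copy()
        off = Z.copy()
        np.fill_diagonal(off, np.nan)
        with np.errstate(invalid="ignore"):
            vals = within - np.nanmean(off, axis=1)
    elif level == "category":
        scn = _select(design, TD1, "scene")
        if len(scn) == 0:
            raise ValueError("category level requires scene trials")
        S = betas.data[betas.rows_for(scn["trial_id"])][:, vox].astype(float)
        Z11 = pairwise_z(A, A)
        runs = obj1["run"].to_numpy()
        eligible = runs[:, None] != runs[None, :]
        Z11 = np.where(eligible, Z11, np.nan)
        Z1s = pairwise_z(A, S)
        with np.errstate(invalid="ignore"):
            vals = np.nanmean(Z11, axis=1) - np.nanmean(Z1s, axis=1)
    else:
        raise ValueError(f"unknown level {level!r}")
    return pd.Series(vals, index=pd.Index(obj1["stimulus_id"].to_numpy(),
                                          name="stimulus_id"), name=f"d_{level}")


def group_valid_mask(maps: Iterable[DistinctivenessMaps]) -> np.ndarray:
    """Voxels with valid searchlight metrics in every subject."""
    masks = [m.valid_mask for m in maps]
    if not masks:
        raise ValueError("no maps supplied")
    out = masks[0].copy()
    for m in masks[1:]:
        out &= m
    return out


def mask_mean(flat_map: np.ndarray, mask: np.ndarray) -> float:
    """Mean map value over a flat boolean mask (NaN-aware)."""
    mask = np.asarray(mask, dtype=bool).reshape(-1)
    return float(np.nanmean(np.asarray(flat_map, dtype=float)[mask]))
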