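"""NIfTI / TSV / JSON input-output and the pipeline configuration.

Volumes are NIfTI-1 via nibabel, stored float32 with NaN for missing
voxels; all statistics are computed in float64.  Trial tables are
tab-separated with a header (BIDS-events-flavored columns).  The
configuration object round-trips losslessly through JSON and carries an
explicit seed for every stochastic stage so any stage can be re-run in
isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import BetaSeries


class VolumeError(ValueError):
    """Shape/affine inconsistency or otherwise unusable volume."""


def save_volume(flat_map: np.ndarray, grid_shape, affine, path) -> None:
    img = nib.Nifti1Image(
        np.asarray(flat_map, dtype=np.float32).reshape(grid_shape), affine)
    img.to_filename(str(path))


def load_volume(path, expect_affine: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3D/4D NIfTI; returns (data, affine).  Raises VolumeError on
    affine mismatch with ``expect_affine``."""
    img = nib.load(str(path))
    affine = img.affine
    if expect_affine is not None and not np.allclose(affine, expect_affine,
                                                     atol=1e-4):
        raise VolumeError(f"affine of {path} does not match reference")
    return np.asarray(img.dataobj, dtype=np.float32), affine


def save_beta_series(betas: BetaSeries, data_path, mask_path) -> None:
    """Write a beta stack as a 4D NIfTI plus its mask NIfTI."""
    vol4 = np.moveaxis(
        betas.data.reshape(betas.n_trials, *betas.grid_shape), 0, -1)
    nib.Nifti1Image(vol4.astype(np.float32), betas.affine).to_filename(str(data_path))
    nib.Nifti1Image(
        betas.mask.reshape(betas.grid_shape).astype(np.uint8),
        betas.affine).to_filename(str(mask_path))


def load_beta_series(data_path, mask_path, trial_ids=None) -> BetaSeries:
    vol4, affine = load_volume(data_path)
    if vol4.ndim != 4:
        raise VolumeError("beta stack must be 4-D")
    mask, mask_affine = load_volume(mask_path)
    if mask.shape != vol4.shape[:3]:
        raise VolumeError("mask shape does not match beta grid")
    if not np.allclose(mask_affine, affine, atol=1e-4):
        raise VolumeError("mask affine does not match beta affine")
    mask = mask.astype(bool).reshape(-1)
    if not mask.any():
        raise VolumeError("mask contains no voxels")
    n_trials = vol4.shape[-1]
    data = np.moveaxis(vol4, -1, 0).reshape(n_trials, -1)
    if trial_ids is None:
        trial_ids = np.arange(n_trials)
    return BetaSeries(data=data, mask=mask, grid_shape=vol4.shape[:3],
                      affine=affine, trial_ids=np.asarray(trial_ids))


def save_trial_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="n/a")


def load_trial_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", na_values=["n/a"])
    if "paired_scene_id" in table:
        table["paired_scene_id"] = table["paired_scene_id"].astype("Int64")
    return table


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class StageSeeds:
    """One explicit seed per stochastic stage."""

    design: int = 11
    betas: int = 12
    memory: int = 13
    permutation: int = 14
    bootstrap: int = 15

    @classmethod
    def from_master(cls, seed: int) -> "StageSeeds":
        ss = np.random.SeedSequence(seed)
        vals = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)]
        return cls(*vals)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one end-to-end run."""

    # cohort
    n_young: int = 8
    n_old: int = 8
    grid_shape: tuple = (12, 12, 12)
    voxel_size_mm: float = 2.0
    region_corner: tuple = (3, 3, 3)
    region_shape: tuple = (4, 4, 4)
    a_cat_young: float = 0.10
    a_cat_old: float = 0.05
    b_item_young: float = 0.10
    b_item_old: float = 0.05
    param_jitter: float = 0.02
    stability: float = 1.0
    # reduced design
    n_objects: int = 40
    n_object_targets: int = 4
    n_paired: int = 30
    n_baseline: int = 6
    n_scenes: int = 12
    n_scene_targets: int = 2
    retrieval_counts: dict = field(default_factory=lambda: {
        "old_match": 12, "old_mismatch": 12, "old_new_scene": 6,
        "new_objects": 18})
    # memory model (slopes act on the raw Fisher-z distinctiveness scale)
    memory_beta0: float = 0.2
    memory_beta1_item: float = 3.0
    memory_beta1_cat: float = 3.0
    memory_specificity: float = 0.85
    # analysis
    radius_mm: float = 4.0
    min_voxels: int = 5
    mask_threshold: float = 0.4
    alpha: float = 0.005
    alpha_control: float = 0.01
    min_size: int = 10
    connectivity: int = 26
    n_perm: int = 200
    n_boot: int = 500
    memory_split: bool = True
    standardize_within_group: bool = False
    seeds: StageSeeds = field(default_factory=StageSeeds)
    version: str = "0.1.0"

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        seeds = payload.pop("seeds", None)
        cfg = cls(**{k: v for k, v in payload.items()})
        if seeds is not None:
            cfg.seeds = StageSeeds(**seeds)
        for name in ("grid_shape", "region_corner", "region_shape"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def region_indices(self) -> np.ndarray:
        """Flat indices of the rectangular signal region."""
        idx = np.zeros(self.grid_shape, dtype=bool)
        c, s = self.region_corner, self.region_shape
        idx[c[0]:c[0] + s[0], c[1]:c[1] + s[1], c[2]:c[2] + s[2]] = True
        return np.flatnonzero(idx.reshape(-1))


def to_jsonable(obj):
    """Recursively convert numpy scalars/arrays for JSON export."""
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return to_jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
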