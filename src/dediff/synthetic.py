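"""Synthetic cohort generator: study design, trial-wise beta images, memory.

Emulates an age-comparative two-session fMRI paradigm: a first
target-detection phase (TD1) with object and scene runs, a second
target-detection phase (TD2) re-presenting the objects, and an old/new
recognition test with item and pair judgments.  Voxel patterns follow an
additive variance-partition model with category-shared, item-specific and
noise components, so expected pattern correlations have closed forms that
downstream similarity analyses can be validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

# Phase labels
TD1 = "td1"
TD2 = "td2"
RETRIEVAL = "retrieval"

# Trial spacing (s): fixation + stimulus + fixation at the scanner TR
TRIAL_DURATION_S = 3 * 2.307

#: retrieval item_outcome / pair_outcome vocabularies
ITEM_OUTCOMES = ("hit", "miss", "corr_rej", "false_alarm", "none")
PAIR_OUTCOMES = ("correct", "incorrect", "none")

TRIAL_COLUMNS = [
    "trial_id", "phase", "run", "onset", "stimulus_id", "category",
    "is_target", "paired_scene_id", "retrieval_condition",
    "item_outcome", "pair_outcome",
]


class DesignError(ValueError):
    """Raised when design counts violate a structural identity."""


@dataclass(frozen=True)
class DesignSpec:
    """Counts defining the trial structure of one subject's session.

    Defaults reproduce the full study design: 320 objects (20 targets,
    250 later paired with scenes, 50 baseline) over three TD1 runs sized
    106/107/107, one 60-scene run (10 targets), three TD2 object runs,
    and a 400-trial retrieval phase (250 old + 150 new objects).
    """

    n_objects: int = 320
    n_object_targets: int = 20
    n_paired: int = 250
    n_baseline: int = 50
    n_scenes: int = 60
    n_scene_targets: int = 10
    n_object_runs_phase1: int = 3
    n_scene_runs_phase1: int = 1
    n_object_runs_phase2: int = 3
    retrieval_counts: Mapping[str, int] = field(
        default_factory=lambda: {
            "old_match": 100,
            "old_mismatch": 100,
            "old_new_scene": 50,
            "new_objects": 150,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_object_targets + self.n_paired + self.n_baseline != self.n_objects:
            raise DesignError(
                "n_object_targets + n_paired + n_baseline must equal n_objects "
                f"({self.n_object_targets} + {self.n_paired} + {self.n_baseline} "
                f"!= {self.n_objects})"
            )
        old = (
            self.retrieval_counts["old_match"]
            + self.retrieval_counts["old_mismatch"]
            + self.retrieval_counts["old_new_scene"]
        )
        if old != self.n_paired:
            raise DesignError(
                f"retrieval old-object counts sum to {old}, expected n_paired="
                f"{self.n_paired}"
            )
        if self.n_scene_targets > self.n_scenes:
            raise DesignError("n_scene_targets exceeds n_scenes")
        for name in ("n_object_runs_phase1", "n_scene_runs_phase1",
                     "n_object_runs_phase2"):
            if getattr(self, name) < 1:
                raise DesignError(f"{name} must be >= 1")


def _partition_sizes(n: int, k: int) -> list[int]:
    """Split n into k near-equal parts (sizes differ by <=1, smaller first)."""
    base, rem = divmod(n, k)
    return [base] * (k - rem) + [base + 1] * rem


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """Generate the full trial table for one subject.

    Pseudorandomization is a uniform shuffle under ``spec.seed``: stimulus
    order within each phase, assignment of objects to targets / scene
    pairings / retrieval conditions are all drawn from one seeded stream,
    so the same spec yields a bit-identical table.

    Runs are numbered globally: TD1 object runs first, then the TD1 scene
    run(s), then TD2 runs, then a single retrieval run, so "different
    runs" is a plain integer comparison.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    objects = rng.permutation(spec.n_objects)
    target_objects = objects[: spec.n_object_targets]
    paired_objects = objects[spec.n_object_targets: spec.n_object_targets + spec.n_paired]
    # remaining objects are baseline

    scene_ids = spec.n_objects + np.arange(spec.n_scenes)
    scenes = rng.permutation(scene_ids)
    target_scenes = scenes[: spec.n_scene_targets]
    old_scenes = scenes[spec.n_scene_targets:]

    # object-scene pairing: round-robin over shuffled paired objects
    pairing: dict[int, int] = {}
    if len(old_scenes) > 0:
        shuffled_paired = rng.permutation(paired_objects)
        for i, obj in enumerate(shuffled_paired):
            pairing[int(obj)] = int(old_scenes[i % len(old_scenes)])

    target_obj_set = set(int(o) for o in target_objects)
    target_scene_set = set(int(s) for s in target_scenes)

    rows: list[dict] = []
    run_no = 0

    def add_phase(phase: str, stimuli: np.ndarray, n_runs: int, category: str):
        nonlocal run_no
        order = rng.permutation(stimuli)
        sizes = _partition_sizes(len(order), n_runs)
        start = 0
        for size in sizes:
            run_no += 1
            for j, stim in enumerate(order[start: start + size]):
                stim = int(stim)
                rows.append({
                    "phase": phase,
                    "run": run_no,
                    "onset": j * TRIAL_DURATION_S,
                    "stimulus_id": stim,
                    "category": category,
                    "is_target": (stim in target_obj_set) if category == "object"
                                 else (stim in target_scene_set),
                    "paired_scene_id": pairing.get(stim),
                    "retrieval_condition": None,
                })
            start += size

    add_phase(TD1, np.arange(spec.n_objects), spec.n_object_runs_phase1, "object")
    add_phase(TD1, scene_ids, spec.n_scene_runs_phase1, "scene")
    add_phase(TD2, np.arange(spec.n_objects), spec.n_object_runs_phase2, "object")

    # retrieval: old paired objects assigned to context conditions + new objects
    rc = spec.retrieval_counts
    cond_labels = (
        ["old_match"] * rc["old_match"]
        + ["old_mismatch"] * rc["old_mismatch"]
        + ["old_new_scene"] * rc["old_new_scene"]
    )
    old_order = rng.permutation(paired_objects)
    new_ids = spec.n_objects + spec.n_scenes + np.arange(rc["new_objects"])
    ret_stims = np.concatenate([old_order, new_ids])
    ret_conds = cond_labels + ["new"] * rc["new_objects"]
    ret_perm = rng.permutation(len(ret_stims))
    run_no += 1
    for j, k in enumerate(ret_perm):
        stim = int(ret_stims[k])
        rows.append({
            "phase": RETRIEVAL,
            "run": run_no,
            "onset": j * TRIAL_DURATION_S,
            "stimulus_id": stim,
            "category": "object",
            "is_target": False,
            "paired_scene_id": pairing.get(stim),
            "retrieval_condition": ret_conds[k],
        })

    table = pd.DataFrame(rows)
    table.insert(0, "trial_id", np.arange(len(table)))
    table["item_outcome"] = "none"
    table["pair_outcome"] = "none"
    table["paired_scene_id"] = table["paired_scene_id"].astype("Int64")
    return table[TRIAL_COLUMNS]


# ---------------------------------------------------------------------------
# Voxel signal model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalParams:
    """Variance-partition signal model on a voxel grid.

    Within ``signal_region`` each trial's beta at voxel v is

        beta = sqrt(a_cat) * C_v(category) + sqrt(b_item) * I_v(stimulus)
             + sqrt(1 - a_cat - b_item) * eps_v(trial)

    with C, I, eps independent unit-variance Gaussian draws, so the
    expected Pearson correlation between two trials equals the variance
    fraction they share (a_cat for same-category different-item pairs,
    a_cat + b_item for same-item pairs).  Voxels outside the region are
    pure noise.  ``stability`` in [0, 1] mixes a fresh item pattern into
    the second target-detection phase: rho = 1 reuses TD1 item patterns
    exactly, rho < 1 lowers expected within-item similarity to
    a_cat + rho * b_item.
    """

    a_cat: float
    b_item: float
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: float = 2.0
    signal_region: np.ndarray | None = None  # flat voxel indices; None = all
    stability: float = 1.0

    def validate(self) -> None:
        if not (0.0 <= self.a_cat and 0.0 <= self.b_item):
            raise ValueError("variance fractions must be non-negative")
        if self.a_cat + self.b_item > 1.0 + 1e-12:
            raise ValueError(
                f"a_cat + b_item = {self.a_cat + self.b_item:.4f} exceeds 1"
            )
        if not (0.0 <= self.stability <= 1.0):
            raise ValueError("stability must lie in [0, 1]")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    def region_indices(self) -> np.ndarray:
        if self.signal_region is None:
            return np.arange(self.n_voxels)
        return np.asarray(self.signal_region, dtype=np.intp)


def default_affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


@dataclass
class BetaSeries:
    """Stack of per-trial beta volumes on a common grid.

    ``data`` is (n_trials, n_voxels) float32 over the flattened grid
    (C order); NaN marks voxels excluded by masking for a given trial.
    ``mask`` is the flat boolean analysis mask; ``trial_ids`` aligns rows
    with the trial table.
    """

    data: np.ndarray
    mask: np.ndarray
    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    trial_ids: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.mask = np.asarray(self.mask, dtype=bool).reshape(-1)
        self.trial_ids = np.asarray(self.trial_ids)
        if self.data.shape != (len(self.trial_ids), self.mask.size):
            raise ValueError("data shape inconsistent with trial_ids/mask")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def volume(self, row: int) -> np.ndarray:
        return self.data[row].reshape(self.grid_shape)

    def rows_for(self, trial_ids: Sequence[int]) -> np.ndarray:
        """Row indices for the given trial ids (order preserved)."""
        lookup = {int(t): i for i, t in enumerate(self.trial_ids)}
        try:
            return np.array([lookup[int(t)] for t in trial_ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"trial id {exc} not present in BetaSeries") from exc


def generate_betas(
    design: pd.DataFrame,
    params: SignalParams,
    seed: int,
) -> BetaSeries:
    """Draw per-trial beta maps for the scanned phases (TD1 + TD2).

    Category patterns C and item patterns I are sampled once per category /
    stimulus and reused wherever that stimulus recurs, giving perfectly
    stable representations by default (see ``SignalParams.stability``).
    """
    params.validate()
    rng = np.random.default_rng(seed)
    scanned = design[design["phase"].isin([TD1, TD2])].reset_index(drop=True)
    n_trials = len(scanned)
    n_vox = params.n_voxels
    region = params.region_indices()
    p = len(region)

    categories = sorted(scanned["category"].unique())
    cat_patterns = {c: rng.standard_normal(p) for c in categories}
    stim_ids = np.sort(scanned["stimulus_id"].unique())
    item_patterns = {int(s): rng.standard_normal(p) for s in stim_ids}
    rho = params.stability
    if rho < 1.0:
        # fresh TD2 item component, variance-preserving mixture
        item_patterns_td2 = {
            int(s): rho * item_patterns[int(s)]
            + np.sqrt(1.0 - rho**2) * rng.standard_normal(p)
            for s in stim_ids
        }
    else:
        item_patterns_td2 = item_patterns

    sa = np.sqrt(params.a_cat)
    sb = np.sqrt(params.b_item)
    se = np.sqrt(max(0.0, 1.0 - params.a_cat - params.b_item))

    data = rng.standard_normal((n_trials, n_vox)).astype(np.float64)
    # out-of-region voxels keep the pure-noise draw; in-region get the model
    for i in range(n_trials):
        row = scanned.iloc[i]
        items = item_patterns_td2 if row["phase"] == TD2 else item_patterns
        data[i, region] = (
            sa * cat_patterns[row["category"]]
            + sb * items[int(row["stimulus_id"])]
            + se * data[i, region]
        )

    mask = np.ones(n_vox, dtype=bool)
    return BetaSeries(
        data=data.astype(np.float32),
        mask=mask,
        grid_shape=params.grid_shape,
        affine=default_affine(params.voxel_size_mm),
        trial_ids=scanned["trial_id"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Memory generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MemoryModel:
    """Logistic subsequent-memory model on trial-wise distinctiveness.

    P(hit) = sigmoid(beta0 + beta1_item * d_item + beta1_cat * d_cat) per
    old object; correct rejection of new objects is Bernoulli with fixed
    ``specificity``.  Pair judgments follow the same logistic form with
    the category slope only (the pairing task is scene-contextual).
    """

    beta0: float = 0.0
    beta1_item: float = 0.0
    beta1_cat: float = 0.0
    specificity: float = 0.85
    seed: int = 0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def generate_memory(
    design: pd.DataFrame,
    trialwise_distinctiveness: pd.DataFrame,
    model: MemoryModel,
) -> pd.DataFrame:
    """Draw retrieval outcomes from trial-wise distinctiveness.

    ``trialwise_distinctiveness`` must be indexed by stimulus_id with
    columns ``d_item`` and ``d_cat`` covering every non-target paired
    object.  Returns a copy of the design with item_outcome and
    pair_outcome filled on retrieval rows and mirrored onto the TD1/TD2
    rows of the same stimulus (so encoding-phase analyses can split by
    subsequent memory without a join).
    """
    rng = np.random.default_rng(model.seed)
    out = design.copy()
    ret = out["phase"] == RETRIEVAL
    old = ret & out["retrieval_condition"].astype(str).str.startswith("old")
    new = ret & (out["retrieval_condition"] == "new")

    old_stims = out.loc[old, "stimulus_id"].to_numpy()
    missing = set(old_stims) - set(trialwise_distinctiveness.index)
    if missing:
        raise ValueError(
            f"missing distinctiveness for {len(missing)} old objects "
            f"(e.g., stimulus {sorted(missing)[:3]})"
        )
    d = trialwise_distinctiveness.loc[old_stims]
    d_item = d["d_item"].to_numpy(dtype=float) if "d_item" in d else np.zeros(len(d))
    d_cat = d["d_cat"].to_numpy(dtype=float) if "d_cat" in d else np.zeros(len(d))

    p_hit = _sigmoid(model.beta0 + model.beta1_item * d_item + model.beta1_cat * d_cat)
    hits = rng.random(len(p_hit)) < p_hit
    out.loc[old, "item_outcome"] = np.where(hits, "hit", "miss")

    p_pair = _sigmoid(model.beta0 + model.beta1_cat * d_cat)
    pair_ok = rng.random(len(p_pair)) < p_pair
    out.loc[old, "pair_outcome"] = np.where(pair_ok, "correct", "incorrect")

    n_new = int(new.sum())
    cr = rng.random(n_new) < model.specificity
    out.loc[new, "item_outcome"] = np.where(cr, "corr_rej", "false_alarm")
    # pair judgment on new objects is scored correct iff item correctly rejected
    out.loc[new, "pair_outcome"] = np.where(cr, "correct", "incorrect")

    # mirror outcomes onto encoding-phase rows by stimulus
    item_by_stim = dict(zip(out.loc[ret, "stimulus_id"], out.loc[ret, "item_outcome"]))
    pair_by_stim = dict(zip(out.loc[ret, "stimulus_id"], out.loc[ret, "pair_outcome"]))
    enc = out["phase"].isin([TD1, TD2])
    out.loc[enc, "item_outcome"] = [
        item_by_stim.get(s, "none") for s in out.loc[enc, "stimulus_id"]
    ]
    out.loc[enc, "pair_outcome"] = [
        pair_by_stim.get(s, "none") for s in out.loc[enc, "stimulus_id"]
    ]
    return out


def region_trial_distinctiveness(
    betas: BetaSeries, design: pd.DataFrame, region: np.ndarray
) -> pd.DataFrame:
    """Latent trial-wise distinctiveness over a voxel region.

    Convenience used to couple memory outcomes to the realized patterns:
    per non-target object, Fisher-z self-similarity across phases minus
    mean z to all other objects (item level), and mean z to other TD1
    objects in different runs minus mean z to scenes (category level).
    Equivalent to the searchlight module's mask-based trial extraction;
    kept here so the generator has no dependency on the analysis code.
    """
    region = np.asarray(region, dtype=np.intp)
    scanned = design[design["phase"].isin([TD1, TD2])].reset_index(drop=True)
    obj1 = scanned[(scanned["phase"] == TD1) & (scanned["category"] == "object")
                   & (~scanned["is_target"])]
    obj2 = scanned[(scanned["phase"] == TD2) & (scanned["category"] == "object")
                   & (~scanned["is_target"])]
    scn = scanned[(scanned["phase"] == TD1) & (scanned["category"] == "scene")
                  & (~scanned["is_target"])]

    def patterns(rows):
        X = betas.data[betas.rows_for(rows["trial_id"])][:, region].astype(float)
        X = X - X.mean(axis=1, keepdims=True)
        X /= np.linalg.norm(X, axis=1, keepdims=True)
        return X

    A = patterns(obj1)
    obj2_sorted = obj2.set_index("stimulus_id").loc[obj1["stimulus_id"]]
    obj2_sorted = obj2_sorted.reset_index()
    B = patterns(obj2_sorted)
    S = patterns(scn) if len(scn) else None

    clip = 1.0 - 1e-7
    Z12 = np.arctanh(np.clip(A @ B.T, -clip, clip))
    n = len(A)
    within = np.diag(Z12)
    between = (Z12.sum(axis=1) - within) / (n - 1)
    d_item = within - between

    Z11 = np.arctanh(np.clip(A @ A.T, -clip, clip))
    runs = obj1["run"].to_numpy()
    diff_run = runs[:, None] != runs[None, :]
    with np.errstate(invalid="ignore"):
        w_cat = np.where(diff_run, Z11, np.nan)
        within_cat = np.nanmean(w_cat, axis=1)
    if S is not None and len(S):
        Z1s = np.arctanh(np.clip(A @ S.T, -clip, clip))
        between_cat = Z1s.mean(axis=1)
    else:
        between_cat = np.zeros(n)
    d_cat = within_cat - between_cat

    return pd.DataFrame(
        {"d_item": d_item, "d_cat": d_cat},
        index=pd.Index(obj1["stimulus_id"].to_numpy(), name="stimulus_id"),
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class Subject:
    subject_id: str
    group: str
    design: pd.DataFrame
    betas: BetaSeries
    params: SignalParams


def generate_cohort(
    n_young: int,
    n_old: int,
    group_params: Mapping[str, SignalParams],
    seed: int,
    design_spec: DesignSpec | None = None,
    memory_model: MemoryModel | None = None,
    param_jitter: float = 0.0,
) -> list[Subject]:
    """Generate an age-comparative cohort of independent subjects.

    Per-subject seeds are spawned deterministically from ``seed``, so the
    same master seed reproduces the cohort bit-for-bit.  ``param_jitter``
    adds truncated-Gaussian between-subject variability (SD in variance-
    fraction units) to a_cat and b_item around the group values, which is
    what gives interindividual distinctiveness differences for the
    brain-behavior analyses.  If ``memory_model`` is given, retrieval
    outcomes are drawn from each subject's realized signal-region
    trial-wise distinctiveness on its raw (Fisher-z) scale, so both
    within-subject trial variation and between-subject differences in
    distinctiveness propagate into memory outcomes.
    """
    base = DesignSpec() if design_spec is None else design_spec
    ss = np.random.SeedSequence(seed)
    n_total = n_young + n_old
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3 * n_total)]
    groups = ["young"] * n_young + ["old"] * n_old
    subjects: list[Subject] = []
    for i, group in enumerate(groups):
        s_design, s_beta, s_mem = child_seeds[3 * i: 3 * i + 3]
        params = group_params[group]
        if param_jitter > 0.0:
            jrng = np.random.default_rng(s_beta + 1)
            a = float(np.clip(params.a_cat + param_jitter * jrng.standard_normal(),
                              0.0, 0.9))
            b = float(np.clip(params.b_item + param_jitter * jrng.standard_normal(),
                              0.0, 0.9 - a))
            params = replace(params, a_cat=a, b_item=b)
        design = generate_design(replace(base, seed=s_design))
        betas = generate_betas(design, params, seed=s_beta)
        if memory_model is not None:
            d = region_trial_distinctiveness(betas, design, params.region_indices())
            design = generate_memory(design, d,
                                     replace(memory_model, seed=s_mem))
        subjects.append(Subject(
            subject_id=f"sub-{i + 1:03d}", group=group,
            design=design, betas=betas, params=params,
        ))
    return subjects


def estimate_signal_fractions(
    betas: BetaSeries, design: pd.DataFrame, region: np.ndarray
) -> tuple[float, float]:
    """Recover (a_cat, b_item) from realized patterns over a region.

    a_hat = tanh(mean z) over same-category different-item TD1 object
    pairs from different runs; b_hat = tanh(mean z) over same-item
    cross-phase pairs minus a_hat.  tanh of the mean z (rather than mean
    r) undoes the slight convexity inflation of averaging atanh values.
    """
    region = np.asarray(region, dtype=np.intp)
    scanned = design[design["phase"].isin([TD1, TD2])].reset_index(drop=True)
    obj1 = scanned[(scanned["phase"] == TD1) & (scanned["category"] == "object")
                   & (~scanned["is_target"])]
    obj2 = scanned[(scanned["phase"] == TD2) & (scanned["category"] == "object")
                   & (~scanned["is_target"])]

    def patterns(rows):
        X = betas.data[betas.rows_for(rows["trial_id"])][:, region].astype(float)
        X = X - X.mean(axis=1, keepdims=True)
        X /= np.linalg.norm(X, axis=1, keepdims=True)
        return X

    A = patterns(obj1)
    obj2_sorted = obj2.set_index("stimulus_id").loc[obj1["stimulus_id"]].reset_index()
    B = patterns(obj2_sorted)
    clip = 1.0 - 1e-7

    runs = obj1["run"].to_numpy()
    Z11 = np.arctanh(np.clip(A @ A.T, -clip, clip))
    diff_run = runs[:, None] != runs[None, :]
    a_hat = float(np.tanh(Z11[diff_run].mean()))

    z_within = np.arctanh(np.clip(np.sum(A * B, axis=1), -clip, clip))
    b_hat = float(np.tanh(z_within.mean())) - a_hat
    return a_hat, b_hat
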