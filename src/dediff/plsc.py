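"""Partial least squares correlation (PLSC) between behavior and brain.

The between-person Pearson correlation matrix R (neural x behavior) of
z-scored columns is decomposed by SVD, R = U S V'.  The first latent
variable (LV1) optimally summarizes the shared association: U[:, 0] are
the neural saliences, V[:, 0] the behavior saliences, S[0] the singular
value.  LV1 significance comes from a permutation test on the singular
value (rows of Y shuffled relative to X) and salience robustness from
bootstrap ratios (original salience / bootstrap SE), with |BSR| > 1.96
read as reliable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SE_FLOOR = 1e-12


@dataclass
class PLSCInput:
    """Behavior block Y (n x q), neural block X (n x p), group labels."""

    X: np.ndarray
    Y: np.ndarray
    group: np.ndarray | None = None
    x_names: list[str] = field(default_factory=list)
    y_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("X and Y must be 2-D")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y must have the same number of subjects")
        if self.X.shape[0] < 4:
            raise ValueError("need n >= 4 subjects")
        if np.isnan(self.X).any() or np.isnan(self.Y).any():
            raise ValueError("missing values are not allowed")
        for tag, M, names in (("X", self.X, self.x_names),
                              ("Y", self.Y, self.y_names)):
            const = np.nonzero(M.std(axis=0) == 0)[0]
            if len(const):
                label = names[const[0]] if names else f"column {const[0]}"
                raise ValueError(f"constant {tag} column: {label}")
        if not self.x_names:
            self.x_names = [f"x{j}" for j in range(self.X.shape[1])]
        if not self.y_names:
            self.y_names = [f"y{j}" for j in range(self.Y.shape[1])]


@dataclass
class PLSCResult:
    singular_values: np.ndarray
    neural_saliences: np.ndarray      # U, (p, k)
    behavior_saliences: np.ndarray    # V, (q, k)
    latent_x: np.ndarray              # Lx = Xz @ U[:, 0]
    latent_y: np.ndarray              # Ly = Yz @ V[:, 0]
    R: np.ndarray
    p_perm: float = np.nan
    bootstrap_ratios: np.ndarray | None = None
    group_latent_correlations: dict = field(default_factory=dict)
    x_names: list[str] = field(default_factory=list)
    y_names: list[str] = field(default_factory=list)


def _zscore(M: np.ndarray, group: np.ndarray | None = None) -> np.ndarray:
    if group is None:
        return (M - M.mean(axis=0)) / M.std(axis=0, ddof=0)
    out = np.empty_like(M, dtype=float)
    for g in np.unique(group):
        sel = group == g
        out[sel] = (M[sel] - M[sel].mean(axis=0)) / M[sel].std(axis=0, ddof=0)
    return out


def _corr_svd(Xz: np.ndarray, Yz: np.ndarray):
    n = Xz.shape[0]
    R = Xz.T @ Yz / n                          # (p, q) correlation matrix
    U, S, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    # sign convention: first behavior salience of each LV non-negative
    for k in range(V.shape[1]):
        if V[0, k] < 0:
            V[:, k] *= -1.0
            U[:, k] *= -1.0
    return R, U, S, V


def plsc_fit(inp: PLSCInput, standardize_within_group: bool = False) -> PLSCResult:
    """Fit the PLSC model and return saliences, latent scores and the
    within-group latent correlations.

    ``standardize_within_group`` z-scores all columns within each age
    group before correlating, removing mean group differences.
    """
    group = inp.group if standardize_within_group else None
    if standardize_within_group and inp.group is None:
        raise ValueError("within-group standardization requires group labels")
    Xz = _zscore(inp.X, group)
    Yz = _zscore(inp.Y, group)
    R, U, S, V = _corr_svd(Xz, Yz)
    lx = Xz @ U[:, 0]
    ly = Yz @ V[:, 0]
    glc = {}
    if inp.group is not None:
        for g in np.unique(inp.group):
            sel = inp.group == g
            if sel.sum() >= 3:
                glc[str(g)] = float(np.corrcoef(lx[sel], ly[sel])[0, 1])
    return PLSCResult(
        singular_values=S, neural_saliences=U, behavior_saliences=V,
        latent_x=lx, latent_y=ly, R=R,
        group_latent_correlations=glc,
        x_names=inp.x_names, y_names=inp.y_names,
    )


def permutation_test(
    inp: PLSCInput,
    n_perm: int = 10000,
    seed: int = 0,
    standardize_within_group: bool = False,
) -> float:
    """Permutation p for LV1: rows of Y are shuffled relative to X and
    the first singular value recomputed; p uses the add-one convention."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    group = inp.group if standardize_within_group else None
    Xz = _zscore(inp.X, group)
    Yz = _zscore(inp.Y, group)
    n = Xz.shape[0]
    _, _, S, _ = _corr_svd(Xz, Yz)
    s_obs = S[0]
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    Yp = Yz[perms]                                     # (P, n, q)
    Rp = np.einsum("np,knq->kpq", Xz, Yp) / n
    s_perm = np.linalg.svd(Rp, compute_uv=False)[:, 0]
    return float((1 + np.sum(s_perm >= s_obs)) / (n_perm + 1))


def bootstrap_ratios(
    inp: PLSCInput,
    n_boot: int = 10000,
    seed: int = 0,
    standardize_within_group: bool = False,
    stratify_by_group: bool = False,
) -> np.ndarray:
    """Bootstrap ratios of the LV1 neural saliences.

    Subjects are resampled with replacement (optionally stratified within
    age group); per resample the PLSC is refit, LV1 saliences are sign-
    aligned to the original solution by dot product, and the BSR is the
    original salience divided by the bootstrap SE (floored at 1e-12).
    Degenerate resamples with a constant column are redrawn (count
    logged).
    """
    if inp.X.shape[0] < 4:
        raise ValueError("need n >= 4 subjects")
    group = inp.group if standardize_within_group else None
    Xz = _zscore(inp.X, group)
    Yz = _zscore(inp.Y, group)
    _, U, _, V = _corr_svd(Xz, Yz)
    u0 = U[:, 0]
    n = inp.X.shape[0]
    rng = np.random.default_rng(seed)
    samples = np.empty((n_boot, len(u0)))
    n_redrawn = 0
    groups = inp.group
    for b in range(n_boot):
        while True:
            if stratify_by_group and groups is not None:
                idx = np.concatenate([
                    rng.choice(np.flatnonzero(groups == g),
                               size=int(np.sum(groups == g)), replace=True)
                    for g in np.unique(groups)
                ])
            else:
                idx = rng.integers(0, n, size=n)
            Xb, Yb = inp.X[idx], inp.Y[idx]
            if Xb.std(axis=0).min() == 0 or Yb.std(axis=0).min() == 0:
                n_redrawn += 1
                continue
            break
        gb = groups[idx] if (group is not None) else None
        Xbz = _zscore(Xb, gb)
        Ybz = _zscore(Yb, gb)
        _, Ub, _, _ = _corr_svd(Xbz, Ybz)
        ub = Ub[:, 0]
        if ub @ u0 < 0:
            ub = -ub
        samples[b] = ub
    if n_redrawn:
        logger.info("bootstrap_ratios: %d degenerate resamples redrawn", n_redrawn)
    se = samples.std(axis=0, ddof=1)
    return u0 / np.maximum(se, SE_FLOOR)


def plsc_analysis(
    inp: PLSCInput,
    n_perm: int = 10000,
    n_boot: int = 10000,
    seed: int = 0,
    standardize_within_group: bool = False,
) -> PLSCResult:
    """Fit + permutation test + bootstrap ratios with seeds derived from
    one master seed."""
    ss = np.random.SeedSequence(seed)
    s_perm, s_boot = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2)]
    res = plsc_fit(inp, standardize_within_group)
    res.p_perm = permutation_test(inp, n_perm=n_perm, seed=s_perm,
                                  standardize_within_group=standardize_within_group)
    res.bootstrap_ratios = bootstrap_ratios(
        inp, n_boot=n_boot, seed=s_boot,
        standardize_within_group=standardize_within_group)
    return res


def plsc_input_from_frame(
    frame: pd.DataFrame,
    behavior_cols: list[str],
    neural_cols: list[str],
    group_col: str = "group",
) -> PLSCInput:
    """Build a PLSCInput from a subjects-by-measures table."""
    group = frame[group_col].to_numpy() if group_col in frame else None
    return PLSCInput(
        X=frame[neural_cols].to_numpy(dtype=float),
        Y=frame[behavior_cols].to_numpy(dtype=float),
        group=group, x_names=list(neural_cols), y_names=list(behavior_cols),
    )
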