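"""Least-squares-single (LSS) trial-wise GLM on BOLD runs.

Each trial gets its own model: one regressor for the target trial, one for
all other trials in the same run, six motion series, a dummy-volume
indicator and an intercept.  Event regressors are impulse ("stick")
functions at stimulus onset convolved with a canonical double-gamma
hemodynamic response; the target column's coefficient is that trial's
beta image.  An implicit intensity mask (SPM-style fraction of the grand
mean) marks low-signal voxels as missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import BetaSeries, default_affine

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HrfSpec:
    """Canonical double-gamma HRF parameters (seconds), SPM defaults."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    dispersion: float = 1.0
    u_dispersion: float = 1.0
    ratio: float = 1.0 / 6.0
    duration: float = 32.0


def canonical_hrf(spec: HrfSpec = HrfSpec(), dt: float = 0.1) -> np.ndarray:
    """Sample the double-gamma HRF on [0, duration] at step dt, unit sum."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, spec.duration + dt / 2, dt)
    peak = stats.gamma.pdf(t, spec.peak_delay / spec.dispersion,
                           scale=spec.dispersion)
    undershoot = stats.gamma.pdf(t, spec.undershoot_delay / spec.u_dispersion,
                                 scale=spec.u_dispersion)
    kernel = peak - spec.ratio * undershoot
    return kernel / kernel.sum()


@dataclass
class RunBold:
    """One BOLD run: 4D data plus per-trial onsets and nuisance series."""

    data: np.ndarray                      # (x, y, z, n_volumes)
    tr_seconds: float
    onsets: np.ndarray                    # per-trial onset (s), increasing
    trial_ids: np.ndarray
    nuisance: np.ndarray | None = None    # (n_volumes, 6) motion series
    n_dummy: int = 3
    affine: np.ndarray = field(default_factory=lambda: default_affine(2.0))

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.trial_ids = np.asarray(self.trial_ids)
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if self.nuisance is not None:
            self.nuisance = np.asarray(self.nuisance, dtype=float)
            if self.nuisance.shape[0] != self.n_volumes:
                raise ValueError("nuisance length must equal number of volumes")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def n_trials(self) -> int:
        return len(self.onsets)


def _convolved_regressor(onsets: np.ndarray, n_volumes: float, tr: float,
                         hrf_spec: HrfSpec, dt: float = 0.1) -> np.ndarray:
    """Stick functions at onsets convolved with the HRF, sampled at the TR."""
    kernel = canonical_hrf(hrf_spec, dt)
    n_fine = int(np.ceil(n_volumes * tr / dt)) + len(kernel)
    fine = np.zeros(n_fine)
    idx = np.round(np.asarray(onsets) / dt).astype(int)
    np.add.at(fine, idx, 1.0)
    conv = np.convolve(fine, kernel)[:n_fine]
    vol_times = np.arange(n_volumes) * tr
    return conv[np.round(vol_times / dt).astype(int)]


def build_lss_design(run: RunBold, target_trial: int,
                     hrf_spec: HrfSpec = HrfSpec()) -> tuple[np.ndarray, list[str]]:
    """LSS design matrix for one target trial within its run.

    Columns: target regressor, all-other-trials regressor, any motion
    series, a dummy-volume indicator (first ``n_dummy`` volumes) and an
    intercept.  Nuisance columns are identical across target trials of
    the same run by construction.
    """
    if not 0 <= target_trial < run.n_trials:
        raise IndexError(f"target_trial {target_trial} outside run")
    others = np.delete(np.arange(run.n_trials), target_trial)
    cols = [_convolved_regressor(run.onsets[[target_trial]], run.n_volumes,
                                 run.tr_seconds, hrf_spec)]
    names = ["target"]
    other_col = (
        _convolved_regressor(run.onsets[others], run.n_volumes,
                             run.tr_seconds, hrf_spec)
        if len(others) else np.zeros(run.n_volumes)
    )
    if len(others) == 0:
        logger.warning("run has a single trial: all-other-trials column is zero")
    cols.append(other_col)
    names.append("others")
    if run.nuisance is not None:
        for j in range(run.nuisance.shape[1]):
            cols.append(run.nuisance[:, j])
            names.append(f"motion{j + 1}")
    if run.n_dummy > 0:
        dummy = np.zeros(run.n_volumes)
        dummy[: run.n_dummy] = 1.0
        cols.append(dummy)
        names.append("dummy")
    cols.append(np.ones(run.n_volumes))
    names.append("intercept")
    return np.column_stack(cols), names


def compute_implicit_mask(runs: list[RunBold], mask_threshold: float = 0.4) -> np.ndarray:
    """SPM-style implicit mask: flat boolean, voxel kept if its mean signal
    over all volumes exceeds ``mask_threshold`` x the grand mean of voxel
    means."""
    means = np.mean(
        [run.data.reshape(-1, run.n_volumes).mean(axis=1) for run in runs],
        axis=0,
    )
    grand = means.mean()
    if grand <= 0:
        # degenerate intensity scale (e.g., zero-mean data): masking by a
        # fraction of the grand mean is meaningless, keep every voxel
        return np.ones_like(means, dtype=bool)
    return means > mask_threshold * grand


def fit_trial_betas(
    runs: list[RunBold],
    mask_threshold: float = 0.4,
    hrf_spec: HrfSpec = HrfSpec(),
) -> BetaSeries:
    """Fit one LSS model per trial across runs, returning a beta stack.

    Rows are ordered by trial_id.  Out-of-mask voxels are NaN.  Rank-
    deficient designs fall back to the pseudo-inverse with a warning.
    """
    if not runs:
        raise ValueError("no runs supplied")
    grid_shape = runs[0].data.shape[:3]
    for run in runs:
        if run.data.shape[:3] != grid_shape:
            raise ValueError("all runs must share the same grid")
    mask = compute_implicit_mask(runs, mask_threshold)

    betas, trial_ids = [], []
    for run in runs:
        Y = run.data.reshape(-1, run.n_volumes).T.astype(float)  # (vols, vox)
        for t in range(run.n_trials):
            X, _ = build_lss_design(run, t, hrf_spec)
            rank = np.linalg.matrix_rank(X)
            if rank < X.shape[1]:
                logger.warning(
                    "rank-deficient LSS design (rank %d < %d cols); "
                    "using pseudo-inverse", rank, X.shape[1],
                )
            coef = np.linalg.pinv(X) @ Y
            beta = coef[0]
            beta[~mask] = np.nan
            betas.append(beta)
            trial_ids.append(run.trial_ids[t])

    order = np.argsort(trial_ids)
    data = np.asarray(betas, dtype=np.float32)[order]
    return BetaSeries(
        data=data,
        mask=mask,
        grid_shape=grid_shape,
        affine=runs[0].affine,
        trial_ids=np.asarray(trial_ids)[order],
    )


def simulate_bold(
    true_betas: np.ndarray,
    onsets: np.ndarray,
    trial_ids: np.ndarray,
    grid_shape: tuple[int, int, int],
    tr_seconds: float = 2.307,
    n_rest_volumes: int = 8,
    baseline: float = 100.0,
    noise_sd: float = 0.0,
    hrf_spec: HrfSpec = HrfSpec(),
    nuisance: np.ndarray | None = None,
    n_dummy: int = 3,
    seed: int = 0,
) -> RunBold:
    """Forward-model a BOLD run from known trial betas.

    ``true_betas`` is (n_trials, n_voxels); each trial contributes its
    stick-convolved HRF time course scaled by its beta map, on top of a
    constant baseline, with optional white noise.  Used to exercise the
    LSS estimator against known ground truth.
    """
    onsets = np.asarray(onsets, dtype=float)
    n_trials, n_vox = true_betas.shape
    kernel = canonical_hrf(hrf_spec)
    n_volumes = int(np.ceil((onsets[-1] + hrf_spec.duration) / tr_seconds)) + n_rest_volumes
    rng = np.random.default_rng(seed)
    Y = np.full((n_volumes, n_vox), float(baseline))
    for t in range(n_trials):
        reg = _convolved_regressor(onsets[[t]], n_volumes, tr_seconds, hrf_spec)
        Y += reg[:, None] * true_betas[t][None, :]
    if nuisance is not None:
        # unit loading on each motion series, shared across voxels
        Y += np.asarray(nuisance, dtype=float).sum(axis=1, keepdims=True)
    if noise_sd > 0:
        Y += noise_sd * rng.standard_normal(Y.shape)
    data = Y.T.reshape(*grid_shape, n_volumes)
    return RunBold(
        data=data, tr_seconds=tr_seconds, onsets=onsets,
        trial_ids=np.asarray(trial_ids), nuisance=nuisance, n_dummy=n_dummy,
        affine=default_affine(2.0),
    )


def events_table(run: RunBold) -> pd.DataFrame:
    """BIDS-events-flavored table (onset, duration, trial_type, trial_id)."""
    return pd.DataFrame({
        "onset": run.onsets,
        "duration": 0.0,
        "trial_type": "stimulus",
        "trial_id": run.trial_ids,
    })
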