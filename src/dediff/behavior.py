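"""Behavioral scoring and distinctiveness-memory association analyses.

Recognition performance is summarized as Pr, the proportion of correct
responses pooling hits and correct rejections, separately for item
(object old/new) and pair (object-scene pairing old/new) judgments.
Item Pr is compared against a chance level that accounts for the old/new
trial ratio, and response bias is FAR / (1 - (HR - FAR)).

Trial-wise associations (memory ~ distinctiveness; item ~ category
distinctiveness) use a two-stage summary-statistics scheme: a slope per
subject (logistic for binary outcomes, least squares otherwise), then
one-sample and two-sample t tests on the slopes for the main effect and
the age interaction — a light-weight stand-in for random-slopes mixed
models that is exact under balanced designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .searchlight import (
    DistinctivenessMaps,
    SearchlightSpec,
    distinctiveness_maps,
)
from .synthetic import RETRIEVAL, BetaSeries

logger = logging.getLogger(__name__)

SLOPE_CLIP = 10.0


@dataclass
class BehavioralScores:
    pr_item: float
    pr_pair: float
    hr: float
    far: float
    bias: float
    chance: float
    above_chance: bool
    n_old: int
    n_new: int


def chance_level(p_response: float, n_old: int, n_total: int) -> float:
    """Chance proportion correct: response probability times the old-trial
    fraction (e.g., 0.5 * 250/400 = 0.3125, reported as 0.31)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 < n_old <= n_total:
        raise ValueError("need 0 < n_old <= n_total")
    return p_response * n_old / n_total


def response_bias(hr: float, far: float) -> float:
    """Recognition response bias FAR / (1 - (HR - FAR)).

    The denominator vanishes only at perfect discrimination (HR = 1,
    FAR = 0), where the numerator vanishes too; the limit 0 is returned.
    """
    if not (0.0 <= hr <= 1.0 and 0.0 <= far <= 1.0):
        raise ValueError("HR and FAR must lie in [0, 1]")
    denom = 1.0 - (hr - far)
    if denom == 0:
        return 0.0
    return far / denom


def memory_scores(design: pd.DataFrame,
                  pair_conditional_on_item: bool = False) -> BehavioralScores:
    """Score retrieval outcomes into Pr, HR/FAR and bias.

    Pr pools hits and correct rejections over all scored old and new
    trials.  Pair judgments are scored on every old-pair trial by
    default; ``pair_conditional_on_item`` restricts pair scoring to
    trials with a correct item response.
    """
    ret = design[design["phase"] == RETRIEVAL]
    if len(ret) == 0:
        raise ValueError("no retrieval trials in design")
    old = ret[ret["retrieval_condition"].astype(str).str.startswith("old")]
    new = ret[ret["retrieval_condition"] == "new"]
    old = old[old["item_outcome"].isin(["hit", "miss"])]
    new = new[new["item_outcome"].isin(["corr_rej", "false_alarm"])]
    n_old, n_new = len(old), len(new)
    if n_old == 0 or n_new == 0:
        raise ValueError("retrieval outcomes missing")
    hits = int((old["item_outcome"] == "hit").sum())
    crs = int((new["item_outcome"] == "corr_rej").sum())
    fas = n_new - crs
    pr_item = (hits + crs) / (n_old + n_new)
    hr = hits / n_old
    far = fas / n_new

    pair_trials = ret[ret["pair_outcome"].isin(["correct", "incorrect"])]
    if pair_conditional_on_item:
        pair_trials = pair_trials[
            pair_trials["item_outcome"].isin(["hit", "corr_rej"])]
    pr_pair = (
        float((pair_trials["pair_outcome"] == "correct").mean())
        if len(pair_trials) else np.nan
    )
    chance = chance_level(0.5, n_old, n_old + n_new)
    return BehavioralScores(
        pr_item=pr_item, pr_pair=pr_pair, hr=hr, far=far,
        bias=response_bias(hr, far), chance=chance,
        above_chance=pr_item > chance, n_old=n_old, n_new=n_new,
    )


# ---------------------------------------------------------------------------
# Subsequent-memory split maps
# ---------------------------------------------------------------------------

class SubsetTooSmall(ValueError):
    """Raised when a memory-outcome subset has fewer than two objects."""


@dataclass
class MemorySplitMaps:
    """Distinctiveness maps over remembered and forgotten objects plus
    their (remembered - forgotten) differences."""

    remembered: DistinctivenessMaps
    forgotten: DistinctivenessMaps
    subject_id: str = ""

    def difference(self, metric: str) -> np.ndarray:
        return getattr(self.remembered, metric) - getattr(self.forgotten, metric)


def memory_outcome_objects(design: pd.DataFrame) -> tuple[list[int], list[int]]:
    """Stimulus ids of subsequently remembered (hit) and forgotten (miss)
    old objects."""
    ret = design[(design["phase"] == RETRIEVAL)
                 & design["item_outcome"].isin(["hit", "miss"])]
    remembered = sorted(ret.loc[ret["item_outcome"] == "hit", "stimulus_id"])
    forgotten = sorted(ret.loc[ret["item_outcome"] == "miss", "stimulus_id"])
    return remembered, forgotten


def subsequent_memory_maps(
    betas: BetaSeries,
    design: pd.DataFrame,
    spec: SearchlightSpec = SearchlightSpec(),
    subject_id: str = "",
) -> MemorySplitMaps:
    """Searchlight distinctiveness computed separately over remembered
    and forgotten objects.

    Similarity is averaged within each outcome subset before the
    distinctiveness difference is taken, so the split maps feed the same
    dependent-design cluster test as the main maps.
    """
    remembered, forgotten = memory_outcome_objects(design)
    if len(remembered) < 2 or len(forgotten) < 2:
        raise SubsetTooSmall(
            f"subject {subject_id or '?'}: need >= 2 remembered and >= 2 "
            f"forgotten objects (got {len(remembered)}/{len(forgotten)})"
        )
    td1_obj = design[(design["phase"] == "td1")
                     & (design["category"] == "object")]
    for label, subset in (("remembered", remembered), ("forgotten", forgotten)):
        runs = td1_obj.loc[td1_obj["stimulus_id"].isin(subset), "run"]
        if runs.nunique() < 2:
            raise SubsetTooSmall(
                f"subject {subject_id or '?'}: {label} objects span a single "
                "run; within-category pairs undefined")
    rem = distinctiveness_maps(betas, design, spec, subject_id, objects=remembered)
    forg = distinctiveness_maps(betas, design, spec, subject_id, objects=forgotten)
    return MemorySplitMaps(remembered=rem, forgotten=forg, subject_id=subject_id)


# ---------------------------------------------------------------------------
# Two-stage association analyses
# ---------------------------------------------------------------------------

@dataclass
class TwoStageResult:
    slopes: pd.DataFrame          # subject, group, slope, intercept
    mean_slope: float
    t_main: float
    p_main: float
    t_group: float = np.nan       # two-sample t across age groups
    p_group: float = np.nan
    n_clipped: int = 0


def _logistic_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Per-subject logistic slope via statsmodels GLM; clipped on
    separation or non-convergence."""
    import warnings

    import statsmodels.api as sm

    X = sm.add_constant(x)
    clipped = False
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        intercept, slope = fit.params
        if not np.isfinite(slope) or abs(slope) > SLOPE_CLIP:
            slope = float(np.clip(slope, -SLOPE_CLIP, SLOPE_CLIP))
            clipped = True
    except Exception:  # separation and other degenerate fits
        direction = np.sign(np.corrcoef(x, y)[0, 1]) if x.std() > 0 else 0.0
        slope = direction * SLOPE_CLIP
        intercept = 0.0
        clipped = True
    if not np.isfinite(slope):
        slope, clipped = 0.0, True
    return float(slope), float(intercept), clipped


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(coef[1]), float(coef[0])


def twostage_association(
    trials: pd.DataFrame,
    predictor: str,
    outcome: str,
    binary: bool,
    subject_col: str = "subject",
    group_col: str = "group",
    min_trials: int = 5,
) -> TwoStageResult:
    """Two-stage association between a trial-wise predictor and outcome.

    Stage 1 fits one slope per subject (logistic when ``binary``, else
    ordinary least squares).  Stage 2 tests the slopes: a one-sample t
    against zero for the main effect and, when two groups are present, a
    two-sample t for the group-by-predictor interaction.  Logistic slopes
    are clipped at +/-10 under separation, with the count reported.
    """
    rows = []
    n_clipped = 0
    for (subj, grp), sub in trials.groupby([subject_col, group_col], sort=True):
        sub = sub.dropna(subset=[predictor, outcome])
        if len(sub) < min_trials:
            logger.info("subject %s: only %d usable trials, skipped", subj, len(sub))
            continue
        x = sub[predictor].to_numpy(dtype=float)
        y = sub[outcome].to_numpy(dtype=float)
        if x.std() == 0:
            continue
        if binary:
            slope, intercept, clipped = _logistic_slope(x, y)
            n_clipped += int(clipped)
        else:
            slope, intercept = _ols_slope(x, y)
        rows.append({"subject": subj, "group": grp,
                     "slope": slope, "intercept": intercept})
    if n_clipped:
        logger.warning("twostage_association: %d slopes clipped at +/-%g",
                       n_clipped, SLOPE_CLIP)
    slopes = pd.DataFrame(rows)
    if len(slopes) < 2:
        raise ValueError("fewer than two subjects with estimable slopes")
    s = slopes["slope"].to_numpy()
    t_main, p_main = stats.ttest_1samp(s, 0.0)
    res = TwoStageResult(
        slopes=slopes, mean_slope=float(s.mean()),
        t_main=float(t_main), p_main=float(p_main), n_clipped=n_clipped,
    )
    groups = slopes["group"].unique()
    if len(groups) == 2:
        g0 = slopes.loc[slopes["group"] == groups[0], "slope"]
        g1 = slopes.loc[slopes["group"] == groups[1], "slope"]
        if len(g0) >= 2 and len(g1) >= 2:
            t_g, p_g = stats.ttest_ind(g0, g1)
            res.t_group, res.p_group = float(t_g), float(p_g)
    return res
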