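"""Dwell-time proportions, binned time courses and trial-duration tests.

Time courses follow the usual convention for free-viewing dynamics:
adjacent, non-overlapping 50 ms bins (default 150-3000 ms of viewing
time), with a fixation contributing to every bin its interval
[onset, onset + duration) overlaps. The observer is the unit of
analysis: curves are computed per observer first, then averaged, with a
95% t-based confidence interval across observers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dir_classify import CLASSES, DIRLabels
from .errors import ContractError
from .gaze_io import Trial

__all__ = [
    "TIMECOURSE_CLASSES",
    "TimeCourse",
    "GroupComparison",
    "default_edges",
    "dwell_proportions",
    "bin_timecourse",
    "compare_groups_bootstrap",
]

#: classes of the proportion time course (exhaustive at margin 0)
TIMECOURSE_CLASSES: tuple[str, ...] = ("D", "I", "R", "unlabelled")


def default_edges(t0: float = 150.0, t1: float = 3000.0, width: float = 50.0
                  ) -> np.ndarray:
    """Adjacent, non-overlapping bin edges [t0, t0+width, ..., t1]."""
    return np.arange(t0, t1 + width / 2, width)


def dwell_proportions(
    labels: DIRLabels, trial: Trial, classes: Sequence[str] = TIMECOURSE_CLASSES
) -> dict[str, float]:
    """Per-class share of total fixation duration in one trial.

    Each class is normalised independently by the trial's total fixation
    duration, so a fixation carrying several class flags (margin-induced
    multi-labels) contributes its full duration to each of them; with
    margin 0 the four classes partition the total. Empty trial returns
    NaN for every class.
    """
    if len(labels) != len(trial):
        raise ContractError("labels and trial differ in fixation count")
    total = sum(f.duration for f in trial.fixations)
    if total == 0:
        return {c: float("nan") for c in classes}
    out = {}
    for c in classes:
        out[c] = (
            sum(f.duration for f, l in zip(trial.fixations, labels)
                if l.has_class(c))
            / total
        )
    return out


@dataclass
class TimeCourse:
    """Binned per-class curves with across-observer mean and 95% CI.

    ``per_observer`` has shape (n_observers, n_classes, n_bins) with NaN
    where an observer contributes no fixation to a bin.
    """

    edges: np.ndarray
    classes: tuple[str, ...]
    quantity: str
    observer_ids: tuple[str, ...]
    per_observer: np.ndarray
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: bin_lo, bin_hi, class, mean, ci_lo, ci_hi, n."""
        rows = []
        n_obs = (~np.isnan(self.per_observer)).sum(axis=0)
        for ci, c in enumerate(self.classes):
            for b in range(len(self.edges) - 1):
                rows.append(
                    {
                        "bin_lo": self.edges[b],
                        "bin_hi": self.edges[b + 1],
                        "class": c,
                        "mean": self.mean[ci, b],
                        "ci_lo": self.ci_lo[ci, b],
                        "ci_hi": self.ci_hi[ci, b],
                        "n_observers": int(n_obs[ci, b]),
                    }
                )
        return pd.DataFrame(rows)


def _overlap(onset: float, offset: float, lo: float, hi: float) -> float:
    """Length of [onset, offset) ∩ [lo, hi)."""
    return max(0.0, min(offset, hi) - max(onset, lo))


def bin_timecourse(
    corpus: Iterable[tuple[Trial, DIRLabels]],
    edges: np.ndarray | None = None,
    quantity: str = "proportion",
    weighting: str = "overlap",
) -> TimeCourse:
    """Per-class time course across viewing time.

    quantity
        ``"proportion"`` — class dwell share per bin. With the default
        ``weighting="overlap"`` a fixation contributes the length of its
        intersection with the bin; ``weighting="full"`` attributes its
        whole duration to every overlapped bin.
        ``"duration"`` — mean full duration of class-c fixations
        overlapping the bin.
        ``"saccade_amplitude"`` — mean Euclidean distance to the previous
        fixation, over class-c fixations (index >= 1) overlapping the bin.
    Bins with no overlapping class fixation are NaN, not zero.
    """
    if edges is None:
        edges = default_edges()
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ContractError("bin edges must be strictly increasing")
    if quantity not in ("proportion", "duration", "saccade_amplitude"):
        raise ContractError(f"unknown quantity '{quantity}'")
    classes = TIMECOURSE_CLASSES if quantity == "proportion" else CLASSES
    n_bins = len(edges) - 1

    # accumulate per observer
    num: dict[str, np.ndarray] = {}
    den: dict[str, np.ndarray] = {}

    def obs_arrays(obs):
        if obs not in num:
            num[obs] = np.zeros((len(classes), n_bins))
            den[obs] = np.zeros((len(classes), n_bins))
        return num[obs], den[obs]

    for trial, labels in corpus:
        if len(trial) != len(labels):
            raise ContractError("trial/labels length mismatch")
        n_arr, d_arr = obs_arrays(trial.observer_id)
        prev = None
        for fix, lab in zip(trial.fixations, labels):
            b0 = int(np.searchsorted(edges, fix.onset, side="right")) - 1
            b1 = int(np.searchsorted(edges, fix.offset, side="left"))
            for b in range(max(b0, 0), min(b1, n_bins)):
                ov = _overlap(fix.onset, fix.offset, edges[b], edges[b + 1])
                if ov <= 0:
                    continue
                w = ov if weighting == "overlap" else fix.duration
                for ci, c in enumerate(classes):
                    flagged = lab.has_class(c)
                    if quantity == "proportion":
                        d_arr[ci, b] += w
                        if flagged:
                            n_arr[ci, b] += w
                    elif flagged:
                        if quantity == "duration":
                            n_arr[ci, b] += fix.duration
                            d_arr[ci, b] += 1
                        elif prev is not None:
                            dist = float(np.hypot(fix.x - prev.x, fix.y - prev.y))
                            n_arr[ci, b] += dist
                            d_arr[ci, b] += 1
            prev = fix

    observer_ids = tuple(sorted(num))
    per_obs = np.full((len(observer_ids), len(classes), n_bins), np.nan)
    for k, obs in enumerate(observer_ids):
        with np.errstate(invalid="ignore", divide="ignore"):
            per_obs[k] = np.where(den[obs] > 0, num[obs] / den[obs], np.nan)
    mean, lo, hi = _mean_ci(per_obs)
    return TimeCourse(
        edges=edges, classes=classes, quantity=quantity,
        observer_ids=observer_ids, per_observer=per_obs,
        mean=mean, ci_lo=lo, ci_hi=hi,
    )


def _mean_ci(per_obs: np.ndarray, level: float = 0.95):
    """Across-observer mean and t-based CI, NaN-aware."""
    import warnings as _warnings

    n = (~np.isnan(per_obs)).sum(axis=0)
    with _warnings.catch_warnings(), np.errstate(invalid="ignore"):
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(n > 0, per_obs, np.nan), axis=0)
        sd = np.nanstd(per_obs, axis=0, ddof=1)
    se = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    tcrit = np.where(n > 1, stats.t.ppf((1 + level) / 2, np.maximum(n - 1, 1)),
                     np.nan)
    return mean, mean - tcrit * se, mean + tcrit * se


@dataclass
class GroupComparison:
    """Pooled-resampling comparison of per-observer statistics.

    ``mean_diff[c]`` is mean(small group) - mean(large group);
    ``p_adjusted`` applies Bonferroni over the compared classes.
    """

    classes: tuple[str, ...]
    mean_diff: dict[str, float]
    p_raw: dict[str, float]
    p_adjusted: dict[str, float]
    n_small: int
    n_large: int
    n_draw: int
    n_boot: int
    seed: int


def compare_groups_bootstrap(
    group_small: Mapping[str, Sequence[float]] | pd.DataFrame,
    group_large: Mapping[str, Sequence[float]] | pd.DataFrame,
    n_boot: int = 10000,
    seed: int = 0,
    n_draw: int | None = None,
    two_sided: bool = True,
) -> GroupComparison:
    """Test per-class group differences by resampling from the pooled data.

    Both arguments map class name to per-observer statistics (e.g. dwell
    proportions over a common time range). All observers are pooled; each
    iteration draws ``n_draw`` (default: the small group's size) without
    replacement and records the mean. The raw p compares the small
    group's observed mean against this null (two-sided by default, ties
    extreme, add-one correction); Bonferroni multiplies by the number of
    classes.
    """
    small = pd.DataFrame(group_small)
    large = pd.DataFrame(group_large)
    if sorted(small.columns) != sorted(large.columns):
        raise ContractError("groups must share the same class columns")
    classes = tuple(small.columns)
    rng = np.random.default_rng(seed)
    if n_draw is None:
        n_draw = len(small)
    mean_diff, p_raw, p_adj = {}, {}, {}
    for c in classes:
        a = np.asarray(small[c], dtype=float)
        b = np.asarray(large[c], dtype=float)
        pool = np.concatenate([a, b])
        if n_draw > pool.size:
            raise ContractError("n_draw exceeds the pooled sample size")
        observed = a.mean()
        pooled_mean = pool.mean()
        boot = np.empty(n_boot)
        for k in range(n_boot):
            idx = rng.choice(pool.size, size=n_draw, replace=False)
            boot[k] = pool[idx].mean()
        if two_sided:
            extreme = np.abs(boot - pooled_mean) >= abs(observed - pooled_mean)
        else:
            extreme = boot - pooled_mean >= observed - pooled_mean
        p = (1 + int(extreme.sum())) / (n_boot + 1)
        mean_diff[c] = float(observed - b.mean())
        p_raw[c] = float(p)
        p_adj[c] = float(min(1.0, len(classes) * p))
    return GroupComparison(
        classes=classes, mean_diff=mean_diff, p_raw=p_raw, p_adjusted=p_adj,
        n_small=len(small), n_large=len(large), n_draw=n_draw,
        n_boot=n_boot, seed=seed,
    )
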