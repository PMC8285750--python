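"""Analysis layer: level-difference trajectories, plateau (balance-point)
detection, hand-trace asymmetry summaries, questionnaire scoring and the
group statistics used to characterize cohorts.

The central performance measure of the adaptive task is the level
difference: the difficulty level in round r minus the starting level,
averaged across sessions round by round.  A cohort started well below its
ability shows a steep initial rise; a plateau marks the balance point where
performance stays between the level-up and level-down thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .simulator import HandTrace, SessionRecord, WORKSPACE_HALFWIDTH_M


@dataclass(frozen=True)
class LevelTrajectorySummary:
    """Per-round mean level difference across sessions (ragged pooling)."""

    mean_diff: np.ndarray   # per-round mean of (level - starting level)
    se: np.ndarray          # sd / sqrt(n) per round
    n: np.ndarray           # sessions contributing each round


@dataclass(frozen=True)
class HandTraceSummary:
    mean_x: float
    median_x: float
    iqr_x: float
    shift_index: float  # mean_x / workspace half-width, in [-1, 1]


def level_difference_trajectory(
    sessions: Sequence[SessionRecord] | Sequence[Sequence[int]],
) -> LevelTrajectorySummary:
    """Mean and SE of the per-round level difference over sessions.

    Accepts SessionRecords or raw level trajectories.  Sessions may have
    unequal round counts (patient protocols); each round pools only the
    sessions that reached it, with SE = sd / sqrt(n) over those sessions.
    """
    trajs = [
        list(s.level_trajectory) if isinstance(s, SessionRecord) else list(s)
        for s in sessions
    ]
    if not trajs or any(len(t) == 0 for t in trajs):
        raise ValueError("need at least one session with at least one round")
    n_rounds = max(len(t) for t in trajs)
    diffs = np.full((len(trajs), n_rounds), np.nan)
    for i, t in enumerate(trajs):
        diffs[i, :len(t)] = np.asarray(t, dtype=float) - t[0]
    n = np.sum(~np.isnan(diffs), axis=0)
    mean = np.nanmean(diffs, axis=0)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(diffs, axis=0, ddof=0)
    se = np.where(n > 0, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return LevelTrajectorySummary(mean_diff=mean, se=se, n=n)


def detect_plateau(trajectory: Sequence[int], plateau_tolerance: int = 1,
                   min_window: int = 3) -> Optional[tuple[int, int]]:
    """Earliest balance-point plateau of a level trajectory.

    Returns ``(plateau_start_round, plateau_level)`` (1-based round) for
    the earliest round r such that the levels from r to the end span at
    most ``plateau_tolerance`` levels over a window of at least
    ``min_window`` rounds, with the plateau level the rounded mean of that
    window.  The plateau starts where the trajectory first sits at its
    settled level (the round-r level must equal the plateau level), not on
    the approach to it.  None if no such round exists.
    """
    levels = np.asarray(list(trajectory), dtype=float)
    if len(levels) < min_window:
        raise ValueError(f"need at least {min_window} rounds, got {len(levels)}")
    for start in range(0, len(levels) - min_window + 1):
        window = levels[start:]
        if window.max() - window.min() <= plateau_tolerance:
            # round half up so the result shifts consistently with the levels
            plateau_level = math.floor(float(window.mean()) + 0.5)
            if levels[start] == plateau_level:
                return start + 1, plateau_level
    return None


def hand_trace_summary(trace: HandTrace) -> HandTraceSummary:
    """Lateral summary of a hand trace; shift index is mean x normalized by
    the 1 m workspace half-width."""
    if len(trace) == 0:
        raise ValueError("hand trace is empty")
    x = np.asarray(trace.x, dtype=float)
    q75, q25 = np.percentile(x, [75, 25])
    return HandTraceSummary(
        mean_x=float(x.mean()),
        median_x=float(np.median(x)),
        iqr_x=float(q75 - q25),
        shift_index=float(x.mean() / WORKSPACE_HALFWIDTH_M),
    )


# Likert ranges and scoring rule per instrument: (lo, hi, aggregate-by-mean)
_INSTRUMENTS = {
    "SUS": (1, 5, True),    # usability, mean of 3 items
    "SSQ": (1, 4, True),    # simulator sickness, mean of 7 items
    "IPQ": (1, 5, False),   # presence/immersion, per-item
    "PGTQ": (1, 7, False),  # game perception, per-item
}


def score_questionnaire(instrument: str, items: Sequence[float]):
    """Score a questionnaire response.

    SUS and SSQ return the mean of their items; IPQ and PGTQ are scored per
    item and returned unchanged (as a list).
    """
    if instrument not in _INSTRUMENTS:
        raise ValueError(
            f"unknown instrument {instrument!r}; expected one of {sorted(_INSTRUMENTS)}"
        )
    lo, hi, take_mean = _INSTRUMENTS[instrument]
    vals = [float(v) for v in items]
    if not vals:
        raise ValueError("no item scores given")
    for v in vals:
        if not lo <= v <= hi:
            raise ValueError(
                f"{instrument} item score {v} outside Likert range [{lo}, {hi}]"
            )
    return float(np.mean(vals)) if take_mean else vals


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sided t test.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both groups have zero variance; t is undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided p via the t transformation."""
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if len(xa) != len(ya):
        raise ValueError("x and y must have equal length")
    if len(xa) < 3:
        raise ValueError("need at least 3 paired values")
    if xa.var() == 0 or ya.var() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)
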