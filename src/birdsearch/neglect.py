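"""Neglect-severity metrics: the Center of Cancellation (CoC) statistic on
cancellation sheets, a lambda-driven cancellation simulator, and lateralized
search-time summaries of simulated sessions.

The CoC summarizes the horizontal distribution of the targets a patient
marks on a paper-and-pencil cancellation sheet (40 targets among 240
distractors).  Each target gets a normalized horizontal coordinate in
[-1, 1] (sheet center = 0, leftmost/rightmost target column = -/+1); the
CoC is the mean normalized coordinate over the marked targets.  Zero means
no spatial bias; CoC >= 0.081 indicates a significant rightward shift of
the marks, i.e. left-sided neglect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .simulator import SessionRecord


COC_CUTOFF = 0.081


def is_significant_left_neglect(value: float) -> bool:
    """Classify a CoC value against the 0.081 cutoff (inclusive)."""
    return value >= COC_CUTOFF


@dataclass(frozen=True)
class CancellationSheet:
    """Target and distractor positions (sheet millimeters, x rightward)."""

    target_positions: np.ndarray   # (n_targets, 2)
    distractor_positions: np.ndarray  # (n_distractors, 2)
    width: float
    height: float

    def __post_init__(self) -> None:
        for name in ("target_positions", "distractor_positions"):
            pos = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, pos)
            if pos.ndim != 2 or pos.shape[1] != 2:
                raise ValueError(f"{name} must be an (n, 2) array")
            if len(pos) and (
                pos[:, 0].min() < 0 or pos[:, 0].max() > self.width
                or pos[:, 1].min() < 0 or pos[:, 1].max() > self.height
            ):
                raise ValueError(f"{name} out of sheet bounds")
        if len(self.target_positions) == 0:
            raise ValueError("sheet must contain at least one target")

    @property
    def n_targets(self) -> int:
        return len(self.target_positions)

    def normalized_x(self) -> np.ndarray:
        """Per-target horizontal coordinate: 0 at sheet center, +/-1 at the
        farther of the leftmost/rightmost target columns (linear between)."""
        x = self.target_positions[:, 0]
        center = self.width / 2.0
        span = max(x.max() - center, center - x.min())
        if span == 0:
            return np.zeros_like(x)
        return (x - center) / span


def default_sheet(width: float = 297.0, height: float = 210.0,
                  margin: float = 20.0) -> CancellationSheet:
    """Synthetic stand-in for the 40-target / 240-distractor cancellation
    sheet: targets on a regular 8x5 grid interleaved among distractors on a
    24x10 grid, left-right symmetric."""
    tx = np.linspace(margin, width - margin, 8)
    ty = np.linspace(margin, height - margin, 5)
    targets = np.array([(x, y) for y in ty for x in tx])
    dx = np.linspace(margin, width - margin, 24)
    dy = np.linspace(margin, height - margin, 10)
    distractors = np.array([(x, y) for y in dy for x in dx])
    return CancellationSheet(target_positions=targets,
                             distractor_positions=distractors,
                             width=width, height=height)


@dataclass(frozen=True)
class CoCResult:
    coc: float
    n_marked: int
    significant_left_neglect: bool
    raw_mean_deviation: float  # mean x deviation from sheet center, mm

    def __post_init__(self) -> None:
        if not -1.0 <= self.coc <= 1.0:
            raise ValueError(f"coc out of [-1, 1]: {self.coc}")


def coc(sheet: CancellationSheet, marks: Sequence[int]) -> CoCResult:
    """Center of Cancellation over the marked targets.

    ``marks`` are indices into ``sheet.target_positions``.  An empty mark
    set is an error: CoC = 0 means "no bias", not "no data".
    """
    idx = np.asarray(list(marks), dtype=int)
    if idx.size == 0:
        raise ValueError("CoC is undefined for an empty mark set")
    if len(np.unique(idx)) != idx.size:
        raise ValueError("mark indices must be unique")
    if idx.min() < 0 or idx.max() >= sheet.n_targets:
        raise ValueError(
            f"mark indices must be in [0, {sheet.n_targets - 1}]"
        )
    xn = sheet.normalized_x()[idx]
    value = float(xn.mean())
    center = sheet.width / 2.0
    raw = float((sheet.target_positions[idx, 0] - center).mean())
    return CoCResult(
        coc=value,
        n_marked=int(idx.size),
        significant_left_neglect=is_significant_left_neglect(value),
        raw_mean_deviation=raw,
    )


def simulate_cancellation(lam: float, sheet: CancellationSheet,
                          rng: np.random.Generator) -> list[int]:
    """Simulate a patient with lateral bias ``lam`` marking the sheet.

    Each target is marked independently with probability
    ``p = clip(1 - lam * (1 - xn) / 2, 0, 1)`` where ``xn`` is its
    normalized coordinate: leftward targets are increasingly omitted as
    ``lam`` grows.  If every draw fails, the rightmost target is marked so
    the CoC stays defined.
    """
    if not 0 <= lam <= 1:
        raise ValueError(f"lam must be in [0, 1], got {lam}")
    xn = sheet.normalized_x()
    p = np.clip(1.0 - lam * (1.0 - xn) / 2.0, 0.0, 1.0)
    marked = np.nonzero(rng.random(sheet.n_targets) < p)[0]
    if marked.size == 0:
        marked = np.array([int(np.argmax(sheet.target_positions[:, 0]))])
    return [int(i) for i in marked]


def _found_times(session: SessionRecord, hemispace: Optional[str] = None) -> np.ndarray:
    times = [
        ev.search_time for ev in session.iter_events()
        if ev.found and (hemispace is None or ev.hemispace == hemispace)
    ]
    return np.asarray(times, dtype=float)


def mean_search_time(session: SessionRecord) -> float:
    """Mean search time over found targets; not-found targets are excluded."""
    times = _found_times(session)
    if times.size == 0:
        raise ValueError("mean search time is undefined: no found targets")
    return float(times.mean())


def hemispace_search_times(session: SessionRecord) -> tuple[float, float]:
    """(left, right) mean search times over found targets per hemispace.

    A hemispace with no found target yields NaN rather than raising.
    """
    out = []
    for side in ("left", "right"):
        times = _found_times(session, side)
        out.append(float(times.mean()) if times.size else float("nan"))
    return out[0], out[1]
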