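"""Adaptive difficulty engine: the 15-level parameter table and the
round-to-round level-switching rule.

The task difficulty is controlled by four parameters per level: the maximum
target lifetime (s), the target speed (°/s), and the level-up / level-down
thresholds (% of targets found in a round).  Levels are generated from the
level-1 values by applying a fixed signed change per level.  Between rounds
the level is promoted when the percentage of found targets strictly exceeds
the level-up threshold, demoted when it falls strictly below the level-down
threshold, and held otherwise; the result is clamped to [1, n_levels].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class LevelParameters:
    """Resolved task parameters for one difficulty level.

    Attributes
    ----------
    level : int
        Difficulty level index (1-based).
    lifetime : float
        Maximum presentation time of a target, seconds (> 0).
    speed : float
        Horizontal target speed, degrees/second (> 0).
    level_up_threshold : float
        Percent-found above which the next round is one level harder.
    level_down_threshold : float
        Percent-found below which the next round is one level easier.
    """

    level: int
    lifetime: float
    speed: float
    level_up_threshold: float
    level_down_threshold: float

    def __post_init__(self) -> None:
        if self.lifetime <= 0:
            raise ValueError(f"lifetime must be > 0, got {self.lifetime}")
        if self.speed <= 0:
            raise ValueError(f"speed must be > 0, got {self.speed}")
        for name in ("level_up_threshold", "level_down_threshold"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise ValueError(f"{name} must be in (0, 100), got {v}")
        if self.level_down_threshold >= self.level_up_threshold:
            raise ValueError(
                "level_down_threshold must be below level_up_threshold "
                f"({self.level_down_threshold} >= {self.level_up_threshold})"
            )


@dataclass(frozen=True)
class PerLevelChange:
    """Signed change applied to each parameter when moving up one level."""

    lifetime: float
    speed: float
    level_up_threshold: float
    level_down_threshold: float


@dataclass(frozen=True)
class DifficultyTable:
    """Level-1 parameters plus the per-level deltas generating all levels."""

    level1: LevelParameters
    per_level_change: PerLevelChange
    n_levels: int = 15

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError(f"n_levels must be >= 1, got {self.n_levels}")
        # Every generated level must itself be a valid LevelParameters
        # (positivity, threshold ordering); constructing them checks this.
        for lvl in range(1, self.n_levels + 1):
            level_params(self, lvl)

    def to_dict(self) -> dict:
        return {
            "n_levels": self.n_levels,
            "level1": {
                "lifetime_s": self.level1.lifetime,
                "speed_deg_s": self.level1.speed,
                "up_pct": self.level1.level_up_threshold,
                "down_pct": self.level1.level_down_threshold,
            },
            "change": {
                "lifetime_s": self.per_level_change.lifetime,
                "speed_deg_s": self.per_level_change.speed,
                "up_pct": self.per_level_change.level_up_threshold,
                "down_pct": self.per_level_change.level_down_threshold,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DifficultyTable":
        level1 = LevelParameters(
            level=1,
            lifetime=d["level1"]["lifetime_s"],
            speed=d["level1"]["speed_deg_s"],
            level_up_threshold=d["level1"]["up_pct"],
            level_down_threshold=d["level1"]["down_pct"],
        )
        change = PerLevelChange(
            lifetime=d["change"]["lifetime_s"],
            speed=d["change"]["speed_deg_s"],
            level_up_threshold=d["change"]["up_pct"],
            level_down_threshold=d["change"]["down_pct"],
        )
        return cls(level1=level1, per_level_change=change, n_levels=d.get("n_levels", 15))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "DifficultyTable":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class RoundOutcome:
    """Number of targets found out of those presented in one round."""

    n_found: int
    n_targets: int

    def __post_init__(self) -> None:
        if self.n_targets <= 0:
            raise ValueError(f"n_targets must be > 0, got {self.n_targets}")
        if not 0 <= self.n_found <= self.n_targets:
            raise ValueError(
                f"n_found must be in [0, {self.n_targets}], got {self.n_found}"
            )


def default_table() -> DifficultyTable:
    """The standard 15-level table.

    Level 1 presents targets for 15 s moving at 2 °/s with promotion above
    70% found and demotion below 60%; each level shortens the lifetime by
    0.786 s, speeds targets up by 2.36 °/s and raises both thresholds by
    1.42 percentage points.
    """
    return DifficultyTable(
        level1=LevelParameters(
            level=1,
            lifetime=15.0,
            speed=2.0,
            level_up_threshold=70.0,
            level_down_threshold=60.0,
        ),
        per_level_change=PerLevelChange(
            lifetime=-0.786,
            speed=2.36,
            level_up_threshold=1.42,
            level_down_threshold=1.42,
        ),
        n_levels=15,
    )


def level_params(table: DifficultyTable, level: int) -> LevelParameters:
    """Resolve the parameters of ``level`` from the table.

    Each parameter equals its level-1 value plus (level - 1) times the
    per-level change.
    """
    if not 1 <= level <= table.n_levels:
        raise ValueError(
            f"level must be in [1, {table.n_levels}], got {level}"
        )
    k = level - 1
    c = table.per_level_change
    l1 = table.level1
    return LevelParameters(
        level=level,
        lifetime=l1.lifetime + k * c.lifetime,
        speed=l1.speed + k * c.speed,
        level_up_threshold=l1.level_up_threshold + k * c.level_up_threshold,
        level_down_threshold=l1.level_down_threshold + k * c.level_down_threshold,
    )


def percent_found(outcome: RoundOutcome) -> float:
    """Percentage of found targets in a round, unrounded."""
    return 100.0 * outcome.n_found / outcome.n_targets


def next_level(table: DifficultyTable, level: int, pct: float) -> int:
    """Level of the next round given the current level and percent found.

    Strictly above the level-up threshold promotes, strictly below the
    level-down threshold demotes, otherwise the level is held.  The result
    is clamped to [1, table.n_levels].
    """
    if not 1 <= level <= table.n_levels:
        raise ValueError(f"level must be in [1, {table.n_levels}], got {level}")
    if not 0 <= pct <= 100:
        raise ValueError(f"pct must be in [0, 100], got {pct}")
    params = level_params(table, level)
    if pct > params.level_up_threshold:
        nxt = level + 1
    elif pct < params.level_down_threshold:
        nxt = level - 1
    else:
        nxt = level
    return min(max(nxt, 1), table.n_levels)
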