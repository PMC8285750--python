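"""Event-based simulation of the visual-search task.

A session is a sequence of rounds; each round presents a fixed number of
targets one at a time.  A target spawns at a uniformly random position in a
rectangular angular spawn area (wider than the player's field of view), moves
horizontally at the level's speed and disappears after the level's maximum
lifetime if not tagged.  After each target resolves (tagged or expired) the
next one appears following a fixed inter-stimulus interval.  Between rounds
the difficulty level follows the adaptive switching rule of
:mod:`birdsearch.difficulty`.

Synthetic player agents replace human participants.  An agent's search time
for a target is modelled as

    t = (base_latency + |azimuth| / scan_speed + aim_time) * penalty * eps

where ``penalty = 1 + bias_gain * lateral_bias`` for targets in the left
hemispace (azimuth < 0) and 1 otherwise, and ``eps`` is lognormal
multiplicative noise with median 1.  The target is found iff ``t`` does not
exceed its lifetime.  ``lateral_bias`` (lambda in [0, 1]) emulates the
lateralized slowing of visual search seen in left hemispatial neglect;
healthy agents have ``lateral_bias = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .difficulty import (
    DifficultyTable,
    LevelParameters,
    RoundOutcome,
    default_table,
    level_params,
    next_level,
    percent_found,
)

WORKSPACE_HALFWIDTH_M = 1.0  # hand trace lives in a 2 m x 2 m workspace
ARM_RADIUS_M = 0.5
TRACE_HZ = 10.0


@dataclass(frozen=True)
class TaskConfig:
    """Geometry and round structure of the task.

    Defaults describe the standard protocol: a +/-60 deg x +/-50 deg spawn
    area (10 deg wider horizontally than the 110 deg field of view), 10
    rounds of 30 targets with a 2 s inter-stimulus interval.  The patient
    variant lowers the level-1 target speed to ``speed_floor_override``
    (0.1 deg/s) and typically shortens rounds via the overridable counts.
    """

    spawn_azimuth_halfwidth: float = 60.0
    spawn_elevation_halfwidth: float = 50.0
    fov_horizontal: float = 110.0
    targets_per_round: int = 30
    n_rounds: int = 10
    isi: float = 2.0
    starting_level: int = 1
    speed_floor_override: Optional[float] = None

    def __post_init__(self) -> None:
        if 2 * self.spawn_azimuth_halfwidth <= self.fov_horizontal:
            raise ValueError(
                "spawn area must exceed the horizontal field of view: "
                f"2*{self.spawn_azimuth_halfwidth} <= {self.fov_horizontal}"
            )
        for name in ("spawn_azimuth_halfwidth", "spawn_elevation_halfwidth",
                     "fov_horizontal", "isi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("targets_per_round", "n_rounds", "starting_level"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.speed_floor_override is not None and self.speed_floor_override <= 0:
            raise ValueError("speed_floor_override must be > 0")


@dataclass(frozen=True)
class AgentProfile:
    """A synthetic player.

    Parameters
    ----------
    base_latency : float
        Seconds from alerting cue to search onset (>= 0).
    scan_speed : float
        Angular search rate in degrees/second (> 0).
    aim_time : float
        Tagging latency after detection, seconds (>= 0).
    noise_sigma : float
        Log-sd of the lognormal multiplicative noise on search time
        (0 = deterministic).
    lateral_bias : float
        Lambda in [0, 1]; 0 = symmetric search, larger values slow search
        for left-hemispace targets (neglect-like behavior).
    bias_gain : float
        Multiplier scaling the left-space penalty: the left-hemispace
        search time is multiplied by ``1 + bias_gain * lateral_bias``.
    """

    base_latency: float = 0.4
    scan_speed: float = 40.0
    aim_time: float = 0.3
    noise_sigma: float = 0.25
    lateral_bias: float = 0.0
    bias_gain: float = 2.0

    def __post_init__(self) -> None:
        if self.scan_speed <= 0:
            raise ValueError("scan_speed must be > 0")
        for name in ("base_latency", "aim_time", "noise_sigma", "bias_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.lateral_bias <= 1:
            raise ValueError(f"lateral_bias must be in [0, 1], got {self.lateral_bias}")


@dataclass
class TargetEvent:
    """One target presentation: spawn geometry, motion and outcome."""

    round_index: int
    level: int
    spawn_time: float
    azimuth: float
    elevation: float
    direction: int  # -1 leftward, +1 rightward
    speed: float
    lifetime: float
    found: Optional[bool] = None
    search_time: Optional[float] = None

    @property
    def hemispace(self) -> str:
        # azimuth exactly 0 counts as right (probability zero under
        # continuous sampling; fixed for reproducibility)
        return "left" if self.azimuth < 0 else "right"

    @property
    def resolution_time(self) -> float:
        if self.found is None:
            raise ValueError("target not yet resolved")
        dt = self.search_time if self.found else self.lifetime
        return self.spawn_time + dt


@dataclass
class RoundRecord:
    level: int
    events: list[TargetEvent]

    @property
    def outcome(self) -> RoundOutcome:
        return RoundOutcome(
            n_found=sum(1 for e in self.events if e.found),
            n_targets=len(self.events),
        )


@dataclass
class HandTrace:
    """Timestamped planar hand positions within the 2 m x 2 m workspace."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class SessionRecord:
    participant_id: str
    cohort: str
    agent: AgentProfile
    config: TaskConfig
    rounds: list[RoundRecord]
    hand_trace: Optional[HandTrace] = None
    seed: Optional[int] = None
    metadata: dict = field(default_factory=dict)

    @property
    def level_trajectory(self) -> list[int]:
        return [r.level for r in self.rounds]

    def iter_events(self):
        for r in self.rounds:
            yield from r.events


def _effective_speed(config: TaskConfig, table: DifficultyTable,
                     params: LevelParameters) -> float:
    """Apply the patient speed floor: the override replaces the level-1
    speed, with the same per-level increment thereafter."""
    if config.speed_floor_override is None:
        return params.speed
    return (config.speed_floor_override
            + (params.level - 1) * table.per_level_change.speed)


def spawn_target(rng: np.random.Generator, config: TaskConfig,
                 params: LevelParameters, time: float,
                 round_index: int = 0,
                 table: Optional[DifficultyTable] = None) -> TargetEvent:
    """Draw an unresolved target uniformly from the spawn area."""
    az = rng.uniform(-config.spawn_azimuth_halfwidth, config.spawn_azimuth_halfwidth)
    el = rng.uniform(-config.spawn_elevation_halfwidth, config.spawn_elevation_halfwidth)
    direction = 1 if rng.random() < 0.5 else -1
    speed = params.speed if table is None else _effective_speed(config, table, params)
    return TargetEvent(
        round_index=round_index,
        level=params.level,
        spawn_time=time,
        azimuth=az,
        elevation=el,
        direction=direction,
        speed=speed,
        lifetime=params.lifetime,
    )


def simulate_target_trial(agent: AgentProfile, target: TargetEvent,
                          rng: np.random.Generator) -> TargetEvent:
    """Resolve a target against an agent's search model."""
    if target.found is not None:
        raise ValueError("target already resolved")
    base = agent.base_latency + abs(target.azimuth) / agent.scan_speed + agent.aim_time
    if target.hemispace == "left":
        base *= 1.0 + agent.bias_gain * agent.lateral_bias
    if agent.noise_sigma > 0:
        base *= math.exp(agent.noise_sigma * rng.standard_normal())
    found = base <= target.lifetime
    target.found = found
    target.search_time = base if found else None
    return target


def run_round(agent: AgentProfile, config: TaskConfig, table: DifficultyTable,
              level: int, rng: np.random.Generator, round_index: int = 0,
              start_time: float = 0.0,
              n_targets: Optional[int] = None) -> RoundRecord:
    """Simulate one round of sequential target presentations."""
    params = level_params(table, level)
    n = config.targets_per_round if n_targets is None else n_targets
    events: list[TargetEvent] = []
    t = start_time
    for _ in range(n):
        ev = spawn_target(rng, config, params, t, round_index=round_index, table=table)
        simulate_target_trial(agent, ev, rng)
        events.append(ev)
        t = ev.resolution_time + config.isi
    return RoundRecord(level=level, events=events)


def run_session(agent: AgentProfile, config: TaskConfig,
                table: Optional[DifficultyTable] = None,
                rng: Optional[np.random.Generator] = None,
                participant_id: str = "sim", cohort: str = "synthetic",
                seed: Optional[int] = None,
                total_targets: Optional[int] = None,
                with_hand_trace: bool = True,
                metadata: Optional[dict] = None) -> SessionRecord:
    """Simulate a full session with adaptive between-round difficulty.

    ``total_targets``, when given, caps the number of presented targets
    (the patient variant configures the total independently of the round
    size); the final round may then be shorter.
    """
    table = table if table is not None else default_table()
    if rng is None:
        rng = np.random.default_rng(seed)
    level = config.starting_level
    if not 1 <= level <= table.n_levels:
        raise ValueError(f"starting_level must be in [1, {table.n_levels}]")
    rounds: list[RoundRecord] = []
    t = 0.0
    presented = 0
    for r in range(config.n_rounds):
        n = config.targets_per_round
        if total_targets is not None:
            n = min(n, total_targets - presented)
            if n <= 0:
                break
        rec = run_round(agent, config, table, level, rng,
                        round_index=r, start_time=t, n_targets=n)
        rounds.append(rec)
        presented += n
        t = rec.events[-1].resolution_time + config.isi
        level = next_level(table, level, percent_found(rec.outcome))
    session = SessionRecord(
        participant_id=participant_id, cohort=cohort, agent=agent,
        config=config, rounds=rounds, seed=seed,
        metadata=dict(metadata or {}),
    )
    if with_hand_trace:
        session.hand_trace = generate_hand_trace(session, rng)
    return session


def generate_hand_trace(session: SessionRecord,
                        rng: np.random.Generator,
                        jitter_sigma: float = 0.01) -> HandTrace:
    """Synthesize a controller x-y trace for a resolved session.

    For each found target the hand moves from its current position toward
    the reach point at arm radius in the target's azimuth direction (x
    lateral, y forward), sampled at 10 Hz with Gaussian jitter.  Left-side
    reach points are attenuated toward the midline by ``1 - lateral_bias``,
    emulating the restricted contralesional exploration of neglect.
    Unresolved targets produce drift around the current position.
    """
    lam = session.agent.lateral_bias
    ts: list[float] = []
    xs: list[float] = []
    ys: list[float] = []
    cx, cy = 0.0, ARM_RADIUS_M  # rest position in front of the player
    for ev in session.iter_events():
        duration = (ev.search_time if ev.found else ev.lifetime)
        n_samp = max(2, int(round(duration * TRACE_HZ)))
        if ev.found:
            az = math.radians(ev.azimuth)
            tx = ARM_RADIUS_M * math.sin(az)
            ty = ARM_RADIUS_M * math.cos(az)
            if tx < 0:
                tx *= (1.0 - lam)
        else:
            tx, ty = cx, cy  # no reach: drift in place
        frac = np.linspace(0.0, 1.0, n_samp)
        x = cx + (tx - cx) * frac + rng.normal(0.0, jitter_sigma, n_samp)
        y = cy + (ty - cy) * frac + rng.normal(0.0, jitter_sigma, n_samp)
        t = ev.spawn_time + frac * duration
        ts.append(t)
        xs.append(x)
        ys.append(y)
        cx, cy = tx, ty
    if not ts:
        empty = np.empty(0)
        return HandTrace(t=empty, x=empty.copy(), y=empty.copy())
    w = WORKSPACE_HALFWIDTH_M
    return HandTrace(
        t=np.concatenate(ts),
        x=np.clip(np.concatenate(xs), -w, w),
        y=np.clip(np.concatenate(ys), -w, w),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Description of a synthetic cohort.

    ``agent`` gives the shared agent parameters; ``lateral_bias_range``,
    when set, draws each participant's lambda uniformly from that interval
    (neglect cohorts) and records it in the session metadata together with
    the group label.
    """

    label: str
    n: int
    agent: AgentProfile = AgentProfile()
    config: TaskConfig = TaskConfig()
    lateral_bias_range: Optional[tuple[float, float]] = None
    total_targets: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"cohort n must be >= 1, got {self.n}")
        if self.lateral_bias_range is not None:
            lo, hi = self.lateral_bias_range
            if not (0 <= lo <= hi <= 1):
                raise ValueError(
                    f"lateral_bias_range must satisfy 0 <= lo <= hi <= 1, got ({lo}, {hi})"
                )


def young_cohort(n: int = 21) -> CohortSpec:
    """Healthy young adults: fast scanning, start at level 8."""
    return CohortSpec(
        label="young", n=n,
        agent=AgentProfile(base_latency=0.4, scan_speed=40.0, aim_time=0.3,
                           noise_sigma=0.25, lateral_bias=0.0),
        config=TaskConfig(starting_level=8),
    )


def elderly_cohort(n: int = 23) -> CohortSpec:
    """Healthy elderly: slower scan speed and noisier search."""
    return CohortSpec(
        label="elderly", n=n,
        agent=AgentProfile(base_latency=0.5, scan_speed=28.0, aim_time=0.35,
                           noise_sigma=0.45, lateral_bias=0.0),
        config=TaskConfig(starting_level=8),
    )


def neglect_cohort(n: int = 11,
                   lateral_bias_range: tuple[float, float] = (0.1, 0.9)) -> CohortSpec:
    """Left-neglect patients: lateralized slowing, gentle start, 0.1 deg/s
    level-1 speed floor."""
    return CohortSpec(
        label="neglect", n=n,
        agent=AgentProfile(base_latency=0.6, scan_speed=25.0, aim_time=0.4,
                           noise_sigma=0.35, lateral_bias=0.5, bias_gain=2.0),
        config=TaskConfig(starting_level=2, speed_floor_override=0.1),
        lateral_bias_range=lateral_bias_range,
    )


def generate_cohort(spec: CohortSpec, rng: np.random.Generator,
                    table: Optional[DifficultyTable] = None) -> list[SessionRecord]:
    """Simulate ``spec.n`` independent sessions from per-participant
    substreams of ``rng``."""
    table = table if table is not None else default_table()
    sessions = []
    for i in range(spec.n):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub_rng = np.random.default_rng(sub_seed)
        agent = spec.agent
        meta: dict = {"cohort": spec.label}
        if spec.lateral_bias_range is not None:
            lo, hi = spec.lateral_bias_range
            lam = float(sub_rng.uniform(lo, hi))
            agent = replace(agent, lateral_bias=lam)
            meta["lateral_bias"] = lam
        sessions.append(run_session(
            agent, spec.config, table, sub_rng,
            participant_id=f"{spec.label}_{i:02d}", cohort=spec.label,
            seed=sub_seed, total_targets=spec.total_targets, metadata=meta,
        ))
    return sessions
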