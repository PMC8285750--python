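"""Task simulation: spawn geometry, the agent response model, rounds,
sessions and cohorts."""

import numpy as np
import pytest

from birdsearch.difficulty import default_table, level_params, next_level, percent_found
from birdsearch.simulator import (
    AgentProfile,
    CohortSpec,
    TaskConfig,
    generate_cohort,
    generate_hand_trace,
    neglect_cohort,
    run_round,
    run_session,
    simulate_target_trial,
    spawn_target,
    SessionRecord,
)

FAST = AgentProfile(base_latency=0.2, scan_speed=100.0, aim_time=0.1, noise_sigma=0.0)
BLIND = AgentProfile(base_latency=20.0, scan_speed=50.0, aim_time=0.0, noise_sigma=0.0)


def _unresolved(azimuth, lifetime=15.0, level=1):
    from birdsearch.simulator import TargetEvent
    return TargetEvent(round_index=0, level=level, spawn_time=0.0,
                       azimuth=azimuth, elevation=0.0, direction=1,
                       speed=2.0, lifetime=lifetime)


class TestSpawn:
    def test_support_and_direction_balance(self, table):
        rng = np.random.default_rng(0)
        cfg = TaskConfig()
        params = level_params(table, 1)
        az, el, dirs = [], [], []
        for _ in range(10_000):
            ev = spawn_target(rng, cfg, params, 0.0)
            az.append(ev.azimuth); el.append(ev.elevation); dirs.append(ev.direction)
        assert -60 <= min(az) and max(az) <= 60
        assert -50 <= min(el) and max(el) <= 50
        assert abs(np.mean(np.array(dirs) == 1) - 0.5) < 0.02
        assert ev.speed == params.speed and ev.lifetime == params.lifetime

    def test_seeded_determinism(self, table):
        cfg = TaskConfig()
        params = level_params(table, 3)
        draws = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            draws.append([(e.azimuth, e.elevation, e.direction)
                          for e in (spawn_target(rng, cfg, params, 0.0)
                                    for _ in range(50))])
        assert draws[0] == draws[1]

    def test_patient_speed_floor_applies_at_level1(self, table):
        cfg = TaskConfig(speed_floor_override=0.1)
        rng = np.random.default_rng(0)
        ev1 = spawn_target(rng, cfg, level_params(table, 1), 0.0, table=table)
        assert ev1.speed == pytest.approx(0.1)
        ev6 = spawn_target(rng, cfg, level_params(table, 6), 0.0, table=table)
        assert ev6.speed == pytest.approx(0.1 + 5 * 2.36)


class TestTrialModel:
    def test_closed_form_no_noise(self):
        agent = AgentProfile(base_latency=0.4, scan_speed=30.0, aim_time=0.1,
                             noise_sigma=0.0, lateral_bias=0.0)
        ev = simulate_target_trial(agent, _unresolved(30.0), np.random.default_rng(0))
        assert ev.found and ev.search_time == pytest.approx(1.5)

    def test_symmetry_at_zero_bias(self):
        agent = AgentProfile(base_latency=0.4, scan_speed=30.0, aim_time=0.1,
                             noise_sigma=0.0, lateral_bias=0.0)
        ev = simulate_target_trial(agent, _unresolved(-30.0), np.random.default_rng(0))
        assert ev.search_time == pytest.approx(1.5)

    def test_left_penalty_factor(self):
        agent = AgentProfile(base_latency=0.4, scan_speed=30.0, aim_time=0.1,
                             noise_sigma=0.0, lateral_bias=0.5, bias_gain=2.0)
        left = simulate_target_trial(agent, _unresolved(-30.0), np.random.default_rng(0))
        assert left.search_time == pytest.approx(3.0)
        right = simulate_target_trial(agent, _unresolved(30.0), np.random.default_rng(0))
        assert right.search_time == pytest.approx(1.5)

    def test_not_found_when_over_lifetime(self):
        ev = simulate_target_trial(BLIND, _unresolved(10.0, lifetime=15.0),
                                   np.random.default_rng(0))
        assert not ev.found and ev.search_time is None

    def test_monotone_impairment_in_lambda(self):
        lams = [0.0, 0.25, 0.5, 0.75, 1.0]
        lefts, rights = [], []
        for lam in lams:
            agent = AgentProfile(base_latency=0.4, scan_speed=30.0, aim_time=0.1,
                                 noise_sigma=0.0, lateral_bias=lam, bias_gain=2.0)
            l = simulate_target_trial(agent, _unresolved(-30.0, lifetime=1e9),
                                      np.random.default_rng(0)).search_time
            r = simulate_target_trial(agent, _unresolved(30.0, lifetime=1e9),
                                      np.random.default_rng(0)).search_time
            lefts.append(l); rights.append(r)
        assert all(b > a for a, b in zip(lefts, lefts[1:]))
        assert all(r == rights[0] for r in rights)


class TestRoundsAndSessions:
    def test_round_has_configured_target_count(self, table):
        rec = run_round(FAST, TaskConfig(), table, 1, np.random.default_rng(0))
        assert len(rec.events) == 30
        assert rec.outcome.n_found + sum(not e.found for e in rec.events) == 30

    def test_fast_agent_finds_all_at_level1(self, table):
        # deterministic max search time 0.2 + 60/100 + 0.1 = 0.9 s < 15 s
        rec = run_round(FAST, TaskConfig(), table, 1, np.random.default_rng(1))
        assert rec.outcome.n_found == 30

    def test_blind_agent_finds_none(self, table):
        rec = run_round(BLIND, TaskConfig(), table, 1, np.random.default_rng(1))
        assert rec.outcome.n_found == 0

    def test_isi_separates_consecutive_targets(self, table):
        rec = run_round(FAST, TaskConfig(), table, 1, np.random.default_rng(2))
        for prev, nxt in zip(rec.events, rec.events[1:]):
            assert nxt.spawn_time == pytest.approx(prev.resolution_time + 2.0)

    def test_always_promoting_trajectory_with_ceiling(self, table):
        s = run_session(FAST, TaskConfig(starting_level=8), table,
                        np.random.default_rng(0), with_hand_trace=False)
        assert s.level_trajectory == [8, 9, 10, 11, 12, 13, 14, 15, 15, 15]

    def test_always_demoting_trajectory_with_floor(self, table):
        s = run_session(BLIND, TaskConfig(starting_level=3), table,
                        np.random.default_rng(0), with_hand_trace=False)
        assert s.level_trajectory == [3, 2, 1, 1, 1, 1, 1, 1, 1, 1]

    def test_trajectory_consistent_with_switching_rule(self, table):
        agent = AgentProfile(noise_sigma=0.5)
        s = run_session(agent, TaskConfig(starting_level=5), table,
                        np.random.default_rng(3), with_hand_trace=False)
        for r, nxt in zip(s.rounds, s.level_trajectory[1:]):
            assert nxt == next_level(table, r.level, percent_found(r.outcome))

    def test_total_targets_cap_shortens_session(self, table):
        s = run_session(FAST, TaskConfig(starting_level=1), table,
                        np.random.default_rng(0), total_targets=44,
                        with_hand_trace=False)
        assert sum(len(r.events) for r in s.rounds) == 44
        assert len(s.rounds[-1].events) == 14

    def test_zero_bias_hemispace_symmetry(self, table):
        # >= 2000 targets; left/right mean search times within 3 SE
        agent = AgentProfile(noise_sigma=0.25)
        left, right = [], []
        for i in range(7):
            s = run_session(agent, TaskConfig(starting_level=3), table,
                            seed=100 + i, with_hand_trace=False)
            for ev in s.iter_events():
                if ev.found:
                    (left if ev.hemispace == "left" else right).append(ev.search_time)
        assert len(left) + len(right) >= 2000
        se = np.hypot(np.std(left) / np.sqrt(len(left)),
                      np.std(right) / np.sqrt(len(right)))
        assert abs(np.mean(left) - np.mean(right)) < 3 * se


class TestHandTrace:
    def test_symmetric_agent_centered_trace(self, table):
        s = run_session(AgentProfile(noise_sigma=0.0), TaskConfig(starting_level=1),
                        table, np.random.default_rng(5))
        assert abs(np.mean(s.hand_trace.x)) < 0.05

    def test_neglect_agent_rightward_shift(self, table):
        agent = AgentProfile(noise_sigma=0.0, lateral_bias=0.9, bias_gain=2.0)
        s = run_session(agent, TaskConfig(starting_level=1), table,
                        np.random.default_rng(5))
        assert np.mean(s.hand_trace.x) > 0

    def test_trace_within_workspace(self, table):
        s = run_session(AgentProfile(), TaskConfig(starting_level=8), table,
                        np.random.default_rng(6))
        assert np.all(np.abs(s.hand_trace.x) <= 1.0)
        assert np.all(np.abs(s.hand_trace.y) <= 1.0)

    def test_empty_session_empty_trace(self, table):
        s = SessionRecord(participant_id="e", cohort="test",
                          agent=AgentProfile(), config=TaskConfig(), rounds=[])
        trace = generate_hand_trace(s, np.random.default_rng(0))
        assert len(trace) == 0


class TestCohorts:
    def test_cohort_size(self):
        spec = CohortSpec(label="x", n=21)
        sessions = generate_cohort(spec, np.random.default_rng(0))
        assert len(sessions) == 21

    def test_same_master_seed_identical(self):
        spec = neglect_cohort(n=4)
        def run():
            return generate_cohort(spec, np.random.default_rng(9))
        a, b = run(), run()
        for sa, sb in zip(a, b):
            assert sa.level_trajectory == sb.level_trajectory
            assert sa.metadata == sb.metadata
            ea = [(e.azimuth, e.found, e.search_time) for e in sa.iter_events()]
            eb = [(e.azimuth, e.found, e.search_time) for e in sb.iter_events()]
            assert ea == eb

    def test_lambda_drawn_within_configured_range(self):
        spec = neglect_cohort(n=8, lateral_bias_range=(0.1, 0.9))
        sessions = generate_cohort(spec, np.random.default_rng(1))
        for s in sessions:
            assert 0.1 <= s.metadata["lateral_bias"] <= 0.9
            assert s.agent.lateral_bias == s.metadata["lateral_bias"]

    def test_invalid_cohort_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(label="x", n=0)
        with pytest.raises(ValueError):
            CohortSpec(label="x", n=3, lateral_bias_range=(0.5, 1.5))


class TestConfigValidation:
    def test_spawn_must_exceed_fov(self):
        with pytest.raises(ValueError, match="field of view"):
            TaskConfig(spawn_azimuth_halfwidth=50.0, fov_horizontal=110.0)

    def test_counts_positive(self):
        with pytest.raises(ValueError):
            TaskConfig(targets_per_round=0)
        with pytest.raises(ValueError):
            AgentProfile(lateral_bias=1.5)
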