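"""Agent-environment simulation, episode detection, and behavioral metrics."""

import numpy as np
import pytest
from scipy import stats as sps

from compulsim import (
    Action,
    SimConfig,
    build_tables,
    classify_compulsion_type,
    compute_metrics,
    detect_episodes,
    run_sequence,
    run_sequences,
    solve,
)
from compulsim.model import belief_update
from compulsim.simulate import EpisodeTrace, _episode_scan

from .conftest import random_params

COOK, WASH, CHECK = int(Action.COOK), int(Action.WASH), int(Action.CHECK)


def episodes_oracle(actions):
    """Naive run-splitting reference for episode detection."""
    episodes = []
    run = []
    start = 0
    for i, a in enumerate(list(actions) + [COOK]):
        if a == COOK:
            if run.count(WASH) >= 2 or run.count(CHECK) >= 2:
                ww = sum(
                    1 for x, y in zip(run, run[1:]) if x == y == WASH
                )
                cc = sum(
                    1 for x, y in zip(run, run[1:]) if x == y == CHECK
                )
                episodes.append(
                    (start, start + len(run) - 1, len(run),
                     run.count(WASH), run.count(CHECK), ww, cc)
                )
            run = []
            start = i + 1
        else:
            run.append(a)
    return episodes


class TestDetectEpisodes:
    def test_check_wash_check_is_one_episode(self):
        eps = detect_episodes([COOK, CHECK, WASH, CHECK, COOK])
        assert len(eps) == 1
        assert eps[0].duration == 3
        assert eps[0].n_check == 2
        assert eps[0].n_wash == 1

    def test_single_wash_and_check_is_not_an_episode(self):
        assert detect_episodes([COOK, WASH, CHECK, COOK]) == []

    def test_all_cook_has_no_episodes(self):
        assert detect_episodes([COOK, COOK, COOK]) == []

    def test_double_wash_and_double_check_runs(self):
        assert len(detect_episodes([COOK, WASH, WASH, COOK])) == 1
        assert len(detect_episodes([COOK, CHECK, CHECK, COOK])) == 1

    def test_boundary_truncated_runs_still_qualify(self):
        eps = detect_episodes([WASH, WASH, COOK])
        assert len(eps) == 1 and eps[0].start == 0
        eps = detect_episodes([COOK, CHECK, CHECK])
        assert len(eps) == 1 and eps[0].end == 2

    def test_matches_bruteforce_oracle_on_random_sequences(self, rng):
        for _ in range(10_000):
            actions = rng.integers(0, 3, size=rng.integers(1, 30))
            got = [
                (e.start, e.end, e.duration, e.n_wash, e.n_check,
                 e.n_wash_repeats, e.n_check_repeats)
                for e in detect_episodes(actions)
            ]
            assert got == episodes_oracle(actions)

    def test_fast_scan_agrees_with_detector(self, rng):
        for _ in range(200):
            actions = rng.integers(0, 3, size=(rng.integers(1, 8), 50))
            n_ep, uc, uw, uk = _episode_scan(actions.astype(np.int8))
            want = sum(len(detect_episodes(row)) for row in actions)
            assert n_ep == want
            assert (uc, uw, uk) == tuple(
                int((actions == a).any()) for a in range(3)
            )


class TestClassifyCompulsionType:
    @staticmethod
    def from_actions(*seqs):
        eps = []
        for seq in seqs:
            eps.extend(detect_episodes(list(seq) + [COOK]))
        return eps

    def test_no_episodes_is_none(self):
        assert classify_compulsion_type([]) == "none"

    def test_pure_wash_and_pure_check(self):
        eps = self.from_actions([WASH, WASH])
        assert classify_compulsion_type(eps) == "pure_wash"
        eps = self.from_actions([CHECK, CHECK, CHECK])
        assert classify_compulsion_type(eps) == "pure_check"

    def test_mixed_across_episodes(self):
        eps = self.from_actions([WASH, WASH], [CHECK, CHECK])
        assert classify_compulsion_type(eps) == "mixed"

    def test_interleaved_repetition_is_mixed(self):
        # check,wash,check: checking repeats but never back-to-back — the
        # agent alternates the two behaviors, so the type is mixed
        eps = self.from_actions([CHECK, WASH, CHECK])
        assert len(eps) == 1
        assert classify_compulsion_type(eps) == "mixed"

    def test_single_stray_check_does_not_break_wash_purity(self):
        # a lone check inside an otherwise wash-repeating episode leaves
        # the re-executed behavior purely washing
        eps = self.from_actions([CHECK, WASH, WASH, WASH])
        assert classify_compulsion_type(eps) == "pure_wash"


def make_trace(actions, beliefs=None):
    actions = np.asarray(actions, dtype=np.int8)
    n = len(actions)
    if beliefs is None:
        beliefs = np.zeros(n + 1)
    return EpisodeTrace(
        actions=actions,
        states=np.zeros(n, dtype=np.int8),
        observations=np.zeros(n, dtype=np.int8),
        beliefs=np.asarray(beliefs, dtype=float),
        rewards=np.zeros(n),
        final_state=0,
    )


class TestComputeMetrics:
    def test_hand_counted_episode_percentages(self):
        m = compute_metrics([make_trace([COOK, WASH, WASH, COOK, COOK])])
        assert m.is_compulsive
        assert m.n_episodes_mean == 1.0
        assert m.episode_duration_mean == 2.0
        assert m.pct_actions_compulsive == pytest.approx(40.0)
        assert m.compulsion_type == "pure_wash"

    def test_all_cook_metrics(self):
        m = compute_metrics([make_trace([COOK] * 10)] * 3)
        assert not m.is_compulsive
        assert m.pct_actions_compulsive == 0.0
        assert m.transition_matrix[COOK, COOK] == 1.0
        assert np.isnan(m.transition_matrix[WASH]).all()  # wash never used
        assert np.isnan(m.belief_update_after_wash)  # undefined, not zero
        assert m.compulsion_type == "none"

    def test_wash_belief_update_amplitude(self):
        # belief 0.6 before each wash, dropping to 0 (p'_success = 1)
        tr = make_trace(
            [COOK, WASH, COOK, WASH], beliefs=[0.0, 0.6, 0.0, 0.6, 0.0]
        )
        m = compute_metrics([tr])
        assert m.belief_update_after_wash == pytest.approx(0.6)

    def test_belief_at_action_is_clean_probability(self):
        tr = make_trace([COOK, WASH], beliefs=[0.2, 0.8, 0.1])
        m = compute_metrics([tr])
        assert m.belief_at_action[COOK] == pytest.approx(0.8)
        assert m.belief_at_action[WASH] == pytest.approx(0.2)
        assert np.isnan(m.belief_at_action[CHECK])

    def test_transition_rows_sum_to_one_where_defined(self, rng):
        traces = [make_trace(rng.integers(0, 3, size=50)) for _ in range(5)]
        m = compute_metrics(traces)
        sums = m.transition_matrix.sum(axis=1)
        for a in range(3):
            if not np.isnan(sums[a]):
                assert sums[a] == pytest.approx(1.0)

    def test_compulsive_iff_nonzero_compulsive_percentage(self, rng):
        for _ in range(50):
            m = compute_metrics([make_trace(rng.integers(0, 3, size=30))])
            assert m.is_compulsive == (m.pct_actions_compulsive > 0)


class TestRunSequence:
    def test_absorbing_clean_world_is_all_cook(self, default_params):
        # soiling impossible: a veridical agent cooks forever at reward 0
        p = default_params.with_(p_soiling=0.0)
        policy = solve(p)
        t = build_tables(p)
        cfg = SimConfig(n_sequences=1, n_actions=200)
        rng = np.random.default_rng(3)
        trace = run_sequence(policy, t, t, cfg, rng)
        after_burnin = trace.actions[50:]  # a dirty random start may wash
        assert np.all(after_burnin == COOK)
        assert np.all(trace.rewards[50:] == 0.0)

    def test_certain_cleaner_believes_clean_after_wash(self, default_params):
        agent = default_params.with_(p_success=1.0)
        policy = solve(agent)
        at, wt = build_tables(agent), build_tables(default_params)
        cfg = SimConfig(n_sequences=1, n_actions=300)
        trace = run_sequence(policy, at, wt, cfg, np.random.default_rng(5))
        wash_idx = np.flatnonzero(trace.actions == WASH)
        assert len(wash_idx) > 0
        assert np.all(trace.beliefs[wash_idx + 1] == 0.0)

    def test_beliefs_replay_through_belief_update(self, rng):
        for _ in range(5):
            world = random_params(rng)
            agent = random_params(rng)
            policy = solve(agent)
            at, wt = build_tables(agent), build_tables(world)
            cfg = SimConfig(n_sequences=2, n_actions=100)
            for trace in run_sequences(
                policy, at, wt, cfg,
                [np.random.default_rng(i) for i in range(2)],
            ):
                b = trace.beliefs[0]
                for t in range(len(trace)):
                    b = belief_update(
                        b, int(trace.actions[t]), int(trace.observations[t]), at
                    )
                    assert b == pytest.approx(trace.beliefs[t + 1], abs=1e-12)

    def test_state_transitions_match_world_frequencies(self, default_params):
        # chi-square on empirical cook-soiling over many replicate steps
        world = default_params.with_(p_soiling=0.35, p_success=0.9)
        agent = world
        policy = solve(agent)
        t = build_tables(world)
        cfg = SimConfig(n_sequences=40, n_actions=250)
        traces = run_sequences(
            policy, t, t, cfg, [np.random.default_rng(i) for i in range(40)]
        )
        soiled = stayed = 0
        for tr in traces:
            cook_clean = (tr.actions == COOK) & (tr.states == 0)
            idx = np.flatnonzero(cook_clean[:-1])
            nxt = tr.states[idx + 1]
            soiled += int((nxt == 1).sum())
            stayed += int((nxt == 0).sum())
        n = soiled + stayed
        assert n > 2000
        chi = sps.chisquare(
            [soiled, stayed], [n * 0.35, n * 0.65]
        )
        assert chi.pvalue > 0.01

    def test_same_rng_seed_reproduces_sequence(self, default_params):
        policy = solve(default_params)
        t = build_tables(default_params)
        cfg = SimConfig(n_sequences=1, n_actions=100)
        tr1 = run_sequence(policy, t, t, cfg, np.random.default_rng(11))
        tr2 = run_sequence(policy, t, t, cfg, np.random.default_rng(11))
        assert np.array_equal(tr1.actions, tr2.actions)
        assert np.array_equal(tr1.beliefs, tr2.beliefs)

    def test_batch_column_equals_single_run(self, default_params):
        policy = solve(default_params)
        t = build_tables(default_params)
        cfg = SimConfig(n_sequences=3, n_actions=50)
        batch = run_sequences(
            policy, t, t, cfg, [np.random.default_rng(i) for i in range(3)]
        )
        single = run_sequence(policy, t, t, cfg, np.random.default_rng(1))
        assert np.array_equal(batch[1].actions, single.actions)
        assert np.array_equal(batch[1].beliefs, single.beliefs)
        assert np.array_equal(batch[1].states, single.states)
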