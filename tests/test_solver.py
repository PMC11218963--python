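"""Value-iteration solver versus brute-force oracles.

The solver is validated against three independent references:
a depth-1 expectimax for single backups, a finite-horizon dynamic program
on a dense belief grid for full solves, and Monte-Carlo evaluation of
fixed-action policies for the optimality lower bound.
"""

import numpy as np
import pytest

from compulsim import (
    Action,
    AlphaVector,
    ModelTables,
    bellman_backup,
    build_tables,
    policy_action,
    policy_value,
    prune_envelope,
    solve,
    solve_tables,
)
from compulsim.solver import action_value_gaps

from .conftest import random_params

GRID = np.linspace(0.0, 1.0, 101)


def envelope_at(alphas, b):
    return max(a.value(b) for a in alphas)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def expectimax_depth1(b, tables: ModelTables, gamma, value_fn):
    """One-step lookahead: max_a E[r] + γ Σ_o P(o|b,a) V(b')."""
    best = -np.inf
    prior = np.array([1.0 - b, b])
    for a in range(3):
        pred = prior @ tables.transition[a]
        q = prior @ tables.reward[a]
        for o in range(2):
            p_o = float(pred @ tables.observation[a, :, o])
            if p_o <= 0.0:
                continue
            post = tables.observation[a, :, o] * pred
            b_next = float(post[1] / post.sum())
            q += gamma * p_o * value_fn(b_next)
        best = max(best, q)
    return best


def grid_dp(tables: ModelTables, gamma, horizon=200, grid_size=2001):
    """Finite-horizon DP on a dense belief grid (linear interpolation)."""
    grid = np.linspace(0.0, 1.0, grid_size)
    prior = np.stack([1.0 - grid, grid], axis=1)  # (G, 2)
    v = np.zeros(grid_size)
    # precompute per-action successor beliefs and observation masses
    succ, masses, rewards = [], [], []
    for a in range(3):
        pred = prior @ tables.transition[a]  # (G, 2)
        rewards.append(prior @ tables.reward[a])
        m_a, s_a = [], []
        for o in range(2):
            post = pred * tables.observation[a, :, o]
            z = post.sum(axis=1)
            m_a.append(z)
            with np.errstate(invalid="ignore", divide="ignore"):
                b_next = np.where(z > 0, post[:, 1] / np.where(z > 0, z, 1), 0.0)
            s_a.append(b_next)
        masses.append(m_a)
        succ.append(s_a)
    for _ in range(horizon):
        q = np.full((3, grid_size), -np.inf)
        for a in range(3):
            cont = np.zeros(grid_size)
            for o in range(2):
                cont += masses[a][o] * np.interp(succ[a][o], grid, v)
            q[a] = rewards[a] + gamma * cont
        v = q.max(axis=0)
    return grid, v


def mc_fixed_action_value(b0, action, tables: ModelTables, gamma, rng,
                          n_rollouts=400):
    """Monte-Carlo discounted return of always playing one action,
    evaluated under the agent's own model (subjective value)."""
    horizon = max(int(np.log(1e-4) / np.log(gamma)), 10) if gamma > 0 else 1
    total = np.zeros(n_rollouts)
    for k in range(n_rollouts):
        s = int(rng.random() < b0)
        disc = 1.0
        for _ in range(horizon):
            total[k] += disc * tables.reward[action, s]
            s = int(rng.random() < tables.transition[action, s, 1])
            disc *= gamma
            if disc < 1e-6:
                break
    return total.mean(), total.std(ddof=1) / np.sqrt(n_rollouts)


# ---------------------------------------------------------------------------
# prune_envelope
# ---------------------------------------------------------------------------


class TestPruneEnvelope:
    def test_pointwise_dominance_removed(self):
        a_hi = AlphaVector(1.0, 1.0, Action.COOK)
        a_lo = AlphaVector(0.0, 0.0, Action.WASH)
        assert prune_envelope([a_hi, a_lo]) == [a_hi]

    def test_crossing_lines_both_kept(self):
        a = AlphaVector(1.0, 0.0, Action.COOK)
        b = AlphaVector(0.0, 1.0, Action.WASH)
        kept = prune_envelope([a, b])
        assert set(kept) == {a, b}

    def test_thousand_random_lines_match_dense_grid_max(self, rng):
        vals = rng.normal(size=(1000, 2))
        alphas = [
            AlphaVector(v[0], v[1], Action(int(i % 3)))
            for i, v in enumerate(vals)
        ]
        pruned = prune_envelope(alphas)
        assert len(pruned) < len(alphas)
        grid = np.linspace(0, 1, 10001)
        full = np.max(
            np.outer(1 - grid, vals[:, 0]) + np.outer(grid, vals[:, 1]), axis=1
        )
        pv = np.array([[a.v_clean, a.v_dirty] for a in pruned])
        kept = np.max(np.outer(1 - grid, pv[:, 0]) + np.outer(grid, pv[:, 1]), axis=1)
        np.testing.assert_allclose(kept, full, atol=1e-10)


# ---------------------------------------------------------------------------
# bellman_backup
# ---------------------------------------------------------------------------


class TestBellmanBackup:
    def test_gamma_zero_returns_immediate_rewards(self, default_params):
        t = build_tables(default_params)
        alphas = [AlphaVector(-5.0, 3.0, Action.COOK)]  # arbitrary input
        out = bellman_backup(alphas, t, gamma=0.0)
        got = {(a.v_clean, a.v_dirty) for a in out}
        expected = {tuple(t.reward[a]) for a in range(3)}
        assert got == expected

    def test_zero_continuation_check_alpha(self, default_params):
        t = build_tables(default_params.with_(
            cost_check=-0.1, cost_wash=-0.2, cost_sickness=-0.7
        ))
        out = bellman_backup([AlphaVector(0.0, 0.0, Action.COOK)], t, gamma=0.9)
        checks = [a for a in out if a.action == Action.CHECK]
        assert len(checks) == 1
        assert (checks[0].v_clean, checks[0].v_dirty) == pytest.approx((-0.1, -0.1))

    def test_backup_matches_depth1_expectimax(self, rng):
        for _ in range(10):
            params = random_params(rng)
            t = build_tables(params)
            vals = rng.uniform(-2, 0, size=(4, 2))
            alphas = [
                AlphaVector(v[0], v[1], Action(int(i % 3)))
                for i, v in enumerate(vals)
            ]
            out = bellman_backup(alphas, t, params.gamma)

            def v_old(b):
                return envelope_at(alphas, b)

            for b in GRID:
                want = expectimax_depth1(b, t, params.gamma, v_old)
                assert envelope_at(out, b) == pytest.approx(want, abs=1e-10)


# ---------------------------------------------------------------------------
# solve
# ---------------------------------------------------------------------------


class TestSolve:
    def test_myopic_actions_at_certainty(self, default_params):
        # γ=0: at b=1 the cheapest action wins; at b=0 cooking is free
        p = default_params.with_(
            gamma=0.0, cost_wash=-0.2, cost_check=-0.1, cost_sickness=-0.7
        )
        policy = solve(p)
        assert policy_action(policy, 1.0) == Action.CHECK
        assert policy_action(policy, 0.0) == Action.COOK

    def test_matches_finite_horizon_grid_dp(self, rng):
        for i in range(50):
            params = random_params(rng)
            if params.gamma > 0.95:
                params = params.with_(gamma=rng.uniform(0, 0.95))
            policy = solve(params)
            assert policy.converged
            t = build_tables(params)
            grid, v_ref = grid_dp(t, params.gamma)
            v_here = policy.value(GRID)
            v_there = np.interp(GRID, grid, v_ref)
            scale = 1.0 / (1.0 - params.gamma)
            assert np.max(np.abs(v_here - v_there)) < 1e-3 * scale, (
                f"instance {i}: gamma={params.gamma}"
            )

    def test_policy_action_matches_alpha_argmax(self, rng):
        for _ in range(5):
            policy = solve(random_params(rng))
            for b in GRID:
                vals = (1 - b) * policy.alpha_vals[:, 0] + b * policy.alpha_vals[:, 1]
                best = np.flatnonzero(vals == vals.max())
                want = min(int(policy.alpha_actions[i]) for i in best)
                assert int(policy_action(policy, b)) == want

    def test_tie_break_at_exact_crossing_prefers_cook(self):
        from compulsim.solver import Policy

        policy = Policy(
            alpha_vals=np.array([[1.0, 0.0], [0.0, 1.0]]),
            alpha_actions=np.array([int(Action.COOK), int(Action.WASH)]),
            seg_starts=np.array([0.0, 0.5]),
            gamma=0.5, residual=0.0, iterations=1, converged=True,
        )
        assert policy_action(policy, 0.25) == Action.COOK
        assert policy_action(policy, 0.75) == Action.WASH
        assert policy_action(policy, 0.5) == Action.COOK

    def test_policy_value_linear_interpolation(self):
        from compulsim.solver import Policy

        policy = Policy(
            alpha_vals=np.array([[0.0, -1.0]]),
            alpha_actions=np.array([0]),
            seg_starts=np.array([0.0]),
            gamma=0.0, residual=0.0, iterations=1, converged=True,
        )
        assert policy_value(policy, 0.25) == pytest.approx(-0.25)

    def test_gamma_zero_value_at_certain_clean_is_reward(self, default_params):
        policy = solve(default_params.with_(gamma=0.0))
        assert policy_value(policy, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_value_dominates_fixed_action_policies(self, rng):
        for _ in range(3):
            params = random_params(rng)
            if params.gamma > 0.9:
                params = params.with_(gamma=0.9)
            policy = solve(params)
            t = build_tables(params)
            for b0 in (0.2, 0.8):
                v_star = policy_value(policy, b0)
                for a in range(3):
                    mean, se = mc_fixed_action_value(
                        b0, a, t, params.gamma, rng
                    )
                    assert v_star >= mean - 4 * se - 1e-6

    def test_affine_reward_invariance(self, rng):
        # greedy actions are unchanged by positive affine reward maps
        for _ in range(10):
            params = random_params(rng)
            t = build_tables(params)
            t2 = ModelTables(
                transition=t.transition,
                observation=t.observation,
                reward=2.5 * t.reward + 0.7,
            )
            p1 = solve_tables(t, params.gamma)
            p2 = solve_tables(t2, params.gamma)
            acts1 = p1.action_at(GRID)
            acts2 = p2.action_at(GRID)
            # microscopic boundary shifts can flip isolated grid points;
            # the policies must agree essentially everywhere
            assert np.mean(acts1 == acts2) > 0.98

    def test_residual_contracts_geometrically(self, default_params):
        policy = solve(default_params, keep_history=True)
        hist = policy.residual_history
        assert policy.converged
        assert hist[-1] <= 1e-5 * (1 - 0.9) / (2 * 0.9)
        # Bellman updates contract at rate ≤ γ (allow tiny slack for
        # envelope simplification)
        ratios = hist[1:] / np.maximum(hist[:-1], 1e-300)
        assert np.all(ratios[:10] <= default_params.gamma + 0.05)

    def test_value_function_convex(self, rng):
        for _ in range(10):
            policy = solve(random_params(rng))
            v = policy.value(GRID)
            second_diff = v[:-2] - 2 * v[1:-1] + v[2:]
            assert np.all(second_diff >= -1e-9)

    def test_nonconvergence_is_flagged_not_silent(self, default_params):
        with pytest.warns(RuntimeWarning, match="did not reach"):
            policy = solve(default_params.with_(gamma=0.99), max_iter=3)
        assert not policy.converged

    def test_jit_core_agrees_with_reference_backup_iteration(self, rng):
        # iterating the pure-python backup + exact pruning must produce the
        # same value function as the compiled value-iteration core
        for _ in range(5):
            params = random_params(rng)
            if params.gamma > 0.8:
                params = params.with_(gamma=0.8)
            t = build_tables(params)
            alphas = [
                AlphaVector(float(t.reward[a][0]), float(t.reward[a][1]),
                            Action(a))
                for a in range(3)
            ]
            for _ in range(60):
                alphas = prune_envelope(
                    bellman_backup(alphas, t, params.gamma)
                )
            policy = solve(params)
            v_ref = np.array([envelope_at(alphas, b) for b in GRID])
            np.testing.assert_allclose(policy.value(GRID), v_ref, atol=1e-4)

    def test_action_gaps_identify_unavailable_actions(self, default_params):
        # checking is useless when observations carry no information
        p = default_params.with_(p_detect_dirty=0.5, p_detect_clean=0.5)
        policy = solve(p)
        gaps = action_value_gaps(policy, build_tables(p))
        assert gaps[int(Action.CHECK)] < -1e-4
        assert gaps[int(Action.COOK)] > -1e-6  # cook is greedy somewhere
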