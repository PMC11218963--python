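"""Agent-environment simulation, compulsive-episode detection and metrics.

An agent acts by querying its subjectively optimal policy at its current
belief, while states, observations and rewards evolve under the *true*
world tables; the belief is then updated with the agent's *subjective*
tables.  This mismatch between the generative process and the agent's
internal model is what turns belief distortions into behavior.

A **compulsive episode** is a maximal run of non-cook actions containing at
least two wash actions or at least two check actions (e.g.
cook–check–wash–check–cook qualifies, cook–wash–check–cook does not).
Per-agent behavioral metrics (episode counts and durations, post-wash
belief-update amplitude, action-transition probabilities, belief held at
each action) are pooled across an agent's sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import Action, BeliefUpdateError, ModelTables
from .solver import Policy

__all__ = [
    "SimConfig",
    "EpisodeTrace",
    "CompulsiveEpisode",
    "AgentMetrics",
    "run_sequence",
    "run_sequences",
    "detect_episodes",
    "compute_metrics",
    "classify_compulsion_type",
]

_COOK, _WASH, _CHECK = int(Action.COOK), int(Action.WASH), int(Action.CHECK)


@dataclass(frozen=True)
class SimConfig:
    """Simulation sizes: number of action sequences per agent and actions
    per sequence.  ``coupled_init`` draws the initial state from the initial
    belief (s₀ ~ Bernoulli(b₀), so the starting belief is calibrated);
    setting it False draws the state as an independent fair coin.
    """

    n_sequences: int = 200
    n_actions: int = 1000
    seed: int | None = None
    coupled_init: bool = True

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.n_actions < 1:
            raise ValueError("n_sequences and n_actions must be positive")


@dataclass(frozen=True)
class EpisodeTrace:
    """One simulated sequence of length N.

    ``states[t]`` is the (hidden) state when action ``actions[t]`` was
    chosen; ``beliefs`` has length N+1 (belief before each action plus the
    terminal belief); ``final_state`` is the state after the last action.
    """

    actions: np.ndarray
    states: np.ndarray
    observations: np.ndarray
    beliefs: np.ndarray
    rewards: np.ndarray
    final_state: int

    def __len__(self) -> int:
        return len(self.actions)


@dataclass(frozen=True)
class CompulsiveEpisode:
    """A maximal non-cook run with a repeated wash or check.

    ``n_wash``/``n_check`` count occurrences inside the run;
    ``n_wash_repeats``/``n_check_repeats`` count *immediate* repetitions
    (wash→wash / check→check adjacent pairs), which drive the
    compulsion-type classification.
    """

    start: int
    end: int
    duration: int
    n_wash: int
    n_check: int
    n_wash_repeats: int = 0
    n_check_repeats: int = 0


@dataclass(frozen=True)
class AgentMetrics:
    """Per-agent behavioral summary pooled over all simulated sequences.

    Metrics whose defining events never occurred (e.g. the post-wash belief
    update of an agent that never washes) are NaN, not zero.
    ``transition_matrix[i, j]`` is the empirical probability of action j
    immediately following action i; rows of unused source actions are NaN.
    ``belief_at_action[a]`` is the mean subjective probability of *clean*
    hands, 1 − b, held when choosing action a.
    """

    is_compulsive: bool
    n_episodes_mean: float
    episode_duration_mean: float
    pct_actions_compulsive: float
    belief_update_after_wash: float
    transition_matrix: np.ndarray
    belief_at_action: np.ndarray
    compulsion_type: str
    n_episodes_total: int = 0
    actions_used: tuple = ()


def _extract_world(tables: ModelTables) -> tuple[float, float, float, float]:
    T, O = tables.transition, tables.observation
    return (
        float(T[_COOK, 0, 1]),  # p_soiling
        float(T[_WASH, 1, 0]),  # p_success
        float(O[_CHECK, 1, 1]),  # p_detect_dirty
        float(O[_CHECK, 0, 0]),  # p_detect_clean
    )


@njit(cache=True)
def _sim_kernel(
    seg_starts: np.ndarray,
    seg_actions: np.ndarray,
    ps_a: float,
    pw_a: float,
    pdd_a: float,
    pdc_a: float,
    ps_w: float,
    pw_w: float,
    pdd_w: float,
    pdc_w: float,
    R_w: np.ndarray,
    b0: np.ndarray,
    s0: np.ndarray,
    uniforms: np.ndarray,
    actions: np.ndarray,
    states: np.ndarray,
    observs: np.ndarray,
    beliefs: np.ndarray,
    rewards: np.ndarray,
    final_states: np.ndarray,
) -> int:
    """Step loop over all sequences; returns 0, or −1 on a zero-probability
    observation under the subjective model (Z = 0 in the Bayes update)."""
    n_seq, n_actions = actions.shape
    for k in range(n_seq):
        b = b0[k]
        s = s0[k]
        beliefs[k, 0] = b
        for t in range(n_actions):
            idx = np.searchsorted(seg_starts, b, side="right") - 1
            a = seg_actions[idx]
            if idx > 0 and b == seg_starts[idx]:
                a2 = seg_actions[idx - 1]  # exact tie on a boundary:
                if a2 < a:  # lowest action index wins
                    a = a2
            u_s = uniforms[k, t, 0]
            u_o = uniforms[k, t, 1]
            if a == 0:  # cook
                s_next = 1 if s == 1 else (1 if u_s < ps_w else 0)
                b_next = b + (1.0 - b) * ps_a
            elif a == 1:  # wash
                s_next = 0 if s == 0 else (0 if u_s < pw_w else 1)
                b_next = b * (1.0 - pw_a)
            else:  # check: state is static, observation informative
                s_next = s
                b_next = b
            if a == 2:
                p_obs_dirty = pdd_w if s_next == 1 else 1.0 - pdc_w
            else:
                p_obs_dirty = 0.5
            o = 1 if u_o < p_obs_dirty else 0
            if a == 2:
                if o == 1:
                    num = b * pdd_a
                    den = num + (1.0 - b) * (1.0 - pdc_a)
                else:
                    num = b * (1.0 - pdd_a)
                    den = num + (1.0 - b) * pdc_a
                if den <= 0.0:
                    return -1
                b_next = num / den
            if b_next < 0.0:
                b_next = 0.0
            elif b_next > 1.0:
                b_next = 1.0
            actions[k, t] = a
            states[k, t] = s
            observs[k, t] = o
            rewards[k, t] = R_w[a, s]
            beliefs[k, t + 1] = b_next
            b = b_next
            s = s_next
        final_states[k] = s
    return 0


def _simulate_arrays(
    policy: Policy,
    agent_tables: ModelTables,
    world_tables: ModelTables,
    n_actions: int,
    b0: np.ndarray,
    s0: np.ndarray,
    uniforms: np.ndarray,
) -> tuple[np.ndarray, ...]:
    """Simulate ``len(b0)`` sequences; returns the raw trace arrays.

    ``uniforms`` has shape (n_seq, n_actions, 2): one draw for the state
    transition and one for the observation at each step.
    """
    ps_a, pw_a, pdd_a, pdc_a = _extract_world(agent_tables)
    ps_w, pw_w, pdd_w, pdc_w = _extract_world(world_tables)

    n_seq = len(b0)
    actions = np.empty((n_seq, n_actions), dtype=np.int8)
    states = np.empty((n_seq, n_actions), dtype=np.int8)
    observs = np.empty((n_seq, n_actions), dtype=np.int8)
    beliefs = np.empty((n_seq, n_actions + 1), dtype=float)
    rewards = np.empty((n_seq, n_actions), dtype=float)
    final_states = np.empty(n_seq, dtype=np.int8)

    status = _sim_kernel(
        np.ascontiguousarray(policy.seg_starts),
        np.ascontiguousarray(policy.alpha_actions),
        ps_a, pw_a, pdd_a, pdc_a,
        ps_w, pw_w, pdd_w, pdc_w,
        np.ascontiguousarray(world_tables.reward),
        np.ascontiguousarray(b0, dtype=float),
        np.ascontiguousarray(s0, dtype=np.int64),
        np.ascontiguousarray(uniforms),
        actions, states, observs, beliefs, rewards, final_states,
    )
    if status != 0:
        raise BeliefUpdateError(
            "observation impossible under the subjective model (Z = 0)"
        )
    return actions, states, observs, beliefs, rewards, final_states


def _simulate_batch(
    policy: Policy,
    agent_tables: ModelTables,
    world_tables: ModelTables,
    n_actions: int,
    b0: np.ndarray,
    s0: np.ndarray,
    uniforms: np.ndarray,
) -> list[EpisodeTrace]:
    actions, states, observs, beliefs, rewards, final_states = _simulate_arrays(
        policy, agent_tables, world_tables, n_actions, b0, s0, uniforms
    )
    return [
        EpisodeTrace(
            actions=actions[k],
            states=states[k],
            observations=observs[k],
            beliefs=beliefs[k],
            rewards=rewards[k],
            final_state=int(final_states[k]),
        )
        for k in range(len(b0))
    ]


def _initial_draws(rng: np.random.Generator, coupled: bool):
    b0 = rng.random()
    u = rng.random()
    s0 = int(u < b0) if coupled else int(u < 0.5)
    return b0, s0


def _batch_draws(
    seq_rngs: list[np.random.Generator], n_actions: int, coupled: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pre-draw all randomness, one generator per sequence."""
    n_seq = len(seq_rngs)
    b0 = np.empty(n_seq)
    s0 = np.empty(n_seq, dtype=np.int64)
    uniforms = np.empty((n_seq, n_actions, 2))
    for k, rng in enumerate(seq_rngs):
        b0[k], s0[k] = _initial_draws(rng, coupled)
        uniforms[k] = rng.random((n_actions, 2))
    return b0, s0, uniforms


def run_sequence(
    policy: Policy,
    agent_tables: ModelTables,
    world_tables: ModelTables,
    config: SimConfig,
    rng: np.random.Generator,
) -> EpisodeTrace:
    """Simulate a single action sequence of length ``config.n_actions``."""
    n = config.n_actions
    b0, s0 = _initial_draws(rng, config.coupled_init)
    uniforms = rng.random((1, n, 2))
    (trace,) = _simulate_batch(
        policy,
        agent_tables,
        world_tables,
        n,
        np.array([b0]),
        np.array([s0]),
        uniforms,
    )
    return trace


def run_sequences(
    policy: Policy,
    agent_tables: ModelTables,
    world_tables: ModelTables,
    config: SimConfig,
    seq_rngs: list[np.random.Generator],
) -> list[EpisodeTrace]:
    """Simulate ``len(seq_rngs)`` sequences, one independent RNG each.

    Per-sequence RNGs make every sequence individually reproducible; the
    random draws per sequence are identical to :func:`run_sequence` with
    the same generator.
    """
    n = config.n_actions
    b0, s0, uniforms = _batch_draws(seq_rngs, n, config.coupled_init)
    return _simulate_batch(
        policy, agent_tables, world_tables, n, b0, s0, uniforms
    )


@njit(cache=True)
def _episode_scan(actions: np.ndarray) -> tuple[int, int, int, int]:
    """Count episodes and per-action usage over a (n_seq, N) action array.

    Returns (episode count, cook used, wash used, check used) — the raw
    ingredients of the world-acceptance criterion, without building
    episode objects.
    """
    n_ep = 0
    used_cook = 0
    used_wash = 0
    used_check = 0
    for k in range(actions.shape[0]):
        run_wash = 0
        run_check = 0
        for t in range(actions.shape[1]):
            a = actions[k, t]
            if a == 0:
                used_cook = 1
                if run_wash >= 2 or run_check >= 2:
                    n_ep += 1
                run_wash = 0
                run_check = 0
            elif a == 1:
                used_wash = 1
                run_wash += 1
            else:
                used_check = 1
                run_check += 1
        if run_wash >= 2 or run_check >= 2:  # run truncated by the boundary
            n_ep += 1
    return n_ep, used_cook, used_wash, used_check


def detect_episodes(actions) -> list[CompulsiveEpisode]:
    """Find all compulsive episodes in one action sequence.

    A maximal run of non-cook actions is an episode iff it contains at
    least two washes or at least two checks; runs truncated by the sequence
    boundary still qualify if the repetition criterion holds.
    """
    a = np.asarray(actions, dtype=np.int64)
    noncook = a != _COOK
    padded = np.concatenate([[0], noncook.astype(np.int8), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    episodes = []
    for s, e in zip(starts, ends):
        seg = a[s : e + 1]
        n_wash = int(np.count_nonzero(seg == _WASH))
        n_check = int(np.count_nonzero(seg == _CHECK))
        if n_wash >= 2 or n_check >= 2:
            pairs = (seg[:-1] == seg[1:]) if len(seg) > 1 else np.zeros(0, bool)
            episodes.append(
                CompulsiveEpisode(
                    start=int(s),
                    end=int(e),
                    duration=int(e - s + 1),
                    n_wash=n_wash,
                    n_check=n_check,
                    n_wash_repeats=int(
                        np.count_nonzero(pairs & (seg[:-1] == _WASH))
                    ),
                    n_check_repeats=int(
                        np.count_nonzero(pairs & (seg[:-1] == _CHECK))
                    ),
                )
            )
    return episodes


def classify_compulsion_type(episodes: list[CompulsiveEpisode]) -> str:
    """Agent-level compulsion type from which action is re-executed.

    The type is defined by *immediate* repetitions across all of an
    agent's episodes: ``pure_wash`` if the agent re-executes only washing
    (wash→wash pairs occur, check→check never does), ``pure_check`` for
    the converse, ``mixed`` when both kinds of repetition occur — and also
    for agents whose episodes qualify only through non-adjacent
    repetitions (e.g. check–wash–check, which interleaves the two
    behaviors).  ``none`` without episodes.
    """
    if not episodes:
        return "none"
    wash_rep = any(e.n_wash_repeats > 0 for e in episodes)
    check_rep = any(e.n_check_repeats > 0 for e in episodes)
    if wash_rep and not check_rep:
        return "pure_wash"
    if check_rep and not wash_rep:
        return "pure_check"
    return "mixed"


def compute_metrics(traces: list[EpisodeTrace]) -> AgentMetrics:
    """Pool all sequences of one agent into a behavioral summary."""
    if not traces:
        raise ValueError("compute_metrics requires at least one trace")

    all_episodes: list[CompulsiveEpisode] = []
    per_trace_counts = []
    total_actions = 0
    compulsive_actions = 0
    trans_counts = np.zeros((3, 3), dtype=np.int64)
    belief_sums = np.zeros(3)
    belief_counts = np.zeros(3, dtype=np.int64)
    wash_update_sum = 0.0
    wash_update_count = 0

    for tr in traces:
        a = np.asarray(tr.actions, dtype=np.int64)
        b = np.asarray(tr.beliefs, dtype=float)
        eps = detect_episodes(a)
        all_episodes.extend(eps)
        per_trace_counts.append(len(eps))
        total_actions += len(a)
        compulsive_actions += sum(e.duration for e in eps)
        np.add.at(trans_counts, (a[:-1], a[1:]), 1)
        np.add.at(belief_sums, a, 1.0 - b[:-1])
        np.add.at(belief_counts, a, 1)
        wash_idx = np.flatnonzero(a == _WASH)
        if len(wash_idx):
            wash_update_sum += float(np.abs(b[wash_idx + 1] - b[wash_idx]).sum())
            wash_update_count += len(wash_idx)

    row_tot = trans_counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        trans = trans_counts / row_tot
        belief_at = np.where(belief_counts > 0, belief_sums, np.nan) / np.where(
            belief_counts > 0, belief_counts, 1
        )

    n_ep = len(all_episodes)
    return AgentMetrics(
        is_compulsive=n_ep > 0,
        n_episodes_mean=float(np.mean(per_trace_counts)),
        episode_duration_mean=(
            float(np.mean([e.duration for e in all_episodes])) if n_ep else np.nan
        ),
        pct_actions_compulsive=100.0 * compulsive_actions / total_actions,
        belief_update_after_wash=(
            wash_update_sum / wash_update_count if wash_update_count else np.nan
        ),
        transition_matrix=trans,
        belief_at_action=belief_at,
        compulsion_type=classify_compulsion_type(all_episodes),
        n_episodes_total=n_ep,
        actions_used=tuple(
            int(x) for x in np.flatnonzero(belief_counts > 0)
        ),
    )
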