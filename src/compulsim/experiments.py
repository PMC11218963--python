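"""Orchestration of the agent-sampling experiments.

Two experiment families are implemented:

* **Simulation 1 (full belief distortions).**  For every accepted world,
  candidate agents with all nine subjective parameters drawn independently
  are simulated until a quota of compulsive and non-compulsive agents is
  collected (the paper-scale design is 50 + 50 per world across 100
  worlds).  Variant 1A additionally requires each retained agent's pooled
  sequences to contain all three actions (so every agent checks at least
  once); variant 1B drops the check requirement (cook and wash must still
  appear).
* **Simulation 2 (selective distortions).**  Agents are veridical except a
  single parameter (washing success, threat magnitude, or threat
  probability) resampled over its full support; all agents are kept,
  spread evenly over the world bank, for severity-curve analyses.

Results are flat per-agent records (world and agent parameters, belief
distortions, group label, behavioral metrics, seed paths) assembled into a
pandas DataFrame for the statistics layer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import pandas as pd

from .model import Action, build_tables
from .params import ScenarioParams, delta_params
from .sampling import (
    WorldBank,
    WorldEntry,
    sample_agent,
    solve_screened,
    subrng,
)
from .simulate import (
    AgentMetrics,
    EpisodeTrace,
    SimConfig,
    _batch_draws,
    _episode_scan,
    _simulate_arrays,
    compute_metrics,
)
from .solver import DEFAULT_MAX_ITER, DEFAULT_TOL

__all__ = [
    "AgentRecord",
    "ExperimentDataset",
    "stratify_agents",
    "run_simulation1",
    "run_simulation2",
    "DEFAULT_AGENT_CAP",
]

#: Candidate-agent cap per world (10,000 per group) before flagging a
#: partial result; prevalence of the rarer group among random agents is
#: world-dependent and unknown a priori.
DEFAULT_AGENT_CAP = 20_000

_TRANSITION_COLS = [
    f"p_{a.name.lower()}_{b.name.lower()}" for a in Action for b in Action
]
_BELIEF_COLS = [f"b_clean_at_{a.name.lower()}" for a in Action]


@dataclass(frozen=True)
class AgentRecord:
    """One simulated agent: parameters, distortions, group and metrics."""

    world_id: int
    world: ScenarioParams
    agent: ScenarioParams
    group: str  # "compulsive" | "non_compulsive"
    metrics: AgentMetrics
    candidate_index: int
    master_seed: int

    def to_row(self) -> dict:
        row: dict = {"world_id": self.world_id}
        for name, value in self.world.to_record("world").items():
            if name != "role":
                row[f"world_{name}"] = value
        for name, value in self.agent.to_record("agent").items():
            if name != "role":
                row[f"agent_{name}"] = value
        row.update(delta_params(self.agent, self.world).to_record())
        row["group"] = self.group
        m = self.metrics
        row.update(
            {
                "is_compulsive": m.is_compulsive,
                "n_episodes_mean": m.n_episodes_mean,
                "episode_duration_mean": m.episode_duration_mean,
                "pct_actions_compulsive": m.pct_actions_compulsive,
                "belief_update_after_wash": m.belief_update_after_wash,
                "compulsion_type": m.compulsion_type,
                "n_actions_used": len(m.actions_used),
            }
        )
        for col, value in zip(_TRANSITION_COLS, m.transition_matrix.ravel()):
            row[col] = value
        for col, value in zip(_BELIEF_COLS, m.belief_at_action):
            row[col] = value
        row["candidate_index"] = self.candidate_index
        row["master_seed"] = self.master_seed
        return row


@dataclass(frozen=True)
class ExperimentDataset:
    """Per-agent table plus the design label and configuration snapshot."""

    records: pd.DataFrame
    design: str  # "sim1A" | "sim1B" | "sim2A" | "sim2B" | "sim2C"
    config: dict

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def write_sidecar(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"design": self.design, "config": self.config}, fh, indent=2)

    def group(self, label: str) -> pd.DataFrame:
        return self.records[self.records["group"] == label]


def _required_actions(variant: str) -> set[int]:
    if variant == "1A":
        return {int(Action.COOK), int(Action.WASH), int(Action.CHECK)}
    if variant == "1B":
        return {int(Action.COOK), int(Action.WASH)}
    raise ValueError(f"variant must be '1A' or '1B', got {variant!r}")


def _traces_from_arrays(arrays) -> list[EpisodeTrace]:
    actions, states, observs, beliefs, rewards, final_states = arrays
    return [
        EpisodeTrace(
            actions=actions[k],
            states=states[k],
            observations=observs[k],
            beliefs=beliefs[k],
            rewards=rewards[k],
            final_state=int(final_states[k]),
        )
        for k in range(len(actions))
    ]


def _simulate_candidate(
    agent: ScenarioParams,
    world: ScenarioParams,
    config: SimConfig,
    seed: int,
    world_id: int,
    candidate: int,
    tol: float,
    max_iter: int,
    required_actions: tuple[int, ...] = (),
):
    """Solve (screened) and simulate one candidate agent.

    Returns (trace arrays, episode count, actions-used tuple) or
    ``(None, reason, None)`` when the solver failed or a required action is
    provably unavailable to the agent's policy.
    """
    policy, reason = solve_screened(
        agent, required_actions=required_actions, tol=tol, max_iter=max_iter
    )
    if policy is None:
        return None, reason, None
    agent_tables = build_tables(agent)
    world_tables = build_tables(world)
    rngs = [
        subrng(seed, world_id, candidate, k) for k in range(config.n_sequences)
    ]
    b0, s0, uniforms = _batch_draws(rngs, config.n_actions, config.coupled_init)
    arrays = _simulate_arrays(
        policy, agent_tables, world_tables, config.n_actions, b0, s0, uniforms
    )
    n_ep, used_cook, used_wash, used_check = _episode_scan(arrays[0])
    used = tuple(
        i for i, f in enumerate((used_cook, used_wash, used_check)) if f
    )
    return arrays, int(n_ep), used


def stratify_agents(
    world: WorldEntry,
    variant: str,
    quota: int,
    config: SimConfig,
    seed: int,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    agent_cap: int = DEFAULT_AGENT_CAP,
) -> tuple[list[AgentRecord], dict]:
    """Collect ``quota`` compulsive + ``quota`` non-compulsive agents.

    Candidate agents (all nine beliefs resampled independently) are
    simulated in this world until both group quotas are filled; candidates
    whose pooled sequences miss a required action for the variant are
    rejected before grouping.  Returns the records plus per-world
    diagnostics (candidates tried, rejections, whether the cap was hit).
    """
    required = _required_actions(variant)
    records: list[AgentRecord] = []
    counts = {"compulsive": 0, "non_compulsive": 0}
    diagnostics = {
        "world_id": world.world_id,
        "candidates": 0,
        "rejected_missing_actions": 0,
        "rejected_quota_full": 0,
        "rejected_solver": 0,
        "partial": False,
    }
    candidate = 0
    while min(counts.values()) < quota:
        if candidate >= agent_cap:
            diagnostics["partial"] = True
            break
        rng = subrng(seed, world.world_id, candidate)
        agent = sample_agent(rng)
        arrays, n_ep, used = _simulate_candidate(
            agent, world.params, config, seed, world.world_id, candidate,
            tol, max_iter, required_actions=tuple(sorted(required)),
        )
        candidate += 1
        diagnostics["candidates"] = candidate
        if arrays is None:
            if n_ep == "excluded_action":
                diagnostics["rejected_missing_actions"] += 1
            else:
                diagnostics["rejected_solver"] += 1
            continue
        if not required.issubset(set(used)):
            diagnostics["rejected_missing_actions"] += 1
            continue
        group = "compulsive" if n_ep > 0 else "non_compulsive"
        if counts[group] >= quota:
            diagnostics["rejected_quota_full"] += 1
            continue
        metrics = compute_metrics(_traces_from_arrays(arrays))
        counts[group] += 1
        records.append(
            AgentRecord(
                world_id=world.world_id,
                world=world.params,
                agent=agent,
                group=group,
                metrics=metrics,
                candidate_index=candidate - 1,
                master_seed=seed,
            )
        )
    return records, diagnostics


def run_simulation1(
    variant: str,
    world_bank: WorldBank,
    quota: int,
    config: SimConfig,
    seed: int,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    agent_cap: int = DEFAULT_AGENT_CAP,
) -> ExperimentDataset:
    """Map :func:`stratify_agents` over the world bank (Simulation 1A/1B)."""
    rows = []
    all_diags = []
    for world in world_bank.worlds:
        records, diag = stratify_agents(
            world, variant, quota, config, seed,
            tol=tol, max_iter=max_iter, agent_cap=agent_cap,
        )
        rows.extend(r.to_row() for r in records)
        all_diags.append(diag)
    return ExperimentDataset(
        records=pd.DataFrame(rows),
        design=f"sim{variant}",
        config={
            "variant": variant,
            "quota": quota,
            "seed": seed,
            "n_worlds": len(world_bank),
            "sim": asdict(config),
            "diagnostics": all_diags,
        },
    )


_SIM2_TARGETS = {
    "p_success": "sim2A",
    "cost_sickness": "sim2B",
    "p_soiling": "sim2C",
}


def run_simulation2(
    target: str,
    world_bank: WorldBank,
    n_agents: int,
    config: SimConfig,
    seed: int,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ExperimentDataset:
    """Selective-distortion agents (Simulation 2A/2B/2C), no group quotas.

    ``n_agents`` agents, veridical except ``target`` resampled over its
    full support, spread as evenly as possible over the bank's worlds.
    """
    if target not in _SIM2_TARGETS:
        raise ValueError(
            f"target must be one of {sorted(_SIM2_TARGETS)}, got {target!r}"
        )
    rows = []
    n_worlds = len(world_bank)
    per_world = [n_agents // n_worlds] * n_worlds
    for i in range(n_agents % n_worlds):
        per_world[i] += 1
    for world, n_here in zip(world_bank.worlds, per_world):
        for candidate in range(n_here):
            rng = subrng(seed, world.world_id, candidate)
            agent = sample_agent(rng, world=world.params, fix_all_but=target)
            arrays, n_ep, used = _simulate_candidate(
                agent, world.params, config, seed, world.world_id, candidate,
                tol, max_iter,
            )
            if arrays is None:
                continue
            metrics = compute_metrics(_traces_from_arrays(arrays))
            group = "compulsive" if metrics.is_compulsive else "non_compulsive"
            rows.append(
                AgentRecord(
                    world_id=world.world_id,
                    world=world.params,
                    agent=agent,
                    group=group,
                    metrics=metrics,
                    candidate_index=candidate,
                    master_seed=seed,
                ).to_row()
            )
    return ExperimentDataset(
        records=pd.DataFrame(rows),
        design=_SIM2_TARGETS[target],
        config={
            "target": target,
            "n_agents": n_agents,
            "seed": seed,
            "n_worlds": n_worlds,
            "sim": asdict(config),
        },
    )
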