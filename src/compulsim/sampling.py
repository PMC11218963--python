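"""Random generation of worlds and agents, and world acceptance filtering.

World parameters are drawn uniformly over their full supports: transition
probabilities over [0, 1], observation reliabilities over [0.5, 1] (state
inference is symmetric around chance), the three costs uniformly over the
unit 2-simplex (Dirichlet(1,1,1), so every affine-inequivalent reward
function is reachable), and the discount over [0, 1] capped just below 1
for solvability.

A sampled world is **accepted** only if a veridical agent (subjective
parameters equal to the true ones) simulated in it (a) uses all three
actions and (b) produces zero compulsive episodes — i.e. environments
where repetitive washing/checking would be the rational response are
excluded, so that compulsions observed later are attributable to *false*
beliefs.

Agents are sampled either with all nine parameters drawn independently by
the same scheme as worlds (beliefs span exactly the true supports), or
with all parameters veridical except one ("selective distortion").
Seeding is hierarchical (master → world → agent → sequence) and every
level is reproducible from integer paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import build_tables
from .params import ScenarioParams, normalize_outcomes
from .simulate import (
    SimConfig,
    _batch_draws,
    _episode_scan,
    _simulate_arrays,
)
from .solver import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    SCREEN_TOL,
    action_value_gaps,
    solve_tables,
)

__all__ = [
    "GAMMA_CAP",
    "subrng",
    "sample_cost_simplex",
    "sample_world",
    "sample_agent",
    "accept_world",
    "build_world_bank",
    "solve_screened",
    "WorldBank",
    "WorldEntry",
]

#: Discounts are sampled over [0, 1] but capped here before solving;
#: an undiscounted infinite-horizon problem is ill-posed.
GAMMA_CAP = 0.999

#: Parameters that :func:`sample_agent` can selectively distort.
SELECTIVE_PARAMS = (
    "p_soiling",
    "p_success",
    "p_detect_dirty",
    "p_detect_clean",
    "cost_sickness",
    "cost_wash",
    "cost_check",
    "gamma",
)


def subrng(master_seed: int, *path: int) -> np.random.Generator:
    """Independent generator for a node of the seeding hierarchy.

    Streams are indexed by integer paths (e.g. master → world index →
    agent index → sequence index) so any node can be replayed in
    isolation.
    """
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([int(master_seed), *map(int, path)]))
    )


def sample_cost_simplex(rng: np.random.Generator) -> tuple[float, float, float]:
    """Uniform draw of (cost_sickness, cost_wash, cost_check) on −(unit 2-simplex)."""
    z = rng.dirichlet((1.0, 1.0, 1.0))
    return (-float(z[0]), -float(z[1]), -float(z[2]))


def sample_world(rng: np.random.Generator, gamma_cap: float = GAMMA_CAP) -> ScenarioParams:
    """Draw one full parameter set uniformly over the supports."""
    cs, cw, cc = sample_cost_simplex(rng)
    return ScenarioParams(
        p_soiling=float(rng.uniform(0.0, 1.0)),
        p_success=float(rng.uniform(0.0, 1.0)),
        p_detect_dirty=float(rng.uniform(0.5, 1.0)),
        p_detect_clean=float(rng.uniform(0.5, 1.0)),
        cost_sickness=cs,
        cost_wash=cw,
        cost_check=cc,
        gamma=min(float(rng.uniform(0.0, 1.0)), gamma_cap),
    )


def sample_agent(
    rng: np.random.Generator,
    world: ScenarioParams | None = None,
    fix_all_but: str | None = None,
    gamma_cap: float = GAMMA_CAP,
) -> ScenarioParams:
    """Draw one agent's subjective parameter set.

    Without ``fix_all_but`` all nine parameters are sampled independently
    by the world scheme (so subjective beliefs span exactly the true
    supports).  With ``fix_all_but=<name>`` the agent equals ``world``
    except that one parameter, which is resampled uniformly over its full
    support.

    Distorting a single cost breaks the −1-sum constraint: the distorted
    cost is substituted at its raw value (uniform over (−1, 0)) with the
    other two costs untouched, and the resulting triple is renormalized
    onto the cost simplex — which preserves the untouched costs' ratio
    and, by affine invariance of the policy, leaves behavior identical to
    using the unnormalized triple directly.  In particular the *relative*
    weight of the untouched costs stays bounded away from zero, so an
    extreme threat distortion cannot make washing or checking spuriously
    free.
    """
    if fix_all_but is None:
        return sample_world(rng, gamma_cap=gamma_cap)
    if world is None:
        raise ValueError("fix_all_but requires a reference world")
    if fix_all_but not in SELECTIVE_PARAMS:
        raise ValueError(f"unknown parameter {fix_all_but!r}")

    if fix_all_but in ("p_soiling", "p_success"):
        return world.with_(**{fix_all_but: float(rng.uniform(0.0, 1.0))})
    if fix_all_but in ("p_detect_dirty", "p_detect_clean"):
        return world.with_(**{fix_all_but: float(rng.uniform(0.5, 1.0))})
    if fix_all_but == "gamma":
        return world.with_(gamma=min(float(rng.uniform(0.0, 1.0)), gamma_cap))

    # cost distortion: substitute the raw target cost, renormalize the triple
    new_cost = -max(float(rng.uniform(0.0, 1.0)), 1e-12)
    raw = {
        "cost_sickness": world.cost_sickness,
        "cost_wash": world.cost_wash,
        "cost_check": world.cost_check,
        fix_all_but: new_cost,
    }
    _, (cs, cw, cc) = normalize_outcomes(
        0.0, (raw["cost_sickness"], raw["cost_wash"], raw["cost_check"])
    )
    return world.with_(cost_sickness=cs, cost_wash=cw, cost_check=cc)


def solve_screened(
    params: ScenarioParams,
    required_actions: tuple[int, ...] = (),
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
):
    """Two-stage solve: cheap screen, then full precision on survivors.

    First solves at the coarse :data:`~compulsim.solver.SCREEN_TOL`; if any
    required action is provably never greedy under the exact optimum (its
    backed-up value stays below the envelope by more than the screen
    tolerance everywhere on the simplex), returns ``(None, reason)``
    without paying for the full solve.  Otherwise resumes value iteration
    from the coarse solution down to ``tol``.

    Returns ``(policy, None)`` on success, ``(None, reason)`` otherwise
    (``reason`` is ``"excluded_action"`` or ``"not_converged"``).
    """
    tables = build_tables(params)
    coarse = solve_tables(
        tables, params.gamma, tol=SCREEN_TOL, max_iter=max_iter
    )
    if not coarse.converged:
        return None, "not_converged"
    if required_actions:
        gaps = action_value_gaps(coarse, tables)
        if any(gaps[a] < -SCREEN_TOL for a in required_actions):
            return None, "excluded_action"
    policy = solve_tables(
        tables, params.gamma, tol=tol, max_iter=max_iter, warm_start=coarse
    )
    if not policy.converged:
        return None, "not_converged"
    return policy, None


@dataclass(frozen=True)
class WorldEntry:
    """An accepted world with its acceptance diagnostics."""

    world_id: int
    params: ScenarioParams
    seed_path: tuple
    actions_used: tuple
    n_episodes: int
    attempts: int


@dataclass(frozen=True)
class WorldBank:
    """Bank of accepted worlds plus the acceptance bookkeeping."""

    worlds: list[WorldEntry]
    master_seed: int
    n_candidates: int
    sim_config: SimConfig

    @property
    def acceptance_rate(self) -> float:
        return len(self.worlds) / self.n_candidates

    def __len__(self) -> int:
        return len(self.worlds)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in self.worlds:
            row = {"world_id": w.world_id}
            row.update(w.params.to_record("world"))
            row.pop("role")
            row.update(
                {
                    "candidate_index": w.seed_path[-1],
                    "master_seed": self.master_seed,
                    "actions_used": "|".join(map(str, w.actions_used)),
                    "n_episodes": w.n_episodes,
                    "attempts": w.attempts,
                }
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def accept_world(
    world: ScenarioParams,
    config: SimConfig,
    seed: int,
    candidate_index: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[bool, dict]:
    """Veridical-agent screen: does the optimal policy avoid compulsions?

    Solves the world with truthful beliefs, simulates
    ``config.n_sequences × config.n_actions`` steps, and accepts iff all
    three actions occur in the pooled sequences and no compulsive episode
    does.  Worlds in which an action is provably never optimal are
    rejected without simulating (an action the policy can never choose
    cannot occur in its sequences).  Returns (accepted, diagnostics).
    """
    policy, reason = solve_screened(
        world, required_actions=(0, 1, 2), tol=tol, max_iter=max_iter
    )
    diagnostics: dict = {"converged": reason != "not_converged"}
    if policy is None:
        diagnostics["reason"] = reason
        diagnostics["n_episodes"] = None
        return False, diagnostics
    tables = build_tables(world)
    rngs = [
        subrng(seed, candidate_index, k) for k in range(config.n_sequences)
    ]
    b0, s0, uniforms = _batch_draws(rngs, config.n_actions, config.coupled_init)
    actions = _simulate_arrays(
        policy, tables, tables, config.n_actions, b0, s0, uniforms
    )[0]
    n_ep, used_cook, used_wash, used_check = _episode_scan(actions)
    used = tuple(
        i for i, flag in enumerate((used_cook, used_wash, used_check)) if flag
    )
    diagnostics["actions_used"] = used
    diagnostics["n_episodes"] = int(n_ep)
    accepted = len(used) == 3 and n_ep == 0
    return accepted, diagnostics


def build_world_bank(
    n: int = 100,
    seed: int = 0,
    config: SimConfig | None = None,
    max_attempts: int | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> WorldBank:
    """Rejection-sample ``n`` accepted worlds.

    Worlds in which a truthful agent never needs to check, or in which even
    truthful agents repeat washing/checking, dominate the uniform parameter
    space, so acceptance is a rare event (empirically a few per thousand
    candidates).  ``max_attempts`` (default 4000·n) bounds the number of
    candidates before giving up with an error.
    """
    config = config or SimConfig()
    if max_attempts is None:
        max_attempts = 4000 * n
    worlds: list[WorldEntry] = []
    candidate = 0
    while len(worlds) < n:
        if candidate >= max_attempts:
            raise RuntimeError(
                f"only {len(worlds)}/{n} worlds accepted after "
                f"{max_attempts} candidates"
            )
        rng = subrng(seed, candidate)
        params = sample_world(rng)
        accepted, diag = accept_world(
            params, config, seed, candidate_index=candidate,
            tol=tol, max_iter=max_iter,
        )
        if accepted:
            worlds.append(
                WorldEntry(
                    world_id=len(worlds),
                    params=params,
                    seed_path=(seed, candidate),
                    actions_used=diag["actions_used"],
                    n_episodes=diag["n_episodes"],
                    attempts=candidate + 1,
                )
            )
        candidate += 1
    return WorldBank(
        worlds=worlds,
        master_seed=seed,
        n_candidates=candidate,
        sim_config=config,
    )
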