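"""POMDP tables and Bayesian belief updating for the handwashing scenario.

The scenario has two hidden states (clean / dirty hands), three actions
(cook / wash / check) and two observations (hands appear clean / dirty).
Cooking can soil clean hands, washing can clean dirty hands, and checking
never changes the state but yields a partially informative observation.
The agent never sees the state; it carries a scalar belief

    b = P(state = dirty)

on the 1-simplex [0, 1] and updates it by Bayes' rule after every action,
using its *subjective* transition and observation tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .params import ScenarioParams

__all__ = [
    "State",
    "Action",
    "Obs",
    "ModelTables",
    "build_tables",
    "belief_update",
    "BELIEF_TOL",
]

#: Tolerance used to clamp beliefs back into [0, 1] after floating-point
#: rounding in the Bayes update.
BELIEF_TOL = 1e-12


class State(IntEnum):
    CLEAN = 0
    DIRTY = 1


class Action(IntEnum):
    # The order encodes the deterministic tie-break used everywhere:
    # at exact value ties the lowest index wins.
    COOK = 0
    WASH = 1
    CHECK = 2


class Obs(IntEnum):
    CLEAN = 0
    DIRTY = 1


@dataclass(frozen=True)
class ModelTables:
    """Dense transition / observation / reward tables.

    Attributes
    ----------
    transition : ndarray, shape (3, 2, 2)
        ``transition[a, s, s']`` = P(next state s' | action a, state s).
    observation : ndarray, shape (3, 2, 2)
        ``observation[a, s', o]`` = P(observation o | action a, next state s').
    reward : ndarray, shape (3, 2)
        ``reward[a, s]`` = utility of taking action a in state s.
    """

    transition: np.ndarray
    observation: np.ndarray
    reward: np.ndarray

    def __post_init__(self) -> None:
        T, O, R = self.transition, self.observation, self.reward
        if T.shape != (3, 2, 2) or O.shape != (3, 2, 2) or R.shape != (3, 2):
            raise ValueError("tables must have shapes (3,2,2), (3,2,2), (3,2)")
        if not np.allclose(T.sum(axis=2), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if not np.allclose(O.sum(axis=2), 1.0, atol=1e-12):
            raise ValueError("observation rows must sum to 1")


def build_tables(params: ScenarioParams) -> ModelTables:
    """Populate the scenario tables from one parameter set.

    Transitions: cooking soils clean hands with probability ``p_soiling``
    (dirty hands stay dirty); washing cleans dirty hands with probability
    ``p_success`` (clean hands stay clean); checking never changes the state.
    Observations are at chance (0.5/0.5) for cook and wash, and match the
    next state with probability ``p_detect_clean`` / ``p_detect_dirty`` for
    check.  Rewards: cooking yields ``reward_dinner`` when clean and
    ``cost_sickness`` when dirty; wash and check have state-independent
    costs.
    """
    ps, pw = params.p_soiling, params.p_success
    T = np.empty((3, 2, 2))
    T[Action.COOK] = [[1.0 - ps, ps], [0.0, 1.0]]
    T[Action.WASH] = [[1.0, 0.0], [pw, 1.0 - pw]]
    T[Action.CHECK] = np.eye(2)

    dc, dd = params.p_detect_clean, params.p_detect_dirty
    O = np.full((3, 2, 2), 0.5)
    O[Action.CHECK] = [[dc, 1.0 - dc], [1.0 - dd, dd]]

    R = np.array(
        [
            [params.reward_dinner, params.cost_sickness],
            [params.cost_wash, params.cost_wash],
            [params.cost_check, params.cost_check],
        ]
    )
    return ModelTables(transition=T, observation=O, reward=R)


class BeliefUpdateError(ArithmeticError):
    """The observation has zero probability under the subjective model."""


def belief_update(
    b: float, action: int, obs: int, agent_tables: ModelTables
) -> float:
    """Bayes-optimal belief update under the agent's subjective model.

    The prior belief ``b = P(dirty)`` is first pushed through the subjective
    transition table of the chosen action (prediction), then reweighted by
    the subjective likelihood of the received observation in each candidate
    next state.  For cook and wash the observation is uninformative (0.5
    likelihood everywhere) so the update reduces to the prediction step; for
    check the state is static so the update is purely observational.

    Returns the posterior P(next state = dirty), clamped into [0, 1] to
    absorb rounding at the 1e-12 level.
    """
    if not 0.0 <= b <= 1.0:
        raise ValueError(f"belief {b!r} outside [0, 1]")
    prior = np.array([1.0 - b, b])
    pred = prior @ agent_tables.transition[action]  # P(s')
    post = agent_tables.observation[action, :, obs] * pred
    z = post.sum()
    if z <= 0.0:
        raise BeliefUpdateError(
            f"observation {obs} has zero probability after action {action} "
            f"from belief {b}"
        )
    b_next = float(post[State.DIRTY] / z)
    if b_next < 0.0:
        if b_next < -BELIEF_TOL:
            raise BeliefUpdateError(f"belief update produced {b_next}")
        b_next = 0.0
    elif b_next > 1.0:
        if b_next > 1.0 + BELIEF_TOL:
            raise BeliefUpdateError(f"belief update produced {b_next}")
        b_next = 1.0
    return b_next
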