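"""Scenario parameters for the handwashing safety scenario.

A scenario is described by nine quantities: two transition probabilities
(``p_soiling``, ``p_success``), two observation reliabilities
(``p_detect_dirty``, ``p_detect_clean``), four outcome utilities
(``reward_dinner``, ``cost_sickness``, ``cost_wash``, ``cost_check``) and a
temporal discount ``gamma``.  The same structure is used in two roles:

* **world parameters** — the true contingencies of the environment, used to
  sample states, observations and rewards during simulation;
* **agent parameters** — an agent's subjective point beliefs about those
  contingencies, used to compute its policy and to update its state belief.

Because an optimal policy is invariant under positive affine transformations
of the reward function, outcomes live on a normalized scale: the single
positive outcome (``reward_dinner``) is fixed to 0 and the three costs are
scaled so that they sum to −1.  The absolute costs then form a point on the
unit 2-simplex, which is the natural space for comparing agents' relative
sensitivities to washing, checking, and sickness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, replace

__all__ = [
    "ScenarioParams",
    "DeltaParams",
    "normalize_outcomes",
    "delta_params",
    "PARAM_NAMES",
]

#: Canonical ordering of the nine scenario parameters.
PARAM_NAMES = (
    "p_soiling",
    "p_success",
    "p_detect_dirty",
    "p_detect_clean",
    "reward_dinner",
    "cost_sickness",
    "cost_wash",
    "cost_check",
    "gamma",
)

_NORM_TOL = 1e-9


class ParameterError(ValueError):
    """A scenario parameter is outside its support."""


@dataclass(frozen=True)
class ScenarioParams:
    """Nine parameters of the handwashing scenario on the normalized scale.

    Parameters
    ----------
    p_soiling : float
        Probability that cooking soils clean hands, in [0, 1].
    p_success : float
        Probability that washing cleans dirty hands, in [0, 1].
    p_detect_dirty : float
        Probability that checking dirty hands yields a "dirty" observation,
        in [0.5, 1] (chance level and up; inference is symmetric around 0.5).
    p_detect_clean : float
        Probability that checking clean hands yields a "clean" observation,
        in [0.5, 1].
    reward_dinner : float
        Utility of cooking with clean hands.  Fixed to 0 on the normalized
        scale; it is the baseline all costs are measured against.
    cost_sickness : float
        Utility (≤ 0) of cooking with dirty hands.
    cost_wash : float
        Utility (≤ 0) of washing, independent of state.
    cost_check : float
        Utility (≤ 0) of checking, independent of state.
    gamma : float
        Temporal discount in [0, 1); horizon of the planning problem.
    """

    p_soiling: float
    p_success: float
    p_detect_dirty: float
    p_detect_clean: float
    cost_sickness: float
    cost_wash: float
    cost_check: float
    gamma: float
    reward_dinner: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_soiling", "p_success"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v!r} outside [0, 1]")
        for name in ("p_detect_dirty", "p_detect_clean"):
            v = getattr(self, name)
            if not 0.5 <= v <= 1.0:
                raise ParameterError(f"{name}={v!r} outside [0.5, 1]")
        if not 0.0 <= self.gamma < 1.0:
            raise ParameterError(f"gamma={self.gamma!r} outside [0, 1)")
        if self.reward_dinner != 0.0:
            raise ParameterError(
                f"reward_dinner={self.reward_dinner!r}; the normalized scale "
                "fixes it to 0 (use normalize_outcomes / from_raw_outcomes)"
            )
        for name in ("cost_sickness", "cost_wash", "cost_check"):
            v = getattr(self, name)
            if v > 0.0:
                raise ParameterError(f"{name}={v!r} must be ≤ 0")
        total = self.cost_sickness + self.cost_wash + self.cost_check
        if abs(total + 1.0) > _NORM_TOL:
            raise ParameterError(
                f"costs sum to {total!r}, expected −1 on the normalized scale"
            )

    @classmethod
    def from_raw_outcomes(
        cls,
        *,
        p_soiling: float,
        p_success: float,
        p_detect_dirty: float,
        p_detect_clean: float,
        reward_dinner: float,
        cost_sickness: float,
        cost_wash: float,
        cost_check: float,
        gamma: float,
    ) -> "ScenarioParams":
        """Build parameters from outcomes on an arbitrary utility scale."""
        _, (cs, cw, cc) = normalize_outcomes(
            reward_dinner, (cost_sickness, cost_wash, cost_check)
        )
        return cls(
            p_soiling=p_soiling,
            p_success=p_success,
            p_detect_dirty=p_detect_dirty,
            p_detect_clean=p_detect_clean,
            cost_sickness=cs,
            cost_wash=cw,
            cost_check=cc,
            gamma=gamma,
        )

    # -- serialization ---------------------------------------------------

    def to_record(self, role: str) -> dict:
        """Flat key→value record; ``role`` is ``"world"`` or ``"agent"``."""
        if role not in ("world", "agent"):
            raise ValueError(f"role must be 'world' or 'agent', got {role!r}")
        rec = {name: getattr(self, name) for name in PARAM_NAMES}
        rec["role"] = role
        return rec

    @classmethod
    def from_record(cls, record: dict) -> "ScenarioParams":
        kwargs = {name: float(record[name]) for name in PARAM_NAMES}
        return cls(**kwargs)

    def to_json(self, role: str) -> str:
        return json.dumps(self.to_record(role))

    @classmethod
    def from_json(cls, text: str) -> "ScenarioParams":
        return cls.from_record(json.loads(text))

    def with_(self, **changes) -> "ScenarioParams":
        """Copy with selected fields replaced (re-validates)."""
        return replace(self, **changes)


def normalize_outcomes(
    raw_reward: float, raw_costs: tuple[float, float, float]
) -> tuple[float, tuple[float, float, float]]:
    """Map outcomes onto the normalized scale (reward 0, costs summing to −1).

    Utilities are only defined up to a positive affine transformation, so the
    four outcome parameters overspecify the reward function.  The map

        z(v) = (v − reward) / Σ_i (cost_i − reward)

    sends the reward to 0 and the three (reward-relative) costs to the unit
    2-simplex; the normalized costs are the negatives of their z-images.

    Parameters
    ----------
    raw_reward : float
        Utility of the positive outcome (dinner) on the raw scale.
    raw_costs : tuple of float
        Raw utilities of (sickness, wash, check), each strictly below
        ``raw_reward``.

    Returns
    -------
    (0.0, (cost_sickness, cost_wash, cost_check)) on the normalized scale.
    """
    shifted = [c - raw_reward for c in raw_costs]
    if any(s >= 0 for s in shifted):
        raise ParameterError(
            "each raw cost must be strictly smaller than the raw reward"
        )
    denom = sum(shifted)
    if denom == 0:
        raise ParameterError("degenerate outcomes: zero normalization denominator")
    z = [s / denom for s in shifted]  # on the open unit simplex
    return 0.0, tuple(-zi for zi in z)


@dataclass(frozen=True)
class DeltaParams:
    """Belief-distortion vector: agent parameters minus world parameters.

    Sign conventions follow the scenario semantics, e.g. ``d_p_success < 0``
    is doubt about the effectiveness of washing and ``d_cost_sickness < 0``
    is overestimation of threat magnitude (a more negative subjective cost).
    ``d_reward_dinner`` is identically 0 on the normalized scale.
    """

    d_p_soiling: float
    d_p_success: float
    d_p_detect_dirty: float
    d_p_detect_clean: float
    d_cost_sickness: float
    d_cost_wash: float
    d_cost_check: float
    d_gamma: float
    d_reward_dinner: float = 0.0

    def to_record(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def delta_params(agent: ScenarioParams, world: ScenarioParams) -> DeltaParams:
    """Elementwise agent − world difference for all nine parameters."""
    return DeltaParams(
        d_p_soiling=agent.p_soiling - world.p_soiling,
        d_p_success=agent.p_success - world.p_success,
        d_p_detect_dirty=agent.p_detect_dirty - world.p_detect_dirty,
        d_p_detect_clean=agent.p_detect_clean - world.p_detect_clean,
        d_cost_sickness=agent.cost_sickness - world.cost_sickness,
        d_cost_wash=agent.cost_wash - world.cost_wash,
        d_cost_check=agent.cost_check - world.cost_check,
        d_gamma=agent.gamma - world.gamma,
        d_reward_dinner=agent.reward_dinner - world.reward_dinner,
    )
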