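"""Run configuration and scale presets.

Two presets are provided: ``paper`` reproduces the published experiment
sizes (100 worlds, 50 + 50 agents per world, 200 sequences × 1,000 actions,
10,000 bootstrap repetitions), and ``desk`` is a scaled-down design (20
worlds, 20 + 20 agents per world, 50 sequences × 500 actions, 2,000
repetitions) that preserves the effect directions while running in minutes
on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

from .simulate import SimConfig
from .solver import DEFAULT_MAX_ITER, DEFAULT_TOL
from .stats import BootstrapConfig

__all__ = ["RunConfig", "PRESETS"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved settings for a full experiment run."""

    n_worlds: int = 100
    quota: int = 50
    sim2_n_agents: int = 5000
    n_sequences: int = 200
    n_actions: int = 1000
    bootstrap_reps: int = 10_000
    solver_tol: float = DEFAULT_TOL
    solver_max_iter: int = DEFAULT_MAX_ITER
    seed: int = 0
    scale: str = "paper"

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_sequences=self.n_sequences,
            n_actions=self.n_actions,
            seed=self.seed,
        )

    def bootstrap_config(self) -> BootstrapConfig:
        return BootstrapConfig(reps=self.bootstrap_reps)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def snapshot(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")

    @classmethod
    def from_preset(cls, scale: str, seed: int = 0, **overrides) -> "RunConfig":
        if scale not in PRESETS:
            raise ValueError(f"unknown preset {scale!r}; choose from {sorted(PRESETS)}")
        base = replace(PRESETS[scale], seed=seed)
        return replace(base, **overrides) if overrides else base

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a flat key=value (or JSON) configuration file."""
        with open(path) as fh:
            text = fh.read()
        stripped = text.strip()
        if stripped.startswith("{"):
            raw = json.loads(stripped)
        else:
            raw = {}
            for line in stripped.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                raw[key.strip()] = value.strip()
        scale = raw.pop("scale", "paper")
        base = PRESETS.get(scale, PRESETS["paper"])
        kwargs = {}
        for f_ in ("n_worlds", "quota", "sim2_n_agents", "n_sequences",
                   "n_actions", "bootstrap_reps", "solver_max_iter", "seed"):
            if f_ in raw:
                kwargs[f_] = int(raw[f_])
        if "solver_tol" in raw:
            kwargs["solver_tol"] = float(raw["solver_tol"])
        return replace(base, scale=scale, **kwargs)


PRESETS = {
    "paper": RunConfig(),
    "desk": RunConfig(
        n_worlds=20,
        quota=20,
        sim2_n_agents=1000,
        n_sequences=50,
        n_actions=500,
        bootstrap_reps=2000,
        scale="desk",
    ),
}
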