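"""Reader/writer for Cassandra's ``.pomdp`` text format.

Exporting a scenario in this format allows cross-validation of policies
against Anthony Cassandra's classic ``pomdp-solve`` program.  Numbers are
written with 17 significant digits so a round-trip through the file is
bit-exact.  The reader supports the explicit-entry dialect this writer
emits (``T:``/``O:``/``R:`` lines with named states), not the full grammar.
"""

from __future__ import annotations

import os
from typing import TextIO

import numpy as np

from .model import ModelTables, build_tables
from .params import ScenarioParams

__all__ = ["write_pomdp_file", "read_pomdp_file"]

_STATES = ("clean", "dirty")
_ACTIONS = ("cook", "wash", "check")
_OBS = ("o-clean", "o-dirty")


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def _write(tables: ModelTables, gamma: float, fh: TextIO) -> None:
    fh.write(f"discount: {_fmt(gamma)}\n")
    fh.write("values: reward\n")
    fh.write(f"states: {' '.join(_STATES)}\n")
    fh.write(f"actions: {' '.join(_ACTIONS)}\n")
    fh.write(f"observations: {' '.join(_OBS)}\n\n")
    for ai, a in enumerate(_ACTIONS):
        for si, s in enumerate(_STATES):
            for ti, t in enumerate(_STATES):
                p = tables.transition[ai, si, ti]
                fh.write(f"T: {a} : {s} : {t} {_fmt(p)}\n")
    fh.write("\n")
    for ai, a in enumerate(_ACTIONS):
        for ti, t in enumerate(_STATES):
            for oi, o in enumerate(_OBS):
                p = tables.observation[ai, ti, oi]
                fh.write(f"O: {a} : {t} : {o} {_fmt(p)}\n")
    fh.write("\n")
    for ai, a in enumerate(_ACTIONS):
        for si, s in enumerate(_STATES):
            r = tables.reward[ai, si]
            fh.write(f"R: {a} : {s} : * : * {_fmt(r)}\n")


def write_pomdp_file(agent_params: ScenarioParams, path: str | os.PathLike) -> None:
    """Export a scenario (subjective model) as a ``.pomdp`` file."""
    tables = build_tables(agent_params)
    with open(path, "w") as fh:
        _write(tables, agent_params.gamma, fh)


def read_pomdp_file(path: str | os.PathLike) -> tuple[ModelTables, float]:
    """Parse a file written by :func:`write_pomdp_file`.

    Returns the (transition, observation, reward) tables and the discount.
    """
    T = np.zeros((3, 2, 2))
    O = np.zeros((3, 2, 2))
    R = np.zeros((3, 2))
    gamma = None
    s_idx = {s: i for i, s in enumerate(_STATES)}
    a_idx = {a: i for i, a in enumerate(_ACTIONS)}
    o_idx = {o: i for i, o in enumerate(_OBS)}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("discount:"):
                gamma = float(line.split(":", 1)[1])
            elif line.startswith(("values:", "states:", "actions:", "observations:")):
                continue
            elif line.startswith("T:"):
                _, a, s, rest = (p.strip() for p in line.split(":"))
                t, p = rest.split()
                T[a_idx[a], s_idx[s], s_idx[t]] = float(p)
            elif line.startswith("O:"):
                _, a, t, rest = (p.strip() for p in line.split(":"))
                o, p = rest.split()
                O[a_idx[a], s_idx[t], o_idx[o]] = float(p)
            elif line.startswith("R:"):
                parts = [p.strip() for p in line.split(":")]
                a, s = parts[1], parts[2]
                r = float(parts[-1].split()[-1])
                R[a_idx[a], s_idx[s]] = float(r)
            else:
                raise ValueError(f"unsupported .pomdp line: {line!r}")
    if gamma is None:
        raise ValueError("no discount line found")
    return ModelTables(transition=T, observation=O, reward=R), gamma
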