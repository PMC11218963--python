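"""Exact infinite-horizon POMDP solver on the 1-D belief simplex.

With two hidden states the belief space is the interval [0, 1] and every
candidate value function is a line ("alpha-vector") over it; the optimal
value function is the upper envelope of finitely many such lines and is
convex piecewise-linear.  This module runs exact value iteration: each
Bellman backup maps a set of lines to a new set (one-step dynamic
programming under the agent's subjective tables), the upper envelope is
pruned after every sweep, and iteration stops once the Bellman residual
guarantees the greedy policy is within the requested tolerance.

For a 2-state, 3-action, 2-observation problem this is cheap and exact,
which makes the solver deterministic and easy to validate against
brute-force oracles (depth-1 expectimax, finite-horizon grid DP).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import Action, ModelTables, build_tables
from .params import ScenarioParams

__all__ = [
    "AlphaVector",
    "Policy",
    "action_value_gaps",
    "bellman_backup",
    "prune_envelope",
    "solve",
    "solve_tables",
    "policy_action",
    "policy_value",
]

#: Pointwise-dominance tolerance for envelope pruning.
DOMINANCE_TOL = 1e-12

#: Default stopping tolerance on the normalized reward scale.
DEFAULT_TOL = 1e-5

#: Default iteration cap (reached only for discounts very close to 1).
DEFAULT_MAX_ITER = 20_000

#: Tolerance of the cheap screening solve used to prove actions optimal
#: nowhere on the belief simplex before committing to a full-precision
#: solve (see :func:`action_value_gaps`).
SCREEN_TOL = 1e-2


@dataclass(frozen=True)
class AlphaVector:
    """A linear value function over the belief simplex.

    Value at belief ``b`` is ``(1 − b)·v_clean + b·v_dirty``; ``action`` is
    the greedy action this line was generated by.
    """

    v_clean: float
    v_dirty: float
    action: Action

    def value(self, b: float) -> float:
        return (1.0 - b) * self.v_clean + b * self.v_dirty


def _as_arrays(alphas) -> tuple[np.ndarray, np.ndarray]:
    vals = np.array([[a.v_clean, a.v_dirty] for a in alphas], dtype=float)
    acts = np.array([int(a.action) for a in alphas], dtype=np.int64)
    return vals, acts


def _as_alphas(vals: np.ndarray, acts: np.ndarray) -> list[AlphaVector]:
    return [
        AlphaVector(float(v[0]), float(v[1]), Action(int(a)))
        for v, a in zip(vals, acts)
    ]


@njit(cache=True)
def _hull_sweep(
    slope: np.ndarray, icept: np.ndarray, tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """Upper-envelope sweep over lines pre-sorted by (slope asc, icept desc).

    Returns positions (into the sorted order) of the envelope lines and
    their segment start points on [0, 1].
    """
    n = len(slope)
    stack = np.empty(n, dtype=np.int64)
    starts = np.empty(n, dtype=np.float64)
    top = -1
    last_m = 0.0
    have_last = False
    for i in range(n):
        if have_last and slope[i] - last_m <= tol:
            continue  # (near-)equal slope: the earlier line has higher icept
        last_m = slope[i]
        have_last = True
        x = 0.0
        while top >= 0:
            j = stack[top]
            x = (icept[j] - icept[i]) / (slope[i] - slope[j])
            if x <= starts[top]:
                top -= 1  # current top never dominates within [0, 1]
            else:
                break
        if top < 0:
            top = 0
            stack[0] = i
            starts[0] = 0.0
        elif x < 1.0:
            top += 1
            stack[top] = i
            starts[top] = x
        # else: the line only dominates beyond b = 1; drop it
    return stack[: top + 1].copy(), starts[: top + 1].copy()


def _envelope_indices(
    vals: np.ndarray, acts: np.ndarray, tol: float = DOMINANCE_TOL
) -> tuple[np.ndarray, np.ndarray]:
    """Minimal upper envelope of lines on [0, 1].

    Returns (kept indices in ascending-slope order, segment start points).
    Equal-slope groups keep the highest intercept; exact ties keep the
    lowest action index (the fixed cook < wash < check tie-break).
    """
    slope = vals[:, 1] - vals[:, 0]
    icept = vals[:, 0]
    order = np.lexsort((acts, -icept, slope))
    pos, starts = _hull_sweep(
        np.ascontiguousarray(slope[order]),
        np.ascontiguousarray(icept[order]),
        tol,
    )
    return order[pos], starts


def prune_envelope(alphas: list[AlphaVector]) -> list[AlphaVector]:
    """Minimal subset of lines whose pointwise max on [0, 1] is unchanged."""
    if not alphas:
        raise ValueError("cannot prune an empty alpha set")
    vals, acts = _as_arrays(alphas)
    kept, _ = _envelope_indices(vals, acts)
    return _as_alphas(vals[kept], acts[kept])


def _simplify_envelope(
    vals: np.ndarray, acts: np.ndarray, starts: np.ndarray, eps: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop envelope facets that improve the value function by ≤ ``eps``.

    The number of linear pieces of the exact value function grows without
    bound as value iteration refines it (facets multiply at every backup
    through the observation branch), while late facets improve the value
    only microscopically.  Removing an interior line changes the envelope
    by at most its height above the crossing of its two neighbours, so
    lines whose height is ≤ ``eps`` are removed greedily (passes repeat
    until stable).  The two extreme-slope lines — which fix the values at
    b = 0 and b = 1 — are always kept.  Inputs must be in envelope form
    (ascending slope with segment starts).
    """
    if eps <= 0.0 or len(vals) <= 2:
        return vals, acts, starts
    m = np.ascontiguousarray(vals[:, 1] - vals[:, 0])
    c = np.ascontiguousarray(vals[:, 0])
    idx, new_starts = _simplify_core(m, c, eps)
    return vals[idx], acts[idx], new_starts


@njit(cache=True)
def _simplify_core(
    m: np.ndarray, c: np.ndarray, eps: float
) -> tuple[np.ndarray, np.ndarray]:
    n = len(m)
    cur = np.arange(n)
    buf = np.empty(n, dtype=np.int64)
    changed = True
    while changed and len(cur) > 2:
        changed = False
        k = 0
        buf[k] = cur[0]
        k += 1
        for pos in range(1, len(cur) - 1):
            a = buf[k - 1]
            b = cur[pos]
            nxt = cur[pos + 1]
            x = (c[a] - c[nxt]) / (m[nxt] - m[a])
            gap = (c[b] + m[b] * x) - (c[a] + m[a] * x)
            if 0.0 <= x <= 1.0 and gap <= eps:
                changed = True  # drop line b
            else:
                buf[k] = b
                k += 1
        buf[k] = cur[len(cur) - 1]
        k += 1
        cur = buf[:k].copy()
    out_starts = np.empty(len(cur))
    out_starts[0] = 0.0
    for i in range(1, len(cur)):
        a, b = cur[i - 1], cur[i]
        out_starts[i] = (c[a] - c[b]) / (m[b] - m[a])
    return cur, out_starts


def _envelope_value(vals: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Upper-envelope values at an array of beliefs."""
    v = np.outer(1.0 - points, vals[:, 0]) + np.outer(points, vals[:, 1])
    return v.max(axis=1)


def _sorted_envelope_value(
    vals: np.ndarray, starts: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Envelope values when lines are already in envelope order with starts."""
    idx = np.maximum(np.searchsorted(starts, points, side="right") - 1, 0)
    return (1.0 - points) * vals[idx, 0] + points * vals[idx, 1]


def _sum_envelopes(
    vals_a: np.ndarray,
    starts_a: np.ndarray,
    vals_b: np.ndarray,
    starts_b: np.ndarray,
) -> np.ndarray:
    """Envelope of the Minkowski sum of two line envelopes.

    The pointwise max of a cross-sum factorizes, max(f_i + g_j) =
    max f + max g, so only sums of lines that are active on a common
    interval can appear on the envelope.
    """
    xs = np.union1d(starts_a, starts_b)
    ia = np.searchsorted(starts_a, xs, side="right") - 1
    ib = np.searchsorted(starts_b, xs, side="right") - 1
    out = vals_a[ia] + vals_b[ib]
    keep = np.ones(len(xs), dtype=bool)
    keep[1:] = (ia[1:] != ia[:-1]) | (ib[1:] != ib[:-1])
    return out[keep]


def _backup_arrays(
    vals: np.ndarray, tables: ModelTables, gamma: float, eps: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """One exact Bellman backup; returns candidate (vals, actions).

    ``eps`` > 0 simplifies the intermediate successor envelopes (see
    :func:`_simplify_envelope`), bounding the growth of the alpha set at
    an ``O(eps)`` cost in value accuracy per backup.
    """
    T, O, R = tables.transition, tables.observation, tables.reward
    out_vals = []
    out_acts = []
    zeros = np.zeros(len(vals), dtype=np.int64)
    for a in (Action.COOK, Action.WASH, Action.CHECK):
        if a is Action.CHECK:
            # observation-dependent successor: cross-sum over the two
            # back-projected envelopes (one per observation)
            g0 = vals @ (T[a] * O[a][:, 0][None, :]).T
            g1 = vals @ (T[a] * O[a][:, 1][None, :]).T
            k0, s0 = _envelope_indices(g0, zeros)
            e0, _, s0 = _simplify_envelope(g0[k0], zeros[: len(k0)], s0, eps)
            k1, s1 = _envelope_indices(g1, zeros)
            e1, _, s1 = _simplify_envelope(g1[k1], zeros[: len(k1)], s1, eps)
            future = _sum_envelopes(e0, s0, e1, s1)
        else:
            # cook/wash observations are 0.5/0.5 and share the same
            # successor set, so the cross-sum collapses to its diagonal
            proj = vals @ T[a].T
            kept, sk = _envelope_indices(proj, zeros[: len(proj)])
            future, _, _ = _simplify_envelope(
                proj[kept], zeros[: len(kept)], sk, eps
            )
        cand = R[a][None, :] + gamma * future
        out_vals.append(cand)
        out_acts.append(np.full(len(cand), int(a), dtype=np.int64))
    return np.concatenate(out_vals), np.concatenate(out_acts)


def bellman_backup(
    alphas: list[AlphaVector], agent_tables: ModelTables, gamma: float
) -> list[AlphaVector]:
    """Exact one-step dynamic-programming backup of an alpha set.

    For every action, each assignment of a successor line to each
    observation induces a candidate line; dominated assignments within an
    action are dropped eagerly (the induced upper envelope is unchanged).
    """
    if not alphas:
        raise ValueError("backup requires a non-empty alpha set")
    vals, _ = _as_arrays(alphas)
    cvals, cacts = _backup_arrays(vals, agent_tables, gamma)
    uniq, pos = np.unique(
        np.column_stack([cvals, cacts]), axis=0, return_index=True
    )
    return _as_alphas(cvals[np.sort(pos)], cacts[np.sort(pos)])


# --------------------------------------------------------------------------
# JIT value-iteration core.  The solver spends essentially all of its time
# in the backup → envelope → simplify → residual cycle, so the whole cycle
# runs inside numba on flat (v_clean, v_dirty) arrays.  Semantics mirror
# the python building blocks above (which remain the reference
# implementation for the public API and the test oracles).
# --------------------------------------------------------------------------


@njit(cache=True)
def _env_core(
    v0: np.ndarray, v1: np.ndarray, acts: np.ndarray, dom_tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """Upper envelope of lines; returns (kept indices, segment starts)."""
    n = len(v0)
    m = np.empty(n)
    c = np.empty(n)
    for i in range(n):
        m[i] = v1[i] - v0[i]
        c[i] = v0[i]
    order = np.argsort(m)
    # near-equal slope groups: keep max intercept, ties to lowest action
    sel = np.empty(n, dtype=np.int64)
    ns = 0
    i = 0
    while i < n:
        j = i
        best = order[i]
        while j + 1 < n and m[order[j + 1]] - m[order[i]] <= dom_tol:
            j += 1
            cand = order[j]
            if c[cand] > c[best] or (
                c[cand] == c[best] and acts[cand] < acts[best]
            ):
                best = cand
        sel[ns] = best
        ns += 1
        i = j + 1
    stack = np.empty(ns, dtype=np.int64)
    starts = np.empty(ns)
    top = -1
    for q in range(ns):
        idx = sel[q]
        x = 0.0
        while top >= 0:
            jdx = stack[top]
            x = (c[jdx] - c[idx]) / (m[idx] - m[jdx])
            if x <= starts[top]:
                top -= 1
            else:
                break
        if top < 0:
            top = 0
            stack[0] = idx
            starts[0] = 0.0
        elif x < 1.0:
            top += 1
            stack[top] = idx
            starts[top] = x
    return stack[: top + 1].copy(), starts[: top + 1].copy()


@njit(cache=True)
def _env_sum_core(
    a0: np.ndarray, a1: np.ndarray, sa: np.ndarray,
    b0: np.ndarray, b1: np.ndarray, sb: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Lines of the Minkowski-sum envelope of two envelopes."""
    na, nb = len(sa), len(sb)
    out0 = np.empty(na + nb)
    out1 = np.empty(na + nb)
    ia = 0
    ib = 0
    k = 0
    while True:
        out0[k] = a0[ia] + b0[ib]
        out1[k] = a1[ia] + b1[ib]
        k += 1
        nxa = sa[ia + 1] if ia + 1 < na else 2.0
        nxb = sb[ib + 1] if ib + 1 < nb else 2.0
        nx = min(nxa, nxb)
        if nx >= 1.0:
            break
        if nxa == nx:
            ia += 1
        if nxb == nx:
            ib += 1
    return out0[:k].copy(), out1[:k].copy()


@njit(cache=True)
def _eval_env_core(
    v0: np.ndarray, v1: np.ndarray, starts: np.ndarray, pts: np.ndarray
) -> np.ndarray:
    out = np.empty(len(pts))
    for i in range(len(pts)):
        idx = np.searchsorted(starts, pts[i], side="right") - 1
        if idx < 0:
            idx = 0
        out[i] = (1.0 - pts[i]) * v0[idx] + pts[i] * v1[idx]
    return out


@njit(cache=True)
def _vi_core(
    T: np.ndarray,
    O: np.ndarray,
    R: np.ndarray,
    gamma: float,
    threshold: float,
    max_iter: int,
    prune_eps: float,
    dom_tol: float,
    init_v0: np.ndarray,
    init_v1: np.ndarray,
    init_acts: np.ndarray,
    init_starts: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float, int, bool]:
    v0 = init_v0
    v1 = init_v1
    acts = init_acts
    starts = init_starts
    residual = np.inf
    it = 0
    zeros1 = np.zeros(1, dtype=np.int64)
    for it in range(1, max_iter + 1):
        n = len(v0)
        zeros = zeros1 if n == 1 else np.zeros(n, dtype=np.int64)
        # --- backup: per-action candidate lines -------------------------
        cand0 = np.empty(6 * n + 8)
        cand1 = np.empty(6 * n + 8)
        cand_acts = np.empty(6 * n + 8, dtype=np.int64)
        k = 0
        for a in range(3):
            if a == 2:
                g00 = np.empty(n)
                g01 = np.empty(n)
                g10 = np.empty(n)
                g11 = np.empty(n)
                for i in range(n):
                    # back-projections for each observation o:
                    # g_o(s) = sum_s' T[a,s,s'] O[a,s',o] alpha_i(s')
                    g00[i] = (
                        T[a, 0, 0] * O[a, 0, 0] * v0[i]
                        + T[a, 0, 1] * O[a, 1, 0] * v1[i]
                    )
                    g01[i] = (
                        T[a, 1, 0] * O[a, 0, 0] * v0[i]
                        + T[a, 1, 1] * O[a, 1, 0] * v1[i]
                    )
                    g10[i] = (
                        T[a, 0, 0] * O[a, 0, 1] * v0[i]
                        + T[a, 0, 1] * O[a, 1, 1] * v1[i]
                    )
                    g11[i] = (
                        T[a, 1, 0] * O[a, 0, 1] * v0[i]
                        + T[a, 1, 1] * O[a, 1, 1] * v1[i]
                    )
                k0, s0 = _env_core(g00, g01, zeros[: len(g00)], dom_tol)
                e00, e01 = g00[k0], g01[k0]
                if prune_eps > 0.0 and len(k0) > 2:
                    sk, s0b = _simplify_core(e01 - e00, e00, prune_eps)
                    e00, e01, s0 = e00[sk], e01[sk], s0b
                k1, s1 = _env_core(g10, g11, zeros[: len(g10)], dom_tol)
                e10, e11 = g10[k1], g11[k1]
                if prune_eps > 0.0 and len(k1) > 2:
                    sk, s1b = _simplify_core(e11 - e10, e10, prune_eps)
                    e10, e11, s1 = e10[sk], e11[sk], s1b
                f0, f1 = _env_sum_core(e00, e01, s0, e10, e11, s1)
            else:
                p0 = np.empty(n)
                p1 = np.empty(n)
                for i in range(n):
                    # proj(s) = sum_s' T[a,s,s'] alpha_i(s')
                    p0[i] = T[a, 0, 0] * v0[i] + T[a, 0, 1] * v1[i]
                    p1[i] = T[a, 1, 0] * v0[i] + T[a, 1, 1] * v1[i]
                kp, sp = _env_core(p0, p1, zeros[: len(p0)], dom_tol)
                f0, f1 = p0[kp], p1[kp]
                if prune_eps > 0.0 and len(kp) > 2:
                    sk, _ = _simplify_core(f1 - f0, f0, prune_eps)
                    f0, f1 = f0[sk], f1[sk]
            for i in range(len(f0)):
                cand0[k] = R[a, 0] + gamma * f0[i]
                cand1[k] = R[a, 1] + gamma * f1[i]
                cand_acts[k] = a
                k += 1
        cand0 = cand0[:k]
        cand1 = cand1[:k]
        cand_acts = cand_acts[:k]
        # --- envelope + simplification ----------------------------------
        kept, new_starts = _env_core(cand0, cand1, cand_acts, dom_tol)
        nv0, nv1, nacts = cand0[kept], cand1[kept], cand_acts[kept]
        if prune_eps > 0.0 and len(nv0) > 2:
            sk, new_starts = _simplify_core(nv1 - nv0, nv0, prune_eps)
            nv0, nv1, nacts = nv0[sk], nv1[sk], nacts[sk]
        # --- sup-norm residual over both breakpoint sets -----------------
        pts = np.empty(len(starts) + len(new_starts) + 1)
        pts[: len(starts)] = starts
        pts[len(starts) : len(starts) + len(new_starts)] = new_starts
        pts[-1] = 1.0
        old_at = _eval_env_core(v0, v1, starts, pts)
        new_at = _eval_env_core(nv0, nv1, new_starts, pts)
        residual = 0.0
        for i in range(len(pts)):
            diff = abs(new_at[i] - old_at[i])
            if diff > residual:
                residual = diff
        v0, v1, acts, starts = nv0, nv1, nacts, new_starts
        if residual <= threshold:
            return v0, v1, acts, starts, residual, it, True
    return v0, v1, acts, starts, residual, max_iter, False


@dataclass(frozen=True)
class Policy:
    """Solved belief-indexed policy: pruned alpha set plus greedy partition.

    ``seg_starts[i]`` is the left edge of the i-th linear piece of the value
    function (ascending, ``seg_starts[0] == 0``) and ``seg_actions[i]`` its
    greedy action.  At exact value ties — including queries landing exactly
    on a segment boundary — the lowest action index (cook < wash < check)
    wins.
    """

    alpha_vals: np.ndarray  # (n, 2) [v_clean, v_dirty], ascending slope
    alpha_actions: np.ndarray  # (n,) int
    seg_starts: np.ndarray  # (n,) left edges of greedy segments
    gamma: float
    residual: float
    iterations: int
    converged: bool
    residual_history: np.ndarray = field(default=None, repr=False)

    @property
    def alphas(self) -> list[AlphaVector]:
        return _as_alphas(self.alpha_vals, self.alpha_actions)

    def value(self, b) -> np.ndarray | float:
        b_arr = np.atleast_1d(np.asarray(b, dtype=float))
        out = _envelope_value(self.alpha_vals, b_arr)
        return float(out[0]) if np.isscalar(b) or np.ndim(b) == 0 else out

    def action_at(self, b) -> np.ndarray:
        """Vectorized greedy action lookup with the fixed tie-break."""
        b_arr = np.asarray(b, dtype=float)
        idx = np.searchsorted(self.seg_starts, b_arr, side="right") - 1
        act = self.alpha_actions[idx]
        on_edge = (idx > 0) & (b_arr == self.seg_starts[idx])
        if np.any(on_edge):
            act = np.where(
                on_edge,
                np.minimum(act, self.alpha_actions[np.maximum(idx - 1, 0)]),
                act,
            )
        return act

    def to_json(self) -> str:
        return json.dumps(
            {
                "alphas": [
                    [float(v[0]), float(v[1]), Action(int(a)).name.lower()]
                    for v, a in zip(self.alpha_vals, self.alpha_actions)
                ],
                "gamma": self.gamma,
                "residual": self.residual,
                "iterations": self.iterations,
                "converged": self.converged,
            }
        )


def solve_tables(
    tables: ModelTables,
    gamma: float,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    keep_history: bool = False,
    warm_start: Policy | None = None,
) -> Policy:
    """Value iteration on arbitrary tables until the Bellman residual bound.

    Stops when the sup-norm residual drops below ``tol·(1−γ)/(2γ)``, the
    standard bound guaranteeing the value estimate is within ``tol/2`` of
    the fixed point (for ``γ = 0`` a single backup is exact).  Reaching
    ``max_iter`` first sets ``converged=False`` and raises a warning.
    ``warm_start`` resumes iteration from a previously solved (e.g.
    coarser-tolerance) policy for the same tables; value iteration
    contracts from any starting set, so the stopping guarantee is
    unaffected.
    """
    if not 0.0 <= gamma < 1.0:
        raise ValueError(f"gamma={gamma!r} outside [0, 1)")
    threshold = np.inf if gamma < 1e-12 else tol * (1.0 - gamma) / (2.0 * gamma)
    # facet-simplification tolerance: keeps the alpha set finite while the
    # accumulated value error stays well below the stopping accuracy
    # (eps/(1−γ) ≤ tol/64 over the whole iteration) and the residual floor
    # induced by facet removal (a few × eps) stays below the threshold
    prune_eps = tol * (1.0 - gamma) / 64.0

    if warm_start is not None:
        vals = warm_start.alpha_vals
        acts = warm_start.alpha_actions
        starts = warm_start.seg_starts
    else:
        vals = np.array(
            [tables.reward[a] for a in (Action.COOK, Action.WASH, Action.CHECK)]
        )
        acts = np.array([0, 1, 2], dtype=np.int64)
        kept, starts = _envelope_indices(vals, acts)
        vals, acts = vals[kept], acts[kept]

    args = (
        np.ascontiguousarray(tables.transition),
        np.ascontiguousarray(tables.observation),
        np.ascontiguousarray(tables.reward),
        gamma,
        threshold,
    )
    v0 = np.ascontiguousarray(vals[:, 0])
    v1 = np.ascontiguousarray(vals[:, 1])
    acts = np.ascontiguousarray(acts)
    starts = np.ascontiguousarray(starts)
    if keep_history:
        # step one backup at a time so the residual trajectory is exposed
        history = []
        converged = False
        iterations = 0
        residual = np.inf
        while iterations < max_iter and not converged:
            v0, v1, acts, starts, residual, _, _ = _vi_core(
                *args, 1, prune_eps, DOMINANCE_TOL, v0, v1, acts, starts
            )
            iterations += 1
            history.append(residual)
            converged = residual <= threshold
        history_arr = np.array(history)
    else:
        v0, v1, acts, starts, residual, iterations, converged = _vi_core(
            *args, max_iter, prune_eps, DOMINANCE_TOL, v0, v1, acts, starts
        )
        history_arr = None
    if not converged:
        warnings.warn(
            f"value iteration did not reach residual {threshold:.3g} within "
            f"{max_iter} iterations (residual {residual:.3g})",
            RuntimeWarning,
        )
    return Policy(
        alpha_vals=np.column_stack([v0, v1]),
        alpha_actions=acts,
        seg_starts=starts,
        gamma=gamma,
        residual=float(residual),
        iterations=int(iterations),
        converged=bool(converged),
        residual_history=history_arr,
    )


def solve(
    agent_params: ScenarioParams,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    keep_history: bool = False,
) -> Policy:
    """Solve the scenario under one (subjective) parameter set."""
    return solve_tables(
        build_tables(agent_params),
        agent_params.gamma,
        tol=tol,
        max_iter=max_iter,
        keep_history=keep_history,
    )


def action_value_gaps(policy: Policy, tables: ModelTables) -> np.ndarray:
    """Per-action optimality gaps, max over the belief simplex.

    ``gaps[a] = max_b (Q_a(b) − V(b))`` where Q is one exact backup of the
    policy's value function.  An action with ``gaps[a] < −(1 + γ)·tol/2 −
    tol/2`` under a policy solved to accuracy ``tol/2`` is provably never
    greedy under the exact optimum; in practice ``gaps[a] < −tol`` is used
    as the screening criterion.  Gaps are 0 (up to pruning tolerance) for
    actions on the current greedy envelope.
    """
    cvals, cacts = _backup_arrays(
        policy.alpha_vals, tables, policy.gamma
    )
    kept_all, starts_all = _envelope_indices(cvals, cacts)
    env_vals, env_starts = cvals[kept_all], starts_all
    gaps = np.empty(3)
    for a in (Action.COOK, Action.WASH, Action.CHECK):
        sel = cacts == int(a)
        avals = cvals[sel]
        kept_a, starts_a = _envelope_indices(
            avals, np.zeros(len(avals), dtype=np.int64)
        )
        pts = np.concatenate([env_starts, starts_a, [1.0]])
        gaps[int(a)] = float(
            np.max(
                _sorted_envelope_value(avals[kept_a], starts_a, pts)
                - _sorted_envelope_value(env_vals, env_starts, pts)
            )
        )
    return gaps


def policy_action(policy: Policy, b: float) -> Action:
    """Greedy action at belief ``b`` (deterministic tie-break)."""
    if not 0.0 <= b <= 1.0:
        raise ValueError(f"belief {b!r} outside [0, 1]")
    return Action(int(policy.action_at(np.float64(b))))


def policy_value(policy: Policy, b: float) -> float:
    """Envelope value at belief ``b``."""
    if not 0.0 <= b <= 1.0:
        raise ValueError(f"belief {b!r} outside [0, 1]")
    return float(_envelope_value(policy.alpha_vals, np.array([b]))[0])
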