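"""End-to-end recomputation of the headline group-level quantities.

Runs the full pipeline — world-bank construction, Simulation 1A and 1B,
bootstrapped statistics — at a chosen scale and returns the key
group-level numbers: the Δp_SUCCESS group means and effect size, post-wash
belief-update amplitudes, uncertainty tolerance at cook decisions, action
repetition/transition probabilities, and the pure-washing compulsion-type
shares.  Every value is computed from freshly simulated agents; nothing is
cached or looked up.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .experiments import ExperimentDataset, run_simulation1
from .sampling import WorldBank, build_world_bank
from .stats import BootstrapConfig, bootstrap_spearman, bootstrap_test

__all__ = ["headline_results", "run_pipeline"]


def run_pipeline(
    config: RunConfig,
) -> tuple[WorldBank, ExperimentDataset, ExperimentDataset]:
    """World bank plus Simulation 1A and 1B datasets for one configuration."""
    sim = config.sim_config()
    bank = build_world_bank(
        n=config.n_worlds,
        seed=config.seed,
        config=sim,
        tol=config.solver_tol,
        max_iter=config.solver_max_iter,
    )
    common = dict(
        world_bank=bank,
        quota=config.quota,
        config=sim,
        tol=config.solver_tol,
        max_iter=config.solver_max_iter,
    )
    # distinct seed offsets keep the two designs' agent streams independent
    ds_1a = run_simulation1("1A", seed=config.seed + 1, **common)
    ds_1b = run_simulation1("1B", seed=config.seed + 2, **common)
    return bank, ds_1a, ds_1b


def _group_mean(records, group: str, column: str) -> tuple[float, int]:
    sel = records.loc[records["group"] == group, column].to_numpy(dtype=float)
    sel = sel[np.isfinite(sel)]
    return float(sel.mean()), int(len(sel))


def _pure_wash_pct(dataset: ExperimentDataset) -> tuple[float, int]:
    comp = dataset.records[dataset.records["is_compulsive"]]
    if len(comp) == 0:
        return float("nan"), 0
    share = (comp["compulsion_type"] == "pure_wash").mean()
    return 100.0 * float(share), int(len(comp))


def headline_results(seed: int, scale: str = "desk") -> dict[str, dict]:
    """Recompute the headline quantities at the requested scale.

    Returns a mapping of descriptive names to ``{"value": ..., "n": ...}``
    records, where ``n`` is the number of agents the value was computed
    over.  Percentages are on the 0–100 scale.
    """
    config = RunConfig.from_preset(scale, seed=seed)
    _, ds_1a, ds_1b = run_pipeline(config)
    rec = ds_1a.records
    boot = BootstrapConfig(reps=config.bootstrap_reps)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 9001])
    )

    out: dict[str, dict] = {}

    def put(name: str, value: float, n: int) -> None:
        out[name] = {"value": float(value), "n": int(n)}

    # belief about washing effectiveness: Δp_SUCCESS by group
    v, n = _group_mean(rec, "compulsive", "d_p_success")
    put("d_p_success_mean_compulsive", v, n)
    v, n = _group_mean(rec, "non_compulsive", "d_p_success")
    put("d_p_success_mean_noncompulsive", v, n)

    xc = rec.loc[rec["group"] == "compulsive", "d_p_success"].to_numpy(float)
    xn = rec.loc[rec["group"] == "non_compulsive", "d_p_success"].to_numpy(float)
    two = bootstrap_test(xc, xn, config=boot, rng=rng)
    put("d_p_success_cohens_d", abs(two.d), len(xc) + len(xn))

    # belief updating after wash actions
    v, n = _group_mean(rec, "non_compulsive", "belief_update_after_wash")
    put("belief_update_after_wash_noncompulsive", v, n)
    v, n = _group_mean(rec, "compulsive", "belief_update_after_wash")
    put("belief_update_after_wash_compulsive", v, n)

    upd = rec["belief_update_after_wash"].to_numpy(float)
    dps = rec["d_p_success"].to_numpy(float)
    keep = np.isfinite(upd) & np.isfinite(dps)
    sp = bootstrap_spearman(upd[keep], dps[keep], config=boot, rng=rng)
    put("spearman_wash_update_vs_d_p_success", sp.statistic, int(keep.sum()))

    # uncertainty tolerance: belief in clean hands when choosing to cook
    v, n = _group_mean(rec, "compulsive", "b_clean_at_cook")
    put("pct_clean_at_cook_compulsive", 100.0 * v, n)
    v, n = _group_mean(rec, "non_compulsive", "b_clean_at_cook")
    put("pct_clean_at_cook_noncompulsive", 100.0 * v, n)

    # action-transition structure
    v, n = _group_mean(rec, "compulsive", "p_check_check")
    put("p_check_check_compulsive", v, n)
    v, n = _group_mean(rec, "non_compulsive", "p_wash_cook")
    put("p_wash_cook_noncompulsive", v, n)

    # compulsion-type split
    v, n = _pure_wash_pct(ds_1b)
    put("pct_pure_wash_sim1b", v, n)
    v, n = _pure_wash_pct(ds_1a)
    put("pct_pure_wash_sim1a", v, n)
    return out
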