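"""Bootstrapped group statistics for the simulated-agent datasets.

Simulated samples are large (thousands of agents), so conventional tests
would declare microscopic effects significant.  Following the study design
all tests are therefore *bootstrapped*: small subsamples (n = 20 for
one-sample tests, 20 + 20 for two-sample tests, 40 for correlations) are
drawn repeatedly, the standard test is applied to each subsample, and the
statistics and p-values are averaged across repetitions (medians for the
non-parametric tests).  Normality is screened with a bootstrapped
Shapiro–Wilk test; when it fails, the Wilcoxon–Mann–Whitney U replaces the
t-test.  Cohen's d (pooled SD) is computed per repetition and averaged;
the full-sample d is reported alongside for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "bootstrap_test",
    "bootstrap_spearman",
    "table2_summary",
    "severity_curves",
    "compulsion_type_breakdown",
    "DELTA_COLUMNS",
]

#: The eight belief-distortion columns analysed in the group table.
DELTA_COLUMNS = (
    "d_gamma",
    "d_cost_wash",
    "d_p_success",
    "d_cost_check",
    "d_p_detect_dirty",
    "d_p_detect_clean",
    "d_cost_sickness",
    "d_p_soiling",
)


@dataclass(frozen=True)
class BootstrapConfig:
    """Subsample sizes and repetition count of the bootstrap scheme."""

    n_one_sample: int = 20
    n_two_sample: int = 20  # per group (2 × 20)
    n_corr: int = 40
    reps: int = 10_000
    alpha: float = 0.05
    with_replacement: bool = False

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be ≥ 1")
        if min(self.n_one_sample, self.n_two_sample, self.n_corr) < 3:
            raise ValueError("subsample sizes must be ≥ 3")


@dataclass(frozen=True)
class BootstrapResult:
    """Averaged outcome of one bootstrapped test."""

    statistic: float
    p: float
    d: float
    test: str  # "t" | "u" | "wilcoxon" | "spearman"
    d_full: float | None = None
    reps_used: int = 0
    reps_skipped: int = 0


def _subsample_indices(
    rng: np.random.Generator, pool: int, n: int, reps: int, replace: bool
) -> np.ndarray:
    """(reps, n) index matrix; rows are independent subsamples."""
    if replace:
        return rng.integers(0, pool, size=(reps, n))
    if n > pool:
        raise ValueError(f"subsample size {n} exceeds pool size {pool}")
    u = rng.random((reps, pool))
    return np.argpartition(u, n - 1, axis=1)[:, :n]


def _shapiro_gate(
    x: np.ndarray, n: int, reps: int, alpha: float, rng: np.random.Generator,
    replace: bool,
) -> bool:
    """True if the bootstrapped Shapiro–Wilk flags non-normality.

    The same (n, reps) subsampling scheme is applied and the median p
    compared to ``alpha``.  The repetition count is capped — the gate is a
    screen, not an estimate, and the median stabilises quickly.
    """
    gate_reps = min(reps, 500)
    idx = _subsample_indices(rng, len(x), n, gate_reps, replace)
    ps = np.empty(gate_reps)
    for i in range(gate_reps):
        sample = x[idx[i]]
        if np.ptp(sample) == 0.0:
            ps[i] = 0.0  # degenerate: certainly not Gaussian
            continue
        ps[i] = sps.shapiro(sample).pvalue
    return float(np.median(ps)) < alpha


def _one_sample(
    x: np.ndarray, config: BootstrapConfig, rng: np.random.Generator
) -> BootstrapResult:
    n = config.n_one_sample
    nonparam = _shapiro_gate(
        x, n, config.reps, config.alpha, rng, config.with_replacement
    )
    idx = _subsample_indices(
        rng, len(x), n, config.reps, config.with_replacement
    )
    xs = x[idx]
    sd = xs.std(axis=1, ddof=1)
    ok = sd > 0
    skipped = int(np.count_nonzero(~ok))
    mean = xs.mean(axis=1)
    d_reps = np.where(ok, mean / np.where(ok, sd, 1.0), np.nan)
    if not nonparam:
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * sps.t.sf(np.abs(t[ok]), df=n - 1)
        full_sd = x.std(ddof=1)
        return BootstrapResult(
            statistic=float(np.mean(t[ok])),
            p=float(np.mean(p)),
            d=float(np.nanmean(d_reps)),
            test="t",
            d_full=float(x.mean() / full_sd) if full_sd > 0 else np.nan,
            reps_used=int(np.count_nonzero(ok)),
            reps_skipped=skipped,
        )
    stats_w = np.full(config.reps, np.nan)
    ps = np.full(config.reps, np.nan)
    for i in np.flatnonzero(ok):
        sample = xs[i]
        sample = sample[sample != 0.0]
        if len(sample) < 3:
            ps[i] = np.nan
            continue
        res = sps.wilcoxon(sample)
        stats_w[i], ps[i] = res.statistic, res.pvalue
    used = int(np.count_nonzero(np.isfinite(ps)))
    full_sd = x.std(ddof=1)
    return BootstrapResult(
        statistic=float(np.nanmedian(stats_w)),
        p=float(np.nanmedian(ps)),
        d=float(np.nanmean(d_reps)),
        test="wilcoxon",
        d_full=float(x.mean() / full_sd) if full_sd > 0 else np.nan,
        reps_used=used,
        reps_skipped=config.reps - used,
    )


def _two_sample(
    x: np.ndarray, y: np.ndarray, config: BootstrapConfig,
    rng: np.random.Generator,
) -> BootstrapResult:
    n = config.n_two_sample
    nonparam = _shapiro_gate(
        x, n, config.reps, config.alpha, rng, config.with_replacement
    ) or _shapiro_gate(
        y, n, config.reps, config.alpha, rng, config.with_replacement
    )
    ix = _subsample_indices(rng, len(x), n, config.reps, config.with_replacement)
    iy = _subsample_indices(rng, len(y), n, config.reps, config.with_replacement)
    xs, ys = x[ix], y[iy]
    mx, my = xs.mean(axis=1), ys.mean(axis=1)
    vx, vy = xs.var(axis=1, ddof=1), ys.var(axis=1, ddof=1)
    sp = np.sqrt((vx + vy) / 2.0)  # pooled SD, equal group sizes
    ok = sp > 0
    skipped = int(np.count_nonzero(~ok))
    d_reps = np.where(ok, (mx - my) / np.where(ok, sp, 1.0), np.nan)
    pooled_full = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2.0)
    d_full = float((x.mean() - y.mean()) / pooled_full) if pooled_full > 0 else np.nan
    if not nonparam:
        se = sp * np.sqrt(2.0 / n)
        t = np.where(ok, (mx - my) / np.where(ok, se, 1.0), np.nan)
        p = 2.0 * sps.t.sf(np.abs(t[ok]), df=2 * n - 2)
        return BootstrapResult(
            statistic=float(np.nanmean(t[ok])),
            p=float(np.mean(p)),
            d=float(np.nanmean(d_reps)),
            test="t",
            d_full=d_full,
            reps_used=int(np.count_nonzero(ok)),
            reps_skipped=skipped,
        )
    stats_u = np.full(config.reps, np.nan)
    ps = np.full(config.reps, np.nan)
    for i in range(config.reps):
        try:
            res = sps.mannwhitneyu(xs[i], ys[i])
        except ValueError:
            continue
        stats_u[i], ps[i] = res.statistic, res.pvalue
    used = int(np.count_nonzero(np.isfinite(ps)))
    return BootstrapResult(
        statistic=float(np.nanmedian(stats_u)),
        p=float(np.nanmedian(ps)),
        d=float(np.nanmean(d_reps)),
        test="u",
        d_full=d_full,
        reps_used=used,
        reps_skipped=config.reps - used,
    )


def bootstrap_test(
    x,
    y=None,
    config: BootstrapConfig | None = None,
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Bootstrapped one-sample (vs 0) or two-sample location test.

    Each repetition draws a fresh small subsample (without replacement by
    default), applies a t-test — or a Wilcoxon signed-rank /
    Wilcoxon–Mann–Whitney U when the bootstrapped Shapiro–Wilk screen
    rejects normality — and the statistics, p-values and Cohen's d are
    averaged across repetitions (medians for the non-parametric branch).
    """
    config = config or BootstrapConfig()
    rng = rng if rng is not None else np.random.default_rng()
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if y is None:
        return _one_sample(x, config, rng)
    y = np.asarray(y, dtype=float)
    y = y[np.isfinite(y)]
    return _two_sample(x, y, config, rng)


def bootstrap_spearman(
    x,
    y,
    config: BootstrapConfig | None = None,
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Bootstrapped Spearman rank correlation on paired samples.

    Repeatedly subsamples ``n_corr`` pairs, ranks within the subsample and
    computes ρ with the usual t-approximation p-value; mean ρ and mean p
    across repetitions are reported.
    """
    config = config or BootstrapConfig()
    rng = rng if rng is not None else np.random.default_rng()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (same length)")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    n = config.n_corr
    idx = _subsample_indices(rng, len(x), n, config.reps, config.with_replacement)
    xr = sps.rankdata(x[idx], axis=1)
    yr = sps.rankdata(y[idx], axis=1)
    xr = xr - xr.mean(axis=1, keepdims=True)
    yr = yr - yr.mean(axis=1, keepdims=True)
    denom = np.sqrt((xr**2).sum(axis=1) * (yr**2).sum(axis=1))
    ok = denom > 0
    rho = np.full(config.reps, np.nan)
    rho[ok] = (xr * yr).sum(axis=1)[ok] / denom[ok]
    r = np.clip(rho[ok], -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    return BootstrapResult(
        statistic=float(np.nanmean(rho)),
        p=float(np.mean(p)),
        d=np.nan,
        test="spearman",
        reps_used=int(np.count_nonzero(ok)),
        reps_skipped=int(np.count_nonzero(~ok)),
    )


def table2_summary(
    dataset,
    config: BootstrapConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Group comparison of all eight belief distortions.

    For each Δ parameter: per-group mean (SD), bootstrapped one-sample
    test against 0 (no distortion), and the bootstrapped two-sample
    comparison with Cohen's d.  Expects a Simulation 1 dataset with both
    groups present.
    """
    config = config or BootstrapConfig()
    rng = rng if rng is not None else np.random.default_rng()
    records = dataset.records if hasattr(dataset, "records") else dataset
    comp = records[records["group"] == "compulsive"]
    nonc = records[records["group"] == "non_compulsive"]
    if len(comp) == 0 or len(nonc) == 0:
        raise ValueError("dataset must contain both groups")
    rows = []
    for col in DELTA_COLUMNS:
        xc = comp[col].to_numpy(dtype=float)
        xn = nonc[col].to_numpy(dtype=float)
        one_n = bootstrap_test(xn, config=config, rng=rng)
        one_c = bootstrap_test(xc, config=config, rng=rng)
        two = bootstrap_test(xc, xn, config=config, rng=rng)
        rows.append(
            {
                "parameter": col,
                "noncompulsive_mean": xn.mean(),
                "noncompulsive_sd": xn.std(ddof=1),
                "noncompulsive_p": one_n.p,
                "noncompulsive_test": one_n.test,
                "compulsive_mean": xc.mean(),
                "compulsive_sd": xc.std(ddof=1),
                "compulsive_p": one_c.p,
                "compulsive_test": one_c.test,
                "cohens_d": two.d,
                "cohens_d_full": two.d_full,
                "group_p": two.p,
                "group_test": two.test,
            }
        )
    return pd.DataFrame(rows)


_SEVERITY_METRICS = (
    "n_episodes_mean",
    "episode_duration_mean",
    "pct_actions_compulsive",
    "belief_update_after_wash",
)


def severity_curves(
    dataset, delta: str = "d_p_success", bin_width: float = 0.1
) -> pd.DataFrame:
    """Severity metrics binned along one belief-distortion axis.

    Bins span [−1, 1].  Per bin: agent count, percent compulsive, and the
    mean of each severity metric (NaN-aware; empty bins reported with NaN).
    """
    records = dataset.records if hasattr(dataset, "records") else dataset
    edges = np.arange(-1.0, 1.0 + bin_width / 2, bin_width)
    x = records[delta].to_numpy(dtype=float)
    which = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
    rows = []
    for i in range(len(edges) - 1):
        sel = records[which == i]
        row = {
            "bin_left": edges[i],
            "bin_right": edges[i + 1],
            "bin_center": (edges[i] + edges[i + 1]) / 2.0,
            "n_agents": len(sel),
            "pct_compulsive": (
                100.0 * sel["is_compulsive"].mean() if len(sel) else np.nan
            ),
        }
        for m in _SEVERITY_METRICS:
            row[f"mean_{m}"] = (
                float(np.nanmean(sel[m].to_numpy(dtype=float)))
                if len(sel) and np.isfinite(sel[m]).any()
                else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def compulsion_type_breakdown(dataset) -> tuple[pd.Series, pd.DataFrame]:
    """Compulsion-type shares and subjective-cost simplex coordinates.

    Returns the proportion of compulsive agents classified pure_wash /
    pure_check / mixed, and a per-agent table of normalized subjective
    cost coordinates (|cost′_check|, |cost′_wash|, |cost′_sickness|, which
    sum to 1) with the agent's type — the simplex scatter behind the
    type-vs-cost analysis.
    """
    records = dataset.records if hasattr(dataset, "records") else dataset
    comp = records[records["is_compulsive"]]
    if len(comp):
        shares = (
            comp["compulsion_type"]
            .value_counts(normalize=True)
            .reindex(["pure_wash", "pure_check", "mixed"], fill_value=0.0)
        )
    else:
        shares = pd.Series(
            0.0, index=["pure_wash", "pure_check", "mixed"], name="proportion"
        )
    coords = pd.DataFrame(
        {
            "z_check": records["agent_cost_check"].abs(),
            "z_wash": records["agent_cost_wash"].abs(),
            "z_sickness": records["agent_cost_sickness"].abs(),
            "compulsion_type": records["compulsion_type"],
            "group": records["group"],
        }
    )
    return shares, coords
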