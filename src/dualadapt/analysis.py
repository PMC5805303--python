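"""Learning-curve and aftereffect analysis with the accompanying statistics.

Training measures are averaged over non-overlapping blocks of 5 trials (one
movement to each target per block). Learning extent and rate are probed at
three milestones — the very first trial, the second block (trials 6-10), and
the final block — and summarized by a single exponential fit to the blocked
series,

    RD(x) = b * exp(-a * x) + c

with block number ``x``, learning rate ``a``, asymptote ``c`` and scaling
factor ``b``. Reach aftereffects are the open-loop (no-cursor) reach errors
after rotated training minus the aligned-baseline no-cursor errors.

The statistical battery mirrors a standard mixed design: 3 (milestone) x 2
(group) mixed ANOVA, one-way repeated-measures ANOVAs within group, one-way
between-groups ANOVA on aftereffects, and Bonferroni-corrected post-hoc
t-tests at alpha = .05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "BlockSeries",
    "Milestones",
    "AftereffectResult",
    "ExpFitResult",
    "TTestResult",
    "FTestResult",
    "block_means",
    "milestones",
    "aftereffect",
    "fit_exponential",
    "bonferroni",
    "ttest_independent",
    "ttest_paired",
    "anova_oneway_between",
    "anova_oneway_rm",
    "anova_mixed",
    "stats_battery",
    "plot_learning_curve",
    "plot_aftereffects",
]

BLOCK_SIZE = 5
ALPHA = 0.05


@dataclass
class BlockSeries:
    """Block means of a per-trial measure; ``x`` is the 1-based block number."""

    name: str
    block_size: int
    block_means: np.ndarray
    x: np.ndarray


@dataclass(frozen=True)
class Milestones:
    first_trial_value: float
    second_block_mean: float
    final_block_mean: float


@dataclass
class AftereffectResult:
    """Rotated-minus-aligned no-cursor reach errors (deg)."""

    per_unit_values: np.ndarray
    mean_deg: float
    sem_deg: float


@dataclass
class ExpFitResult:
    a: float
    b: float
    c: float
    rss: float
    converged: bool

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.b * np.exp(-self.a * np.asarray(x, dtype=float)) + self.c


@dataclass(frozen=True)
class TTestResult:
    t: float
    dof: float
    p: float
    p_adjusted: float | None = None


@dataclass(frozen=True)
class FTestResult:
    F: float
    dof_num: float
    dof_den: float
    p: float


def block_means(series: Sequence[float], block_size: int = BLOCK_SIZE, name: str = "measure") -> BlockSeries:
    """Non-overlapping consecutive block means, order preserved."""
    values = np.asarray(series, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise ValueError("series must be a non-empty 1-D sequence")
    if len(values) % block_size:
        raise ValueError(
            f"series length {len(values)} not divisible by block size {block_size}"
        )
    means = values.reshape(-1, block_size).mean(axis=1)
    return BlockSeries(name, block_size, means, np.arange(1, len(means) + 1))


def milestones(series: Sequence[float], block_size: int = BLOCK_SIZE) -> Milestones:
    """(first trial raw value, second-block mean, final-block mean)."""
    values = np.asarray(series, dtype=float)
    if len(values) < 2 * block_size:
        raise ValueError("need at least two blocks of trials")
    return Milestones(
        first_trial_value=float(values[0]),
        second_block_mean=float(values[block_size : 2 * block_size].mean()),
        final_block_mean=float(values[-block_size:].mean()),
    )


def aftereffect(
    nc_rotated: Sequence[Sequence[float]],
    nc_aligned: Sequence[Sequence[float]],
    baseline: str = "final",
    block_size: int = BLOCK_SIZE,
) -> AftereffectResult:
    """Per-participant reach aftereffects and their group mean +/- SEM.

    For each participant: mean of the first block of no-cursor errors after
    rotated training minus the mean of the aligned-baseline no-cursor block
    (``baseline="final"`` uses the final aligned block, ``"first"`` the first
    one).
    """
    if baseline not in ("final", "first"):
        raise ValueError("baseline must be 'final' or 'first'")
    if len(nc_rotated) != len(nc_aligned) or len(nc_rotated) == 0:
        raise ValueError("need matched, non-empty per-participant series")
    values = []
    for rot, ali in zip(nc_rotated, nc_aligned):
        rot = np.asarray(rot, dtype=float)
        ali = np.asarray(ali, dtype=float)
        if len(rot) < block_size or len(ali) < block_size:
            raise ValueError("each phase needs at least one full block")
        base = ali[-block_size:] if baseline == "final" else ali[:block_size]
        values.append(rot[:block_size].mean() - base.mean())
    values = np.asarray(values)
    sem = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else float("nan")
    return AftereffectResult(values, float(values.mean()), sem)


def fit_exponential(
    blocks: BlockSeries | Sequence[float],
    x: Sequence[float] | None = None,
    init: tuple[float, float, float] | None = None,
    bounds: tuple[Sequence[float], Sequence[float]] | None = None,
) -> ExpFitResult:
    """Bounded least-squares fit of ``b * exp(-a x) + c`` to block means.

    Defaults: initial ``a = 0.1``, ``b = first - last`` block value,
    ``c = last`` block value; bounds ``a`` in [0, 5], ``b`` and ``c``
    unbounded (tracking-error fits can be negative).
    """
    if isinstance(blocks, BlockSeries):
        y = np.asarray(blocks.block_means, dtype=float)
        xv = np.asarray(blocks.x, dtype=float)
    else:
        y = np.asarray(blocks, dtype=float)
        xv = np.arange(1, len(y) + 1, dtype=float) if x is None else np.asarray(x, dtype=float)
    if len(y) < 4:
        raise ValueError("need at least 4 blocks to fit 3 parameters")
    if not (np.isfinite(y).all() and np.isfinite(xv).all()):
        raise ValueError("non-finite inputs")
    p0 = np.asarray(init if init is not None else (0.1, y[0] - y[-1], y[-1]), dtype=float)
    lo, hi = bounds if bounds is not None else ((0.0, -np.inf, -np.inf), (5.0, np.inf, np.inf))
    p0 = np.clip(p0, lo, hi)

    def resid(p):
        return p[1] * np.exp(-p[0] * xv) + p[2] - y

    def jac(p):
        e = np.exp(-p[0] * xv)
        return np.column_stack([-p[1] * xv * e, e, np.ones_like(xv)])

    sol = optimize.least_squares(
        resid, p0, jac=jac, bounds=(lo, hi), xtol=1e-10, ftol=1e-12, gtol=1e-12
    )
    return ExpFitResult(
        a=float(sol.x[0]),
        b=float(sol.x[1]),
        c=float(sol.x[2]),
        rss=float(2 * sol.cost),
        converged=bool(sol.success),
    )


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def bonferroni(p: float | Sequence[float], n_comparisons: int) -> float | np.ndarray:
    """Bonferroni adjustment: multiply by the comparison count, cap at 1."""
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    adj = np.minimum(np.asarray(p, dtype=float) * n_comparisons, 1.0)
    return float(adj) if np.isscalar(p) else adj


def _check_group(x, min_n=2):
    x = np.asarray(x, dtype=float)
    if len(x) < min_n:
        raise ValueError(f"group size must be >= {min_n}")
    return x


def _degenerate_zero_effect(t: float, effect: float) -> tuple[float, float] | None:
    # 0/0 from zero effect with zero variance: no evidence against the null
    if np.isnan(t) and np.isclose(effect, 0.0):
        return 0.0, 1.0
    return None


def ttest_independent(x, y) -> TTestResult:
    x, y = _check_group(x), _check_group(y)
    res = stats.ttest_ind(x, y)
    t, p = float(res.statistic), float(res.pvalue)
    fix = _degenerate_zero_effect(t, float(np.mean(x) - np.mean(y)))
    if fix:
        t, p = fix
    return TTestResult(t, float(len(x) + len(y) - 2), p)


def ttest_paired(x, y) -> TTestResult:
    x, y = _check_group(x), _check_group(y)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    res = stats.ttest_rel(x, y)
    t, p = float(res.statistic), float(res.pvalue)
    fix = _degenerate_zero_effect(t, float(np.mean(x - y)))
    if fix:
        t, p = fix
    return TTestResult(t, float(len(x) - 1), p)


def ttest_onesample(x, popmean: float = 0.0) -> TTestResult:
    x = _check_group(x)
    res = stats.ttest_1samp(x, popmean)
    return TTestResult(float(res.statistic), float(len(x) - 1), float(res.pvalue))


def anova_oneway_between(*groups) -> FTestResult:
    groups = [_check_group(g) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    res = stats.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    return FTestResult(float(res.statistic), float(k - 1), float(n - k), float(res.pvalue))


def anova_oneway_rm(data: np.ndarray) -> FTestResult:
    """One-way repeated-measures ANOVA on a (subjects x levels) array."""
    from statsmodels.stats.anova import AnovaRM

    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need a (subjects >= 2) x (levels >= 2) array")
    n, k = data.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "level": np.tile(np.arange(k), n),
            "value": data.ravel(),
        }
    )
    row = AnovaRM(long, depvar="value", subject="subject", within=["level"]).fit().anova_table.iloc[0]
    return FTestResult(
        float(row["F Value"]), float(row["Num DF"]), float(row["Den DF"]), float(row["Pr > F"])
    )


def anova_mixed(df: pd.DataFrame, dv="value", within="level", between="group", subject="subject") -> dict[str, FTestResult]:
    """Mixed ANOVA (within x between); returns the three effect F-tests."""
    import pingouin as pg

    for col in (dv, within, between, subject):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    counts = df.groupby([subject])[within].nunique()
    if counts.nunique() != 1:
        raise ValueError("unbalanced repeated measures")
    aov = pg.mixed_anova(data=df, dv=dv, within=within, between=between, subject=subject)
    pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
    out = {}
    for _, row in aov.iterrows():
        out[str(row["Source"])] = FTestResult(
            float(row["F"]), float(row["DF1"]), float(row["DF2"]), float(row[pcol])
        )
    return out


def stats_battery(
    milestone_table: pd.DataFrame | None = None,
    aftereffect_table: pd.DataFrame | None = None,
) -> dict:
    """The full test battery on tidy per-participant tables.

    ``milestone_table`` columns: participant, group, milestone (first_trial /
    second_block / final_block), value. ``aftereffect_table`` columns:
    participant, group, value. Post-hoc p values are Bonferroni-adjusted.
    """
    results: dict = {}
    if milestone_table is not None:
        mt = milestone_table
        groups = sorted(mt["group"].unique())
        if len(groups) == 2:
            results["mixed_anova"] = anova_mixed(
                mt, dv="value", within="milestone", between="group", subject="participant"
            )
            # between-group post-hocs at each milestone
        posthoc = {}
        levels = ["first_trial", "second_block", "final_block"]
        if len(groups) == 2:
            for lev in levels:
                a = mt.query("group == @groups[0] and milestone == @lev")["value"]
                b = mt.query("group == @groups[1] and milestone == @lev")["value"]
                res = ttest_independent(a, b)
                posthoc[lev] = TTestResult(res.t, res.dof, res.p, bonferroni(res.p, len(levels)))
            results["posthoc_between"] = posthoc
        results["rm_anova_by_group"] = {}
        for g in groups:
            wide = (
                mt[mt["group"] == g]
                .pivot(index="participant", columns="milestone", values="value")
                .reindex(columns=levels)
                .to_numpy()
            )
            results["rm_anova_by_group"][g] = anova_oneway_rm(wide)
    if aftereffect_table is not None:
        at = aftereffect_table
        groups = sorted(at["group"].unique())
        series = [at[at["group"] == g]["value"].to_numpy() for g in groups]
        if len(groups) >= 2:
            results["aftereffect_anova"] = anova_oneway_between(*series)
            n_pairs = len(groups) * (len(groups) - 1) // 2
            pairwise = {}
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    res = ttest_independent(series[i], series[j])
                    pairwise[f"{groups[i]}_vs_{groups[j]}"] = TTestResult(
                        res.t, res.dof, res.p, bonferroni(res.p, n_pairs)
                    )
            results["aftereffect_pairwise"] = pairwise
        results["aftereffect_vs_zero"] = {
            g: ttest_onesample(s) for g, s in zip(groups, series)
        }
    return results


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------

def plot_learning_curve(
    blocks_by_group: dict[str, BlockSeries],
    fits_by_group: dict[str, ExpFitResult] | None = None,
    ylabel: str = "angular error (deg)",
    path=None,
):
    """Blocked learning curves with fitted exponential overlays."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, bs in blocks_by_group.items():
        ax.plot(bs.x, bs.block_means, "o-", ms=3, label=name)
        if fits_by_group and name in fits_by_group:
            xx = np.linspace(bs.x[0], bs.x[-1], 200)
            ax.plot(xx, fits_by_group[name].predict(xx), "r--", lw=1)
    ax.set_xlabel("block (5 trials)")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_aftereffects(results: dict[str, AftereffectResult], path=None):
    """Aftereffect bars with per-participant points and SEM error bars."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    names = list(results)
    for i, name in enumerate(names):
        r = results[name]
        ax.bar(i, r.mean_deg, width=0.6, alpha=0.6)
        ax.errorbar(i, r.mean_deg, yerr=r.sem_deg, fmt="none", ecolor="k", capsize=4)
        jitter = (np.arange(len(r.per_unit_values)) / max(len(r.per_unit_values) - 1, 1) - 0.5) * 0.3
        ax.plot(i + jitter, r.per_unit_values, "ko", ms=3, alpha=0.5)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xticks(range(len(names)), names)
    ax.set_ylabel("reach aftereffect (deg)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
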