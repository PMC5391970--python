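"""Statistics for the downstream validation experiments.

Covers the fly eye modifier screen (one-way ANOVA with Holm-Sidak
adjusted pairwise comparisons against the disease-model control, and
suppressor/enhancer calling), neuromuscular-junction endplate occupancy
(percentages and Mann-Whitney comparison), body-weight comparison
(Student's t) and survival (Kaplan-Meier curves, median survival and the
Mantel-Cox log-rank test).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ModifierCall:
    """Suppressor/enhancer call for one fly line.

    A suppressor increases mean eye area relative to the disease-model
    control; an enhancer decreases it; either requires Holm-Sidak
    adjusted significance.
    """

    line_id: str
    mean_area: float
    adjusted_p: float
    call: str  # suppressor | enhancer | no_effect


@dataclass
class SurvivalSummary:
    """Two-group Kaplan-Meier comparison.

    ``curves`` maps group -> DataFrame(time, at_risk, survival).
    ``medians`` uses the first time S(t) <= 0.5; a group in which no
    death is observed has an undefined median (NaN, flagged).
    """

    curves: dict[str, pd.DataFrame]
    medians: dict[str, float]
    median_defined: dict[str, bool]
    percent_change: float
    logrank_chi2: float
    logrank_p: float


def holm_sidak_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, in input order.

    Sorted ascending, adjusted_(i) = max_{j <= i} 1 - (1 - p_(j))^(m-j+1),
    clipped at 1.
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm-sidak")[1]


def anova_holm_sidak(
    areas: Mapping[str, Sequence[float]], control: str, alpha: float = 0.05
) -> pd.DataFrame:
    """One-way ANOVA with pairwise-vs-control Holm-Sidak comparisons.

    The overall F test runs across all lines; each non-control line is
    then compared with the control by a two-sided t test using the
    pooled ANOVA error (mean within-group square, N - k df), and the raw
    p-values are Holm-Sidak adjusted.  Returns one row per non-control
    line: mean_area, raw_p, adjusted_p, significant.
    """
    if control not in areas:
        raise ValueError(f"control line {control!r} not in areas")
    if len(areas) < 2:
        raise ValueError("need at least 2 lines")
    for line, vals in areas.items():
        if len(vals) < 2:
            raise ValueError(f"line {line!r} has fewer than 2 values")

    groups = {line: np.asarray(v, float) for line, v in areas.items()}
    k = len(groups)
    n_total = sum(len(v) for v in groups.values())
    df_err = n_total - k
    sse = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    mse = sse / df_err

    control_vals = groups[control]
    lines = [line for line in groups if line != control]
    raw = []
    for line in lines:
        v = groups[line]
        diff = v.mean() - control_vals.mean()
        if mse == 0:
            raw.append(1.0 if diff == 0 else 0.0)
            continue
        se = math.sqrt(mse * (1 / len(v) + 1 / len(control_vals)))
        t = diff / se
        raw.append(2 * stats.t.sf(abs(t), df_err))

    adjusted = holm_sidak_adjust(raw)
    out = pd.DataFrame(
        {
            "line_id": lines,
            "mean_area": [groups[line].mean() for line in lines],
            "raw_p": raw,
            "adjusted_p": adjusted,
            "significant": adjusted < alpha,
        }
    ).set_index("line_id")
    grand = np.concatenate(list(groups.values())).mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    out.attrs["anova_F"] = float((ssb / (k - 1)) / mse) if mse > 0 else float("inf")
    out.attrs["anova_df"] = (k - 1, df_err)
    return out


def call_modifiers(
    areas: Mapping[str, Sequence[float]], control: str, alpha: float = 0.05
) -> tuple[list[ModifierCall], int]:
    """Suppressor/enhancer calls plus the integer hit rate in percent.

    Lines with adjusted p below ``alpha`` are suppressors when their
    mean eye area exceeds the disease-model control mean and enhancers
    when below; everything else is no_effect.  The hit rate is
    100 x modifiers / lines tested, rounded to the nearest percent.
    """
    table = anova_holm_sidak(areas, control, alpha)
    control_mean = float(np.mean(np.asarray(areas[control], float)))
    calls = []
    for line, row in table.iterrows():
        if row["adjusted_p"] < alpha and row["mean_area"] != control_mean:
            call = "suppressor" if row["mean_area"] > control_mean else "enhancer"
        else:
            call = "no_effect"
        calls.append(
            ModifierCall(
                line_id=str(line),
                mean_area=float(row["mean_area"]),
                adjusted_p=float(row["adjusted_p"]),
                call=call,
            )
        )
    n_hits = sum(c.call != "no_effect" for c in calls)
    return calls, hit_rate_percent(n_hits, len(calls))


def hit_rate_percent(n_modifiers: int, n_tested: int) -> int:
    """100 x n_modifiers / n_tested, rounded half away from zero."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    return int(math.floor(100 * n_modifiers / n_tested + 0.5))


EXACT_MW_MAX_N = 12


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (of ``x``) with a two-sided p.

    Small samples (n_x + n_y <= 12) get an exact permutation p by
    enumerating every assignment of the pooled ranks, which remains
    valid under ties; larger samples use the normal approximation with
    tie correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")

    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_x = ranks[:nx].sum() - nx * (nx + 1) / 2

    if nx + ny <= EXACT_MW_MAX_N:
        idx = range(nx + ny)
        stats_u = []
        for chosen in combinations(idx, nx):
            r = ranks[list(chosen)].sum() - nx * (nx + 1) / 2
            stats_u.append(r)
        stats_u = np.asarray(stats_u)
        lo = float((stats_u <= u_x + 1e-12).mean())
        hi = float((stats_u >= u_x - 1e-12).mean())
        p = min(1.0, 2 * min(lo, hi))
        return float(u_x), p

    _, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(u_x), float(p)


def km_summary(
    survival: pd.DataFrame, groups: tuple[str, str]
) -> SurvivalSummary:
    """Kaplan-Meier curves, medians and the Mantel-Cox log-rank test.

    ``survival`` needs columns group, day, event (death/censored).  The
    percent change in median survival is 100 x (median_b - median_a) /
    median_a for ``groups = (a, b)``; it is NaN when either median is
    undefined (no deaths, or the curve never falls to 0.5).
    """
    group_a, group_b = groups
    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    defined: dict[str, bool] = {}
    frames = {}
    for g in groups:
        sub = survival[survival["group"] == g]
        if not len(sub):
            raise ValueError(f"group {g!r} has no observations")
        if (sub["day"] <= 0).any():
            raise ValueError("survival times must be positive")
        observed = (sub["event"] == "death").to_numpy()
        frames[g] = (sub["day"].to_numpy(float), observed)
        kmf = KaplanMeierFitter()
        kmf.fit(sub["day"], event_observed=observed, label=g)
        curve = kmf.survival_function_.rename(columns={g: "survival"})
        curve["at_risk"] = kmf.event_table["at_risk"].reindex(curve.index)
        curves[g] = curve.reset_index().rename(columns={"timeline": "time"})
        med = kmf.median_survival_time_
        ok = math.isfinite(med) and observed.any()
        medians[g] = float(med) if ok else float("nan")
        defined[g] = ok
        if not observed.any():
            warnings.warn(
                f"group {g!r} has no observed deaths; median undefined",
                stacklevel=2,
            )

    if defined[group_a] and defined[group_b]:
        pct = 100 * (medians[group_b] - medians[group_a]) / medians[group_a]
    else:
        pct = float("nan")

    (ta, ea), (tb, eb) = frames[group_a], frames[group_b]
    lr = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return SurvivalSummary(
        curves=curves,
        medians=medians,
        median_defined=defined,
        percent_change=float(pct),
        logrank_chi2=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
    )


def endplate_occupancy(counts: pd.DataFrame, min_total: int = 100) -> pd.DataFrame:
    """Per-muscle endplate occupancy percentages.

    ``counts`` needs n_full, n_partial, n_vacant columns.  The fully
    occupied percentage is the primary denervation endpoint; muscles
    with fewer than ``min_total`` classified endplates trigger a warning
    because small fields of view make the percentage unstable.
    """
    for col in ("n_full", "n_partial", "n_vacant"):
        if col not in counts.columns:
            raise ValueError(f"missing column {col!r}")
    total = counts[["n_full", "n_partial", "n_vacant"]].sum(axis=1)
    if (total == 0).any():
        raise ValueError("muscle with zero classified endplates")
    if (total < min_total).any():
        n_small = int((total < min_total).sum())
        warnings.warn(
            f"{n_small} muscle(s) with fewer than {min_total} endplates",
            stacklevel=2,
        )
    out = counts.copy()
    out["pct_full"] = 100 * counts["n_full"] / total
    out["pct_partial"] = 100 * counts["n_partial"] / total
    out["pct_vacant"] = 100 * counts["n_vacant"] / total
    return out


def compare_occupancy(
    counts: pd.DataFrame, groups: tuple[str, str]
) -> tuple[float, float]:
    """Mann-Whitney comparison of per-muscle fully-occupied percentages."""
    pct = endplate_occupancy(counts)
    a = pct.loc[pct["group"] == groups[0], "pct_full"]
    b = pct.loc[pct["group"] == groups[1], "pct_full"]
    return mann_whitney(a.to_numpy(), b.to_numpy())


def weight_compare(
    weights_a: Sequence[float], weights_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Student's t (pooled variance) on body weights."""
    a = np.asarray(weights_a, float)
    b = np.asarray(weights_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 weights per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
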