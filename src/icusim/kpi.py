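"""Aggregation of simulated KPI trajectories: per-timepoint means,
boxplot statistics, capacity-exceedance rates, and the ANOVA / Tukey HSD
validation of between-model occupancy differences."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .simulator import KPI_COLUMNS, trajectories_to_frame

__all__ = [
    "KPISummary",
    "summarize_trajectories",
    "kpi_wide_table",
    "anova_per_timepoint",
    "tukey_posthoc",
]


def _as_frame(trajs) -> pd.DataFrame:
    if isinstance(trajs, pd.DataFrame):
        frame = trajs
    else:
        frame = trajectories_to_frame(list(trajs))
    if frame.empty:
        raise ValueError("no trajectories supplied")
    horizons = frame.groupby("model")["t"].max()
    if horizons.nunique() != 1:
        raise ValueError(f"ragged horizons across models: {dict(horizons)}")
    return frame


@dataclass
class KPISummary:
    """Per-(model, t) aggregates over simulation runs.

    ``means``: mean Npat/Ncor/Nov/Nun.  ``boxplot``: five-number summary of
    Npat (1.5·IQR whiskers) plus outlier count.  ``exceedance``: fraction of
    runs with Npat above the reference capacity.
    """

    means: pd.DataFrame
    boxplot: pd.DataFrame
    exceedance: pd.DataFrame


def _box_stats(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = x[(x >= lo_fence) & (x <= hi_fence)]
    return {
        "whisker_low": float(inliers.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_high": float(inliers.max()),
        "n_outliers": int(np.sum((x < lo_fence) | (x > hi_fence))),
    }


def summarize_trajectories(trajs, reference_capacity: int = 60) -> KPISummary:
    """Reduce raw trajectories to per-(model, t) summary statistics."""
    frame = _as_frame(trajs)
    means = (
        frame.groupby(["model", "t"], sort=True)[list(KPI_COLUMNS)]
        .mean()
        .reset_index()
    )
    box_rows, exc_rows = [], []
    for (model, t), grp in frame.groupby(["model", "t"], sort=True):
        npat = grp["Npat"].to_numpy()
        box_rows.append({"model": model, "t": t, **_box_stats(npat)})
        exc_rows.append(
            {
                "model": model,
                "t": t,
                "exceedance": float(np.mean(npat > reference_capacity)),
            }
        )
    return KPISummary(
        means=means,
        boxplot=pd.DataFrame(box_rows),
        exceedance=pd.DataFrame(exc_rows),
    )


def kpi_wide_table(summary: KPISummary) -> pd.DataFrame:
    """Wide per-model KPI table: one row per (model, KPI), one column per t."""
    long = summary.means.melt(
        id_vars=["model", "t"], value_vars=list(KPI_COLUMNS),
        var_name="kpi", value_name="value",
    )
    wide = long.pivot_table(
        index=["model", "kpi"], columns="t", values="value", sort=False
    )
    wide.columns = [f"t={t}" for t in wide.columns]
    return wide.reset_index()


def _npat_groups(trajs, t: int):
    frame = _as_frame(trajs)
    at_t = frame[frame["t"] == t]
    if at_t.empty:
        raise ValueError(f"no records at t={t}")
    models = sorted(at_t["model"].unique())
    if len(models) < 2:
        raise ValueError("need at least two models")
    groups = [at_t.loc[at_t["model"] == m, "Npat"].to_numpy(float) for m in models]
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least two runs per model")
    return models, groups


def anova_per_timepoint(trajs, t: int) -> tuple[float, float]:
    """One-way ANOVA of Npat across models at time t → (F, p).

    Degenerate case: zero within-group variance with equal group means is
    reported as F = 0, p = 1 (no evidence of a difference) rather than nan.
    """
    _, groups = _npat_groups(trajs, t)
    within_var = sum(np.var(g) for g in groups)
    means = [g.mean() for g in groups]
    if within_var == 0:
        if np.ptp(means) == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def tukey_posthoc(trajs, t: int, alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Tukey HSD of Npat across models at time t.

    Columns: model_a, model_b, mean_diff (a − b), p_adj, significant.
    Degenerate zero-variance groups follow the ANOVA convention.
    """
    models, groups = _npat_groups(trajs, t)
    means = {m: g.mean() for m, g in zip(models, groups)}
    within_var = sum(np.var(g) for g in groups)
    rows = []
    if within_var == 0:
        for a, b in combinations(models, 2):
            diff = means[a] - means[b]
            p = 1.0 if diff == 0 else 0.0
            rows.append((a, b, float(diff), p, p < alpha))
    else:
        res = stats.tukey_hsd(*groups)
        for ia, ib in combinations(range(len(models)), 2):
            rows.append(
                (
                    models[ia],
                    models[ib],
                    float(res.statistic[ia, ib]),
                    float(res.pvalue[ia, ib]),
                    bool(res.pvalue[ia, ib] < alpha),
                )
            )
    return pd.DataFrame(
        rows, columns=["model_a", "model_b", "mean_diff", "p_adj", "significant"]
    )
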