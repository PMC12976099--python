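"""Classification metrics, decision-curve analysis and calibration binning
for binary LOS prediction sets.

Conventions: the positive class (label 1) is the *longer* stay; probability
thresholds classify positive with ``prob >= threshold`` (inclusive);
proportion confidence intervals use Wilson's method; the AUROC interval uses
the DeLong variance estimator; the scaled Brier score is measured against
the constant-prevalence reference model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PredictionSet",
    "MetricsReport",
    "DCACurve",
    "UndefinedMetricError",
    "confusion_metrics",
    "auroc",
    "scaled_brier",
    "nir_binomial_test",
    "decision_curve",
    "calibration_bins",
    "evaluate_prediction_set",
]

#: threshold band considered operationally relevant for ward management
PRACTICAL_THRESHOLD_RANGE = (0.25, 0.75)


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is empty (e.g. no positives)."""


@dataclass(frozen=True)
class PredictionSet:
    """Paired scores (probabilities or binary labels) and truth labels."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        y = np.asarray(self.labels)
        if s.shape != y.shape or s.ndim != 1:
            raise ValueError("scores and labels must be equal-length vectors")
        if s.size == 0:
            raise ValueError("empty prediction set")
        if np.any(np.isnan(s)) or np.any((s < 0) | (s > 1)):
            raise ValueError("scores must lie in [0, 1]")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be binary")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "labels", y.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.labels.size)

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean())


@dataclass
class MetricsReport:
    """Point estimates (with optional 95% CIs) of the standard metrics."""

    n: int
    auroc: float | None = None
    auroc_ci: tuple[float, float] | None = None
    sensitivity: float | None = None
    sensitivity_ci: tuple[float, float] | None = None
    specificity: float | None = None
    specificity_ci: tuple[float, float] | None = None
    precision: float | None = None
    precision_ci: tuple[float, float] | None = None
    scaled_brier: float | None = None
    f1: float | None = None
    accuracy: float | None = None
    accuracy_ci: tuple[float, float] | None = None
    nir: float | None = None
    nir_pvalue: float | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, tuple):
                out[k] = [float(x) for x in v]
            elif isinstance(v, (int, float)) or v is None:
                out[k] = v
            else:
                out[k] = v
        return out


def _wilson(k: int, n: int) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def confusion_metrics(preds: PredictionSet, threshold: float = 0.5) -> MetricsReport:
    """Threshold-based metrics: SE, SP, PRE, ACC, F1 and the NIR test.

    The no-information rate (NIR) is the majority-class share; the reported
    p-value is the exact one-sided binomial tail for accuracy exceeding it.
    """
    y = preds.labels
    yhat = (preds.scores >= threshold).astype(np.int64)
    tp = int(np.sum((yhat == 1) & (y == 1)))
    tn = int(np.sum((yhat == 0) & (y == 0)))
    fp = int(np.sum((yhat == 1) & (y == 0)))
    fn = int(np.sum((yhat == 0) & (y == 1)))
    n = preds.n
    n_pos, n_neg = tp + fn, tn + fp
    if n_pos == 0:
        raise UndefinedMetricError("no positive labels: sensitivity undefined")
    if n_neg == 0:
        raise UndefinedMetricError("no negative labels: specificity undefined")
    if tp + fp == 0:
        raise UndefinedMetricError("no predicted positives: precision undefined")
    se = tp / n_pos
    sp = tn / n_neg
    pre = tp / (tp + fp)
    acc = (tp + tn) / n
    f1 = 0.0 if (pre + se) == 0 else 2 * pre * se / (pre + se)
    nir = max(n_pos, n_neg) / n
    return MetricsReport(
        n=n,
        sensitivity=se, sensitivity_ci=_wilson(tp, n_pos),
        specificity=sp, specificity_ci=_wilson(tn, n_neg),
        precision=pre, precision_ci=_wilson(tp, tp + fp),
        accuracy=acc, accuracy_ci=_wilson(tp + tn, n),
        f1=f1,
        nir=nir,
        nir_pvalue=nir_binomial_test(tp + tn, n, nir),
    )


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Midrank-based placement values of positives (V10) and negatives (V01)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def auroc(preds: PredictionSet, ci: bool = True):
    """Rank-based AUROC (ties counted 1/2) with a 95% DeLong interval.

    Returns ``(estimate, (lo, hi))``; the interval is clipped to [0, 1] and
    degenerates to the point estimate when both placement variances vanish
    (perfect separation).
    """
    y = preds.labels
    if y.min() == y.max():
        raise UndefinedMetricError("AUROC needs both classes present")
    v10, v01 = _delong_components(preds.scores, y)
    theta = float(v10.mean())
    if not ci:
        return theta, None
    m, n = v10.size, v01.size
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    half = 1.959963984540054 * np.sqrt(var)
    return theta, (max(0.0, theta - half), min(1.0, theta + half))


def scaled_brier(preds: PredictionSet) -> float:
    """1 − Brier/Brier_ref, with the constant-prevalence model as reference."""
    pbar = preds.prevalence
    if pbar in (0.0, 1.0):
        raise UndefinedMetricError(
            "scaled Brier reference undefined at prevalence 0 or 1"
        )
    bs = float(np.mean((preds.scores - preds.labels) ** 2))
    bs_ref = pbar * (1.0 - pbar)
    return 1.0 - bs / bs_ref


def nir_binomial_test(successes: int, n: int, nir: float) -> float:
    """Exact one-sided binomial tail P(X >= successes | p = nir)."""
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in 0..n")
    if not 0 < nir < 1:
        raise ValueError("nir must lie in (0, 1)")
    return float(stats.binomtest(successes, n, nir, alternative="greater").pvalue)


@dataclass
class DCACurve:
    """Standardized net benefit over a threshold-probability grid.

    ``table`` columns: pt, snb_model, snb_all, snb_none (identically 0).
    """

    table: pd.DataFrame
    prevalence: float
    highlight_range: tuple[float, float] = PRACTICAL_THRESHOLD_RANGE


def decision_curve(preds: PredictionSet, grid=None) -> DCACurve:
    """Decision-curve analysis against treat-all and treat-none.

    Net benefit at threshold pt: NB = TP/n − (FP/n)·pt/(1−pt), classifying
    positive when prob ≥ pt; standardized by dividing by the prevalence π.
    Treat-all: NB_all = π − (1−π)·pt/(1−pt).  Grid points at pt = 1 (or
    outside (0, 1)) are dropped.
    """
    if grid is None:
        grid = np.arange(0.01, 1.0, 0.01)
    grid = np.asarray(grid, dtype=float)
    grid = grid[(grid > 0) & (grid < 1)]
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    y = preds.labels
    n = preds.n
    pi = preds.prevalence
    if pi == 0:
        raise UndefinedMetricError("sNB undefined at prevalence 0")
    rows = []
    for pt in grid:
        yhat = preds.scores >= pt
        tp = np.sum(yhat & (y == 1)) / n
        fp = np.sum(yhat & (y == 0)) / n
        odds = pt / (1.0 - pt)
        nb = tp - fp * odds
        nb_all = pi - (1.0 - pi) * odds
        rows.append((float(pt), nb / pi, nb_all / pi, 0.0))
    table = pd.DataFrame(rows, columns=["pt", "snb_model", "snb_all", "snb_none"])
    return DCACurve(table=table, prevalence=pi)


def calibration_bins(preds: PredictionSet, n_bins: int = 10) -> pd.DataFrame:
    """Equal-width calibration bins on [0, 1].

    Columns: bin_mid, mean_predicted, observed_freq, count.  Empty bins are
    kept with count 0 and NaN mean/frequency.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # right-closed last bin so prob 1.0 lands in the top bin
    idx = np.clip(np.digitize(preds.scores, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        count = int(mask.sum())
        rows.append(
            {
                "bin_mid": float((edges[b] + edges[b + 1]) / 2),
                "mean_predicted": float(preds.scores[mask].mean()) if count else np.nan,
                "observed_freq": float(preds.labels[mask].mean()) if count else np.nan,
                "count": count,
            }
        )
    return pd.DataFrame(rows)


def evaluate_prediction_set(preds: PredictionSet, threshold: float = 0.5,
                            probabilistic: bool = True) -> MetricsReport:
    """Full metrics report; score-based metrics only when probabilistic.

    Individually undefined metrics (e.g. precision with no predicted
    positives) are left as None with an explanatory note instead of
    aborting the whole report.
    """
    try:
        report = confusion_metrics(preds, threshold=threshold)
    except UndefinedMetricError as exc:
        report = MetricsReport(n=preds.n, notes=[str(exc)])
    if probabilistic:
        try:
            report.auroc, report.auroc_ci = auroc(preds)
        except UndefinedMetricError as exc:
            report.notes.append(str(exc))
        try:
            report.scaled_brier = scaled_brier(preds)
        except UndefinedMetricError as exc:
            report.notes.append(str(exc))
    return report
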