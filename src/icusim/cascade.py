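"""Sequential LOS prediction pipeline on irregular multi-variable vitals.

The cascade issues one binary classifier per prediction time τ ∈ {0, 1, 2}.
Inputs are long-format vitals series on a 5-minute grid (columns
patient_id, variable_id, offset_min, value).  Features per variable:

* an admission-window aggregate (mean, max, or binary occurrence) over the
  first 40 minutes, and
* ordinary least-squares (intercept, slope) of value on time-in-hours over
  the τ-specific informative horizon (τ=0: the 40-min window itself;
  τ=1: 24 h; τ=2: 48 h).

The classifier itself is a pluggable contract (any callable mapping a
training matrix to a probability scorer); the reference learner is an
L1-penalized (lasso) logistic regression.  Out-of-sample probabilities for
*every* patient come from a modified 5-fold scheme: the cohort is
partitioned once, five submodels each score the fold they never saw, and the
per-fold predictions are assembled into one table usable downstream by the
ward simulator.

A synthetic vitals generator stands in for a real high-resolution ICU
dataset so the pipeline's signal recovery can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .cohort import LOSDistribution, sample_los, truth_label

__all__ = [
    "GRID_STEP_MIN",
    "ADMISSION_WINDOW_MIN",
    "HORIZON_HOURS",
    "FeatureSpec",
    "FoldAssignment",
    "extract_initial_features",
    "extract_trend_features",
    "trend_feature_matrix",
    "make_folds",
    "logistic_lasso_learner",
    "fit_predict_out_of_sample",
    "generate_synthetic_timeseries",
    "run_cascade",
]

#: vitals sampling grid (minutes)
GRID_STEP_MIN = 5
#: admission window used for the initial aggregates (minutes)
ADMISSION_WINDOW_MIN = 40
#: informative horizon per prediction time, in hours from admission
HORIZON_HOURS = {0: ADMISSION_WINDOW_MIN / 60.0, 1: 24.0, 2: 48.0}

VITALS_COLUMNS = ["patient_id", "variable_id", "offset_min", "value"]

AGGREGATES = ("mean", "max", "binary")


@dataclass(frozen=True)
class FeatureSpec:
    """Aggregate kind per variable for the admission-window features.

    ``aggregates`` maps variable_id → one of ``mean`` (continuous
    observations), ``max``, or ``binary`` (1 iff any record exists in the
    window — for treatment/dosing variables).
    """

    aggregates: dict

    def __post_init__(self) -> None:
        bad = {v: a for v, a in self.aggregates.items() if a not in AGGREGATES}
        if bad:
            raise ValueError(f"unknown aggregate kinds: {bad}")

    @classmethod
    def all_mean(cls, variable_ids) -> "FeatureSpec":
        return cls({v: "mean" for v in variable_ids})


@dataclass(frozen=True)
class FoldAssignment:
    """Single random partition of the cohort into k folds (1-based)."""

    folds: dict

    def fold_of(self, patient_id) -> int:
        return self.folds[patient_id]

    @property
    def k(self) -> int:
        return max(self.folds.values())

    def members(self, fold: int):
        return [pid for pid, f in self.folds.items() if f == fold]


def _validate_series(series: pd.DataFrame) -> pd.DataFrame:
    missing = set(VITALS_COLUMNS) - set(series.columns)
    if missing:
        raise ValueError(f"vitals series missing columns {sorted(missing)}")
    off = series["offset_min"].to_numpy()
    if np.any(off < 0) or np.any(off % GRID_STEP_MIN != 0):
        raise ValueError(f"offsets must be non-negative multiples of {GRID_STEP_MIN}")
    return series


def extract_initial_features(series: pd.DataFrame, spec: FeatureSpec,
                             general: pd.DataFrame | None = None) -> pd.DataFrame:
    """Admission-window (first 40 min) aggregates, one row per patient.

    Missing variables yield NaN for mean/max aggregates and 0 for binary
    occurrence.  ``general`` (indexed by patient_id, e.g. age / admission
    hour / sex) is passed through unchanged when given.
    """
    series = _validate_series(series)
    window = series[series["offset_min"] <= ADMISSION_WINDOW_MIN]
    patients = pd.Index(sorted(series["patient_id"].unique()), name="patient_id")
    cols = {}
    for var, kind in sorted(spec.aggregates.items()):
        sub = window[window["variable_id"] == var]
        if kind == "binary":
            present = sub.groupby("patient_id").size() > 0
            cols[f"v{var}_occ"] = present.astype(float).reindex(patients,
                                                                fill_value=0.0)
        else:
            agg = sub.groupby("patient_id")["value"].agg(kind)
            cols[f"v{var}_{kind}"] = agg.reindex(patients)
    out = pd.DataFrame(cols, index=patients)
    if general is not None:
        out = out.join(general, how="left")
    return out


def extract_trend_features(offsets_min, values, horizon_hours: float):
    """OLS (intercept, slope) of value on time-in-hours within the horizon.

    Fewer than two points → (nan, nan); two or more points at a single
    distinct time → (mean, 0.0) by convention.
    """
    t = np.asarray(offsets_min, dtype=float) / 60.0
    y = np.asarray(values, dtype=float)
    keep = t <= horizon_hours + 1e-9
    t, y = t[keep], y[keep]
    if t.size < 2:
        return float("nan"), float("nan")
    tbar, ybar = t.mean(), y.mean()
    stt = float(np.sum((t - tbar) ** 2))
    if stt == 0.0:
        return float(ybar), 0.0
    slope = float(np.sum((t - tbar) * (y - ybar)) / stt)
    return float(ybar - slope * tbar), slope


def trend_feature_matrix(series: pd.DataFrame, horizon_hours: float) -> pd.DataFrame:
    """Per-patient, per-variable (intercept, slope) over one horizon.

    Vectorized over (patient, variable) groups via the closed-form
    two-parameter OLS solution; column names ``v{var}_icpt`` / ``v{var}_slope``.
    """
    series = _validate_series(series)
    sub = series[series["offset_min"] / 60.0 <= horizon_hours + 1e-9].copy()
    sub["t"] = sub["offset_min"] / 60.0
    g = sub.groupby(["patient_id", "variable_id"])
    stats_ = g.agg(
        n=("value", "size"),
        st=("t", "sum"),
        sy=("value", "sum"),
        stt=("t", lambda x: float(np.sum(np.square(x)))),
        sty=("t", "sum"),  # placeholder, replaced below
    )
    # cross-moment needs both columns; compute via a product column
    sub["ty"] = sub["t"] * sub["value"]
    stats_["sty"] = sub.groupby(["patient_id", "variable_id"])["ty"].sum()
    n = stats_["n"].to_numpy(float)
    st, sy = stats_["st"].to_numpy(float), stats_["sy"].to_numpy(float)
    stt, sty = stats_["stt"].to_numpy(float), stats_["sty"].to_numpy(float)
    denom = stt - st * st / n
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(denom > 0, (sty - st * sy / n) / np.where(denom > 0, denom, 1),
                         0.0)
        icpt = sy / n - slope * st / n
    slope = np.where(n >= 2, slope, np.nan)
    icpt = np.where(n >= 2, icpt, np.nan)
    res = pd.DataFrame(
        {"icpt": icpt, "slope": slope}, index=stats_.index
    ).reset_index()
    wide = res.pivot(index="patient_id", columns="variable_id",
                     values=["icpt", "slope"])
    wide.columns = [f"v{var}_{which}" for which, var in wide.columns]
    return wide.sort_index(axis=1)


def make_folds(patient_ids, k: int = 5,
               rng: np.random.Generator | None = None) -> FoldAssignment:
    """Random single partition into k folds of size within ±1 of n/k."""
    ids = np.asarray(list(patient_ids))
    if len(set(ids.tolist())) != ids.size:
        raise ValueError("duplicate patient ids")
    if ids.size < k:
        raise ValueError(f"need at least k={k} patients, got {ids.size}")
    rng = np.random.default_rng() if rng is None else rng
    splitter = KFold(n_splits=k, shuffle=True,
                     random_state=int(rng.integers(2**32)))
    folds = {}
    for fold_no, (_, test_idx) in enumerate(splitter.split(ids), start=1):
        for i in test_idx:
            folds[ids[i].item() if hasattr(ids[i], "item") else ids[i]] = fold_no
    return FoldAssignment(folds)


def logistic_lasso_learner(C: float = 1.0) -> Callable:
    """Reference learner: imputation + scaling + L1 logistic regression.

    Returns a contract-conforming callable: (X, y) → scorer(X') → P(y=1).
    """

    def fit(X: np.ndarray, y: np.ndarray) -> Callable:
        pipe = Pipeline(
            [
                ("impute", SimpleImputer(strategy="mean", keep_empty_features=True)),
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                           C=C, max_iter=1000)),
            ]
        )
        pipe.fit(X, y)
        return lambda Xnew: pipe.predict_proba(Xnew)[:, 1]

    return fit


@dataclass
class OutOfFoldResult:
    """Assembled out-of-fold probabilities plus per-fold bookkeeping."""

    probabilities: pd.Series          # indexed by patient_id
    fold_of: pd.Series                # indexed by patient_id
    per_fold: pd.DataFrame            # fold, n_test, plus metric-hook columns


def fit_predict_out_of_sample(features: pd.DataFrame, labels: pd.Series,
                              folds: FoldAssignment,
                              learner: Callable | None = None,
                              fold_metrics: dict[str, Callable] | None = None,
                              ) -> OutOfFoldResult:
    """Train k submodels, each scoring the one fold it never saw.

    ``features`` is indexed by patient_id; ``labels`` aligned.  Every
    patient receives exactly one out-of-fold probability.  ``fold_metrics``
    maps metric name → f(y_true, probs) evaluated per fold (e.g. per-fold
    AUROC rows).
    """
    learner = logistic_lasso_learner() if learner is None else learner
    ids = features.index
    if set(ids) != set(folds.folds):
        raise ValueError("fold assignment does not match the feature index")
    y = labels.reindex(ids).to_numpy()
    fold_vec = np.asarray([folds.fold_of(pid) for pid in ids])
    probs = pd.Series(np.nan, index=ids, name="prob")
    rows = []
    for f in range(1, folds.k + 1):
        test = fold_vec == f
        train = ~test
        y_train = y[train]
        if y_train.min() == y_train.max():
            raise ValueError(f"training split for fold {f} has a single class")
        scorer = learner(features.to_numpy()[train], y_train)
        p = scorer(features.to_numpy()[test])
        probs.iloc[np.flatnonzero(test)] = p
        row = {"fold": f, "n_test": int(test.sum())}
        for mname, mfun in (fold_metrics or {}).items():
            row[mname] = float(mfun(y[test], p))
        rows.append(row)
    assert not probs.isna().any()
    return OutOfFoldResult(
        probabilities=probs,
        fold_of=pd.Series(fold_vec, index=ids, name="fold"),
        per_fold=pd.DataFrame(rows),
    )


def generate_synthetic_timeseries(n_patients: int, n_variables: int,
                                  los_model: LOSDistribution,
                                  effect_size: float,
                                  rng: np.random.Generator,
                                  noise_sd: float = 0.5,
                                  trend_sd: float = 0.5,
                                  level_sd: float = 1.0):
    """Synthetic vitals with a recoverable longer-stay signal.

    Per patient: LOS from ``los_model``; per variable a latent linear trend
    value(t) = a + b·t_hours + ε, ε ~ N(0, noise_sd²), with a ~ N(0,
    level_sd²) and b ~ N(0, trend_sd²) shifted by ``effect_size`` · 1[LOS > 1]
    — longer-stay patients drift where one-day patients stay flat.  Values
    are sampled on the 5-minute grid over min(LOS·24 h, 48 h).

    This emulates only the *shape* of high-resolution ICU data (irregular
    per-patient horizons on a fixed grid, multi-channel, signal correlated
    with LOS), not its clinical content.

    Returns ``(series, meta)``: the long-format vitals table and a
    per-patient frame (patient_id index) with true_los and the three general
    passthrough variables (age, admission_hour, sex — pure noise here).
    """
    if n_patients < 1 or n_variables < 1:
        raise ValueError("need n_patients >= 1 and n_variables >= 1")
    los = sample_los(los_model, rng, size=n_patients)
    shift = effect_size * (los > 1)
    frames = []
    for pid in range(n_patients):
        horizon_min = min(int(los[pid]) * 24 * 60, 48 * 60)
        offsets = np.arange(0, horizon_min + 1, GRID_STEP_MIN)
        t_hours = offsets / 60.0
        a = rng.normal(0.0, level_sd, size=n_variables)
        b = rng.normal(0.0, trend_sd, size=n_variables) + shift[pid]
        vals = (a[:, None] + b[:, None] * t_hours[None, :]
                + rng.normal(0.0, noise_sd, size=(n_variables, offsets.size)))
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "variable_id": np.repeat(np.arange(1, n_variables + 1),
                                             offsets.size),
                    "offset_min": np.tile(offsets, n_variables),
                    "value": vals.ravel(),
                }
            )
        )
    series = pd.concat(frames, ignore_index=True)
    meta = pd.DataFrame(
        {
            "true_los": los,
            "age": rng.normal(60.0, 15.0, size=n_patients),
            "admission_hour": rng.uniform(0.0, 24.0, size=n_patients),
            "sex": rng.integers(0, 2, size=n_patients).astype(float),
        },
        index=pd.Index(range(n_patients), name="patient_id"),
    )
    return series, meta


def run_cascade(series: pd.DataFrame, meta: pd.DataFrame,
                spec: FeatureSpec | None = None,
                learner: Callable | None = None,
                k: int = 5,
                rng: np.random.Generator | None = None,
                fold_metrics: dict[str, Callable] | None = None):
    """End-to-end cascade: features → folds → out-of-fold probabilities.

    Builds, for each τ with at least two classes in its risk set (patients
    with LOS ≥ τ+1), the feature matrix (admission aggregates + τ-horizon
    trends + general variables), fits the k-fold out-of-sample scheme with a
    single partition shared across all τ, and returns a prediction table
    with columns patient_id, tau, prob, label (prob ≥ 0.5) and true_los,
    plus per-(τ, fold) metric rows.
    """
    rng = np.random.default_rng() if rng is None else rng
    if spec is None:
        spec = FeatureSpec.all_mean(sorted(series["variable_id"].unique()))
    general = meta[["age", "admission_hour", "sex"]]
    base = extract_initial_features(series, spec, general=general)
    folds = make_folds(base.index, k=k, rng=rng)
    out_rows, fold_rows = [], []
    for tau in (0, 1, 2):
        in_risk = meta.index[meta["true_los"] >= tau + 1]
        labels = pd.Series(
            [truth_label(int(meta.loc[pid, "true_los"]), tau) for pid in in_risk],
            index=in_risk,
        )
        if labels.nunique() < 2:
            continue
        trends = trend_feature_matrix(series, HORIZON_HOURS[tau])
        X = base.join(trends, rsuffix="_tr").loc[in_risk]
        sub_folds = FoldAssignment({pid: folds.fold_of(pid) for pid in in_risk})
        res = fit_predict_out_of_sample(X, labels, sub_folds, learner=learner,
                                        fold_metrics=fold_metrics)
        for pid in in_risk:
            p = float(res.probabilities.loc[pid])
            out_rows.append(
                (pid, tau, p, int(p >= 0.5), int(meta.loc[pid, "true_los"]))
            )
        pf = res.per_fold.copy()
        pf.insert(0, "tau", tau)
        fold_rows.append(pf)
    table = pd.DataFrame(
        out_rows, columns=["patient_id", "tau", "prob", "label", "true_los"]
    )
    per_fold = (pd.concat(fold_rows, ignore_index=True)
                if fold_rows else pd.DataFrame())
    return table, per_fold
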