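"""Interchangeable LOS prediction rules p̂(i, τ) ∈ {0, 1}.

Three kinds of rule drive the ward simulator:

* :class:`NaivePredictor` — the majority-class benchmark: at each τ it
  deterministically predicts the larger of P(LOS = τ+1 | LOS ≥ τ+1) and
  P(LOS > τ+1 | LOS ≥ τ+1), i.e. it always predicts the no-information class.
* :class:`ConfusionEmulator` — a stochastic stand-in for a fitted classifier,
  calibrated to its per-τ sensitivity/specificity: given the truth label it
  predicts 1 with probability SE(τ) (truth 1) or 1−SP(τ) (truth 0).
* :class:`TablePredictor` — real out-of-fold model predictions looked up per
  (patient, τ) from a delimited file.

``REFERENCE_CONFUSION_SPECS`` carries the out-of-fold sensitivity/specificity
of the three classifiers fitted to the HiRID cohort (a simple and a complex
logistic lasso regression and a gradient-boosting model), which the emulators
reproduce in distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    PREDICTION_TIMES,
    LOSDistribution,
    NotInRiskSetError,
)

__all__ = [
    "ConfusionSpec",
    "PredictorModel",
    "NaivePredictor",
    "ConfusionEmulator",
    "TablePredictor",
    "REFERENCE_CONFUSION_SPECS",
    "naive_from_distribution",
    "emulator_from_confusion",
    "load_prediction_table",
    "PredictionLookupError",
]


class PredictionLookupError(KeyError):
    """Raised when a table-driven model has no entry for (patient_id, tau)."""


@dataclass(frozen=True)
class ConfusionSpec:
    """Per-τ (sensitivity, specificity) pairs of a binary LOS classifier."""

    sensitivity: tuple[float, float, float]
    specificity: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name, vals in (
            ("sensitivity", self.sensitivity),
            ("specificity", self.specificity),
        ):
            v = np.asarray(vals, dtype=float)
            if v.shape != (len(PREDICTION_TIMES),):
                raise ValueError(f"{name} needs one value per tau, got {vals}")
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} values must be probabilities, got {vals}")


#: Out-of-fold sensitivity/specificity at τ = 0, 1, 2 of the LOS classifiers
#: fitted to the HiRID cohort: simple logistic lasso (LRs), full-feature
#: logistic lasso (LRc) and extreme gradient boosting (XGB).
REFERENCE_CONFUSION_SPECS: dict[str, ConfusionSpec] = {
    "LRs": ConfusionSpec((0.33, 0.71, 0.99), (0.84, 0.54, 0.02)),
    "LRc": ConfusionSpec((0.43, 0.70, 0.96), (0.83, 0.58, 0.08)),
    "XGB": ConfusionSpec((0.66, 0.73, 0.91), (0.76, 0.62, 0.20)),
}


class PredictorModel:
    """Base class: a rule producing the binary prediction p̂(i, τ)."""

    name: str = "model"

    #: whether repeated calls with the same arguments can differ
    stochastic: bool = False

    def predict(self, los, tau, rng=None, *, patient_id=None, u=None) -> int:
        """Binary prediction for a single patient with true LOS ``los`` at τ."""
        out = self.predict_batch(
            np.asarray([los]),
            np.asarray([tau]),
            rng,
            patient_ids=None if patient_id is None else np.asarray([patient_id]),
            u=None if u is None else np.asarray([u], dtype=float),
        )
        return int(out[0])

    def predict_batch(self, los, tau, rng=None, *, patient_ids=None, u=None):
        raise NotImplementedError

    @staticmethod
    def _check_risk_set(los, tau) -> None:
        bad = los < tau + 1
        if np.any(bad):
            i = int(np.argmax(bad))
            raise NotInRiskSetError(
                f"prediction requested at tau={int(tau[i])} for a patient with "
                f"los={int(los[i])} (already discharged)"
            )


class NaivePredictor(PredictorModel):
    """Deterministic majority-class rule with one fixed prediction per τ."""

    def __init__(self, majority: tuple[int, int, int], name: str = "NP"):
        m = tuple(int(x) for x in majority)
        if len(m) != len(PREDICTION_TIMES) or any(x not in (0, 1) for x in m):
            raise ValueError(f"majority must be 3 binary entries, got {majority}")
        self.majority = m
        self.name = name

    def predict_batch(self, los, tau, rng=None, *, patient_ids=None, u=None):
        los = np.asarray(los)
        tau = np.asarray(tau)
        self._check_risk_set(los, tau)
        return np.asarray(self.majority, dtype=np.int64)[tau]


def naive_from_distribution(dist: LOSDistribution, name: str = "NP") -> NaivePredictor:
    """Majority-class rule implied by a LOS distribution.

    At each τ the rule compares the conditional discharge probability
    P(LOS = τ+1 | LOS ≥ τ+1) with its complement and fixes the prediction to
    the majority class.  Ties, and τ with an empty risk set, predict 1
    (the capacity-conservative choice: the bed is kept).
    """
    majority = []
    for tau in PREDICTION_TIMES:
        try:
            p_discharge = dist.conditional_discharge_prob(tau)
        except NotInRiskSetError:
            majority.append(1)
            continue
        majority.append(0 if p_discharge > 0.5 else 1)
    return NaivePredictor(tuple(majority), name=name)


class ConfusionEmulator(PredictorModel):
    """Stochastic predictor calibrated to per-τ sensitivity/specificity.

    Given the truth label y = truth_label(los, τ), predicts 1 with
    probability SE(τ) when y = 1 and with probability 1 − SP(τ) when y = 0.

    ``coupling`` controls dependence of a patient's draws across τ:

    * ``"independent"`` (default): fresh uniform per call via ``rng``.
    * ``"comonotone"``: a single per-patient latent uniform ``u`` thresholds
      every draw, maximizing cross-τ dependence.  Per-τ marginals — and
      hence all ward-occupancy expectations — are identical under either
      coupling; only run-to-run variance differs.
    """

    stochastic = True

    def __init__(self, spec: ConfusionSpec, name: str = "emulator",
                 coupling: str = "independent"):
        if coupling not in ("independent", "comonotone"):
            raise ValueError(f"unknown coupling {coupling!r}")
        self.spec = spec
        self.name = name
        self.coupling = coupling

    def predict_batch(self, los, tau, rng=None, *, patient_ids=None, u=None):
        los = np.asarray(los)
        tau = np.asarray(tau)
        self._check_risk_set(los, tau)
        se = np.asarray(self.spec.sensitivity)[tau]
        fpr = 1.0 - np.asarray(self.spec.specificity)[tau]
        truth = los > tau + 1
        p_one = np.where(truth, se, fpr)
        if self.coupling == "comonotone":
            if u is None:
                raise ValueError("comonotone coupling needs per-patient uniforms u")
            draws = np.asarray(u, dtype=float)
        else:
            if rng is None:
                raise ValueError("independent coupling needs an rng")
            draws = rng.random(size=los.shape)
        return (draws < p_one).astype(np.int64)


def emulator_from_confusion(spec: ConfusionSpec, name: str = "emulator",
                            coupling: str = "independent") -> ConfusionEmulator:
    """Convenience constructor for :class:`ConfusionEmulator`."""
    return ConfusionEmulator(spec, name=name, coupling=coupling)


class TablePredictor(PredictorModel):
    """Lookup rule answering queries from a (patient_id, τ) → label table.

    When the table also carries each patient's true LOS (``true_los``
    column), the predictor doubles as a finite cohort the simulator can
    resample whole patients from (id, LOS and all made predictions).
    """

    def __init__(self, table: pd.DataFrame, name: str = "table"):
        required = {"patient_id", "tau", "label"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"prediction table missing columns {sorted(missing)}")
        self.name = name
        self._labels = {
            (pid, int(t)): int(lab)
            for pid, t, lab in zip(table["patient_id"], table["tau"], table["label"])
        }
        self._true_los: dict | None = None
        if "true_los" in table.columns:
            per_patient = table.groupby("patient_id")["true_los"].agg(["min", "max"])
            if (per_patient["min"] != per_patient["max"]).any():
                raise ValueError("inconsistent true_los within a patient")
            self._true_los = per_patient["min"].astype(int).to_dict()
        self._patient_ids = np.asarray(sorted({pid for pid, _ in self._labels}))

    @property
    def has_cohort(self) -> bool:
        return self._true_los is not None

    def sample_patients(self, n: int, rng: np.random.Generator):
        """Resample n (patient_id, true LOS) pairs with replacement."""
        if not self.has_cohort:
            raise ValueError("table has no true_los column; cannot act as a cohort")
        ids = rng.choice(self._patient_ids, size=n, replace=True)
        los = np.asarray([self._true_los[pid] for pid in ids], dtype=np.int64)
        return ids, los

    def predict_batch(self, los, tau, rng=None, *, patient_ids=None, u=None):
        if patient_ids is None:
            raise PredictionLookupError("table rule requires patient ids")
        tau = np.asarray(tau)
        out = np.empty(tau.shape, dtype=np.int64)
        for i, (pid, t) in enumerate(zip(np.asarray(patient_ids), tau)):
            key = (pid, int(t))
            if key not in self._labels:
                raise PredictionLookupError(
                    f"no prediction for patient_id={pid!r} at tau={int(t)}"
                )
            out[i] = self._labels[key]
        return out


def load_prediction_table(path, threshold: float = 0.5,
                          name: str = "table") -> TablePredictor:
    """Load per-patient out-of-fold predictions from a delimited file.

    The file needs columns ``patient_id``, ``tau`` and at least one of
    ``prob`` (probability of the positive/longer-stay class, in [0, 1]) or
    ``label`` (binary).  When only ``prob`` is present, labels are assigned
    by ``prob >= threshold``.  An optional ``true_los`` column enables
    cohort resampling (see :class:`TablePredictor`).
    """
    try:
        table = pd.read_csv(path)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed prediction table {path}: {exc}") from exc
    if "patient_id" not in table.columns or "tau" not in table.columns:
        raise ValueError(f"{path}: need patient_id and tau columns")
    if not set(np.unique(table["tau"])) <= set(PREDICTION_TIMES):
        raise ValueError(f"{path}: tau values must lie in {PREDICTION_TIMES}")
    dup = table.duplicated(subset=["patient_id", "tau"])
    if dup.any():
        row = table[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate entry for patient_id={row['patient_id']!r} "
            f"tau={int(row['tau'])}"
        )
    if "label" not in table.columns:
        if "prob" not in table.columns:
            raise ValueError(f"{path}: need a prob or label column")
        probs = table["prob"].astype(float)
        if probs.isna().any() or ((probs < 0) | (probs > 1)).any():
            bad = int(np.argmax(probs.isna() | (probs < 0) | (probs > 1)))
            raise ValueError(
                f"{path}: probability out of [0, 1] at data row {bad + 1}"
            )
        table = table.assign(label=(probs >= threshold).astype(int))
    return TablePredictor(table, name=name)


def predict(model: PredictorModel, los, tau, rng=None, *,
            patient_id=None, u=None) -> int:
    """Functional form of :meth:`PredictorModel.predict`."""
    return model.predict(los, tau, rng, patient_id=patient_id, u=u)
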