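"""Discretized length-of-stay population model for a simulated ICU cohort.

The ICU length of stay (LOS) is discretized to whole days (ceiling) and
capped at 4: patients staying four days *or longer* are treated as staying
exactly 4 days. The cohort is therefore fully described by a probability
vector over LOS ∈ {1, 2, 3, 4}. The default class sizes come from the
HiRID ICU cohort (Bern University Hospital): 18,629 / 6,722 / 2,623 / 5,931
patients with LOS of 1, 2, 3 and ≥4 days.

Predictions are issued at day-indexed prediction times τ ∈ {0, 1, 2}
(roughly: 40 minutes, 24 h and 48 h after admission).  The binary target at
τ is 0 if the stay ends after day τ+1 and 1 if it continues beyond day τ+1;
a prediction at τ exists only for patients still in treatment (LOS ≥ τ+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HIRID_LOS_CLASS_COUNTS",
    "MAX_LOS_DAYS",
    "PREDICTION_TIMES",
    "LOSDistribution",
    "PatientRecord",
    "InvalidDistributionError",
    "NotInRiskSetError",
    "from_class_counts",
    "truth_label",
    "sample_los",
    "sample_initial_stage",
]

#: Number of LOS classes; the last class ("≥4 d") is capped at 4 days.
MAX_LOS_DAYS = 4

#: Day-indexed prediction times: after 40 min, 24 h and 48 h of treatment.
PREDICTION_TIMES = (0, 1, 2)

#: Patients per discretized LOS class (1, 2, 3, ≥4 days) in the HiRID cohort.
HIRID_LOS_CLASS_COUNTS = (18629, 6722, 2623, 5931)


class InvalidDistributionError(ValueError):
    """Raised for LOS class counts/probabilities that do not form a distribution."""


class NotInRiskSetError(ValueError):
    """Raised when a prediction is requested for a patient already discharged."""


@dataclass(frozen=True)
class LOSDistribution:
    """Probability distribution over the four discretized LOS classes.

    Parameters
    ----------
    probs
        Probabilities for LOS = 1, 2, 3, 4 days.  Must be non-negative and
        sum to 1 (within 1e-12).
    source_counts
        Optional raw class counts the probabilities were derived from.
    """

    probs: tuple[float, float, float, float]
    source_counts: tuple[int, int, int, int] | None = field(default=None)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (MAX_LOS_DAYS,):
            raise InvalidDistributionError(
                f"expected {MAX_LOS_DAYS} class probabilities, got shape {p.shape}"
            )
        if np.any(p < 0):
            raise InvalidDistributionError(f"negative probability in {self.probs}")
        if abs(p.sum() - 1.0) > 1e-12:
            raise InvalidDistributionError(
                f"probabilities sum to {p.sum()!r}, expected 1"
            )
        if self.source_counts is not None:
            c = np.asarray(self.source_counts, dtype=float)
            if c.shape != (MAX_LOS_DAYS,) or np.any(c < 0) or c.sum() <= 0:
                raise InvalidDistributionError(
                    f"invalid source counts {self.source_counts}"
                )
            if not np.allclose(p, c / c.sum(), atol=1e-12):
                raise InvalidDistributionError(
                    "probs inconsistent with source_counts"
                )
        object.__setattr__(self, "probs", tuple(float(x) for x in p))

    @property
    def probs_array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)

    def conditional_discharge_prob(self, tau: int) -> float:
        """P(LOS = τ+1 | LOS ≥ τ+1): the discharge share of the risk set at τ.

        Raises :class:`NotInRiskSetError` when the risk set is empty
        (P(LOS ≥ τ+1) = 0).
        """
        if tau not in PREDICTION_TIMES:
            raise ValueError(f"tau must be in {PREDICTION_TIMES}, got {tau}")
        p = self.probs_array
        tail = p[tau:].sum()
        if tail <= 0:
            raise NotInRiskSetError(f"empty risk set at tau={tau}")
        return float(p[tau] / tail)


def from_class_counts(counts) -> LOSDistribution:
    """Build a :class:`LOSDistribution` from raw per-class patient counts.

    >>> d = from_class_counts((18629, 6722, 2623, 5931))
    >>> round(d.probs[0], 4)
    0.5494
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (MAX_LOS_DAYS,):
        raise InvalidDistributionError(f"expected {MAX_LOS_DAYS} counts, got {counts}")
    if np.any(c < 0):
        raise InvalidDistributionError(f"negative count in {counts}")
    if np.any(c != np.round(c)):
        raise InvalidDistributionError(f"counts must be integers, got {counts}")
    total = c.sum()
    if total <= 0:
        raise InvalidDistributionError("all-zero class counts")
    return LOSDistribution(
        probs=tuple(c / total), source_counts=tuple(int(x) for x in c)
    )


def truth_label(los: int, tau: int) -> int:
    """Ground-truth binary class for the prediction at time τ.

    Returns 0 when the stay ends after day τ+1 (LOS = τ+1) and 1 when it
    continues beyond day τ+1 (LOS > τ+1).  Only defined for patients still
    in treatment at τ, i.e. LOS ≥ τ+1.
    """
    if tau not in PREDICTION_TIMES:
        raise ValueError(f"tau must be in {PREDICTION_TIMES}, got {tau}")
    if los < tau + 1:
        raise NotInRiskSetError(
            f"patient with los={los} already discharged before tau={tau}"
        )
    return 0 if los == tau + 1 else 1


@dataclass
class PatientRecord:
    """A single ward occupant.

    ``stage`` indexes the currently-used prediction: a patient at stage s is
    on treatment day s+1.  Predictions are only issued at τ ∈ {0,1,2}; a
    patient at stage 3 (fourth treatment day, necessarily LOS = 4) keeps the
    τ=2 prediction as only the predictions actually made are used.
    """

    los: int
    stage: int
    used_prediction: int

    def __post_init__(self) -> None:
        if self.los not in (1, 2, 3, 4):
            raise ValueError(f"los must be in 1..4, got {self.los}")
        if not 0 <= self.stage <= self.los - 1:
            raise ValueError(
                f"stage {self.stage} past discharge for los={self.los}"
            )
        if self.stage == 3 and self.los != 4:
            raise ValueError("stage 3 requires los=4")
        if self.used_prediction not in (0, 1):
            raise ValueError(f"prediction must be binary, got {self.used_prediction}")

    @property
    def effective_tau(self) -> int:
        """Prediction time of the currently-used prediction (min(stage, 2))."""
        return min(self.stage, 2)


def sample_los(dist: LOSDistribution, rng: np.random.Generator, size=None):
    """Draw LOS values (days, in {1..4}) from the class distribution.

    With ``size=None`` returns a single int, otherwise an int array.
    """
    draws = rng.choice(MAX_LOS_DAYS, size=size, p=dist.probs_array) + 1
    if size is None:
        return int(draws)
    return draws.astype(np.int64)


def sample_initial_stage(los, rng: np.random.Generator):
    """Uniformly assign the currently-used prediction index at ward entry.

    A patient with LOS = l has had min(l, 3) predictions made (at
    τ = 0..min(l,3)−1); each is equally likely to be the current one.  For
    LOS = 4 the support is {0, 1, 2}: only three predictions exist, so stage
    3 is never an initial state.  Accepts a scalar or an integer array.
    """
    los_arr = np.asarray(los)
    if np.any((los_arr < 1) | (los_arr > MAX_LOS_DAYS)):
        raise ValueError(f"los values must be in 1..{MAX_LOS_DAYS}")
    n_preds = np.minimum(los_arr, 3)
    stages = np.floor(rng.random(size=los_arr.shape) * n_preds).astype(np.int64)
    # guard against the measure-zero rng.random() == 1.0 edge
    stages = np.minimum(stages, n_preds - 1)
    if np.isscalar(los):
        return int(stages)
    return stages
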