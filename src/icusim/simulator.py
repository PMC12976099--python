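"""Monte Carlo ward engine: ICU bed capacity managed by LOS predictions.

One simulation run models a B-bed ICU over T daily steps.  The ward starts
full (B patients resampled from the LOS distribution, each at a uniformly
drawn point of their stay).  Each day:

1. KPIs are counted: of the Npat occupants, how many currently-used
   predictions are correct (Ncor), overestimating (Nov: predict "stays",
   truth "leaves") or underestimating (Nun: predict "leaves", truth
   "stays").
2. The predicted number of beds freeing up overnight, F̂, is read off the
   currently-used predictions (a patient on their fourth treatment day is
   counted as freeing with certainty — the 4-day cap is known).
3. Patients whose stay actually ends leave; survivors advance one day and,
   while predictions are still being made (stage ≤ 2), receive the next
   prediction; past that they keep their τ=2 prediction.
4. A = max(0, F̂ + (B − Npat)) new patients are admitted: the predicted
   discharges plus an occupancy correction toward the B-bed target.  There
   is no hard cap — overadmission due to underestimated stays shows up as
   occupancy above B.

The run-to-run mean of Npat measures how well a prediction rule holds the
ward at its target occupancy; Nov/Nun decompose the error direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import LOSDistribution, sample_initial_stage, sample_los
from .predictors import PredictorModel, TablePredictor

__all__ = [
    "SimulationConfig",
    "WardState",
    "KPIRecord",
    "KPITrajectory",
    "initialize_ward",
    "count_kpis",
    "predicted_free_beds",
    "advance_day",
    "run_simulation",
    "run_experiment",
    "trajectories_to_frame",
    "model_run_rng",
]

KPI_COLUMNS = ("Npat", "Ncor", "Nov", "Nun")


@dataclass(frozen=True)
class SimulationConfig:
    """Monte Carlo study parameters.

    Defaults follow the reference study: R = 1000 runs, T = 10 daily steps,
    a 50-bed occupancy target on a physically 60-bed unit (the extra 10 beds
    are a planning buffer; ``reference_capacity`` is used only to report how
    often simulated occupancy exceeds the physical unit size).
    """

    runs: int = 1000
    horizon: int = 10
    beds: int = 50
    reference_capacity: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.runs < 1 or self.horizon < 0 or self.beds < 1:
            raise ValueError("runs and beds must be >= 1 and horizon >= 0")
        if self.reference_capacity < self.beds:
            raise ValueError("reference_capacity must be >= beds")


@dataclass
class WardState:
    """Occupants of the ward at one time point, as parallel arrays."""

    t: int
    los: np.ndarray          # true LOS in days, 1..4
    stage: np.ndarray        # treatment-day index, 0..los-1
    pred: np.ndarray         # currently-used binary prediction
    latent_u: np.ndarray     # per-patient uniform for comonotone emulators
    patient_ids: np.ndarray | None = None  # set when driven by a cohort table

    @property
    def n_patients(self) -> int:
        return int(self.los.size)

    @property
    def effective_tau(self) -> np.ndarray:
        """Prediction time of each currently-used prediction (min(stage, 2))."""
        return np.minimum(self.stage, 2)

    def validate(self) -> None:
        if np.any((self.los < 1) | (self.los > 4)):
            raise ValueError("los out of 1..4")
        if np.any(self.stage > self.los - 1):
            raise ValueError("patient past true discharge day")
        if np.any((self.stage == 3) & (self.los != 4)):
            raise ValueError("stage 3 requires los=4")


@dataclass(frozen=True)
class KPIRecord:
    t: int
    Npat: int
    Ncor: int
    Nov: int
    Nun: int

    def __post_init__(self) -> None:
        if self.Ncor + self.Nov + self.Nun != self.Npat:
            raise ValueError("KPI counts do not partition the ward")
        if min(self.Npat, self.Ncor, self.Nov, self.Nun) < 0:
            raise ValueError("negative KPI count")


@dataclass
class KPITrajectory:
    """KPI records of one run: t = 0..T, T+1 records."""

    model: str
    run: int
    records: list[KPIRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.model,
                "run": self.run,
                "t": [r.t for r in self.records],
                "Npat": [r.Npat for r in self.records],
                "Ncor": [r.Ncor for r in self.records],
                "Nov": [r.Nov for r in self.records],
                "Nun": [r.Nun for r in self.records],
            }
        )


def _admit(n: int, dist: LOSDistribution, model: PredictorModel,
           rng: np.random.Generator):
    """Draw n fresh patients: (los, patient_ids or None)."""
    if isinstance(model, TablePredictor) and model.has_cohort:
        ids, los = model.sample_patients(n, rng)
        return los, ids
    return sample_los(dist, rng, size=n), None


def initialize_ward(cfg: SimulationConfig, dist: LOSDistribution,
                    model: PredictorModel, rng: np.random.Generator) -> WardState:
    """Fill all B beds with patients mid-stay.

    Each patient gets a LOS from the cohort distribution, a uniformly drawn
    stage over the predictions actually made for that LOS (0..min(los,3)−1,
    so stage ≤ 2 always holds at initialization), and the model's prediction
    at that stage as the currently-used one.
    """
    los, ids = _admit(cfg.beds, dist, model, rng)
    stage = sample_initial_stage(los, rng)
    latent_u = rng.random(cfg.beds)
    pred = model.predict_batch(los, stage, rng, patient_ids=ids, u=latent_u)
    state = WardState(t=0, los=los, stage=stage, pred=pred,
                      latent_u=latent_u, patient_ids=ids)
    state.validate()
    return state


def count_kpis(state: WardState) -> KPIRecord:
    """Judge every occupant's currently-used prediction against the truth.

    The truth at effective time τ = min(stage, 2) is 1 iff LOS > τ+1;
    patients on their fourth day (stage 3, LOS = 4) are judged by their
    retained τ=2 prediction against truth 1.
    """
    tau = state.effective_tau
    truth = (state.los > tau + 1).astype(np.int64)
    pred = state.pred
    ncor = int(np.sum(pred == truth))
    nov = int(np.sum((pred == 1) & (truth == 0)))
    nun = int(np.sum((pred == 0) & (truth == 1)))
    return KPIRecord(t=state.t, Npat=state.n_patients, Ncor=ncor, Nov=nov, Nun=nun)


def predicted_free_beds(state: WardState) -> int:
    """Beds forecast to free up overnight.

    A bed is counted when the occupant's currently-used prediction is 0
    (stay ends after the current day) or the occupant is on their fourth
    treatment day, whose discharge is certain under the 4-day cap.
    """
    return int(np.sum((state.pred == 0) | (state.stage == 3)))


def advance_day(state: WardState, cfg: SimulationConfig, dist: LOSDistribution,
                model: PredictorModel, rng: np.random.Generator) -> WardState:
    """One daily transition: discharges, prediction updates, admissions."""
    f_hat = predicted_free_beds(state)
    n_before = state.n_patients

    stays = state.stage < state.los - 1
    los = state.los[stays]
    stage = state.stage[stays] + 1
    pred = state.pred[stays].copy()
    latent_u = state.latent_u[stays]
    ids = None if state.patient_ids is None else state.patient_ids[stays]

    # survivors still in the prediction window get the next prediction;
    # at stage 3 the tau=2 prediction is retained
    upd = stage <= 2
    if np.any(upd):
        pred[upd] = model.predict_batch(
            los[upd], stage[upd], rng,
            patient_ids=None if ids is None else ids[upd],
            u=latent_u[upd],
        )

    n_admit = max(0, f_hat + (cfg.beds - n_before))
    if n_admit > 0:
        new_los, new_ids = _admit(n_admit, dist, model, rng)
        new_u = rng.random(n_admit)
        new_pred = model.predict_batch(
            new_los, np.zeros(n_admit, dtype=np.int64), rng,
            patient_ids=new_ids, u=new_u,
        )
        los = np.concatenate([los, new_los])
        stage = np.concatenate([stage, np.zeros(n_admit, dtype=np.int64)])
        pred = np.concatenate([pred, new_pred])
        latent_u = np.concatenate([latent_u, new_u])
        if ids is not None and new_ids is not None:
            ids = np.concatenate([ids, new_ids])

    nxt = WardState(t=state.t + 1, los=los, stage=stage, pred=pred,
                    latent_u=latent_u, patient_ids=ids)
    nxt.validate()
    return nxt


def run_simulation(cfg: SimulationConfig, dist: LOSDistribution,
                   model: PredictorModel, rng: np.random.Generator,
                   run: int = 0) -> KPITrajectory:
    """One run: initialize, then T daily steps, recording KPIs at each t."""
    state = initialize_ward(cfg, dist, model, rng)
    traj = KPITrajectory(model=model.name, run=run, records=[count_kpis(state)])
    for _ in range(cfg.horizon):
        state = advance_day(state, cfg, dist, model, rng)
        traj.records.append(count_kpis(state))
    return traj


def model_run_rng(seed: int, model_index: int, run: int) -> np.random.Generator:
    """Independent substream for one (model, run) cell.

    Keyed by position so appending a model never perturbs the draws of the
    models already configured.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(model_index, run))
    )


def run_experiment(cfg: SimulationConfig, dist: LOSDistribution,
                   models: list[PredictorModel]) -> list[KPITrajectory]:
    """R runs for every model, on independent RNG substreams of cfg.seed."""
    if not models:
        raise ValueError("need at least one model")
    trajectories = []
    for m_idx, model in enumerate(models):
        for r in range(cfg.runs):
            rng = model_run_rng(cfg.seed, m_idx, r)
            trajectories.append(run_simulation(cfg, dist, model, rng, run=r))
    return trajectories


def trajectories_to_frame(trajectories: list[KPITrajectory]) -> pd.DataFrame:
    """Tidy long table: model, run, t, Npat, Ncor, Nov, Nun."""
    rows = []
    for traj in trajectories:
        for rec in traj.records:
            rows.append((traj.model, traj.run, rec.t,
                         rec.Npat, rec.Ncor, rec.Nov, rec.Nun))
    return pd.DataFrame(rows, columns=["model", "run", "t", *KPI_COLUMNS])
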