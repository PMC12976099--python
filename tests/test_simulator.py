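import numpy as np
import pandas as pd
import pytest

from icusim import (
    ConfusionSpec,
    LOSDistribution,
    NaivePredictor,
    REFERENCE_CONFUSION_SPECS,
    SimulationConfig,
    advance_day,
    count_kpis,
    emulator_from_confusion,
    initialize_ward,
    naive_from_distribution,
    predicted_free_beds,
    run_experiment,
    run_simulation,
    trajectories_to_frame,
)
from icusim.simulator import WardState, model_run_rng

from analytic_oracle import emulator_marginal, expected_kpis, naive_marginal
from conftest import SUITE_SEED

PERFECT = emulator_from_confusion(
    ConfusionSpec((1.0, 1.0, 1.0), (1.0, 1.0, 1.0)), name="perfect"
)


def small_cfg(**kw):
    defaults = dict(runs=50, horizon=10, beds=50, seed=SUITE_SEED)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestInitialization:
    def test_ward_starts_full(self, hirid_dist, rng):
        state = initialize_ward(small_cfg(), hirid_dist, PERFECT, rng)
        assert state.n_patients == 50
        assert state.t == 0
        assert np.all(state.stage <= 2)

    def test_degenerate_distribution(self, rng):
        dist = LOSDistribution((1.0, 0.0, 0.0, 0.0))
        state = initialize_ward(small_cfg(), dist, PERFECT, rng)
        assert np.all(state.los == 1) and np.all(state.stage == 0)

    def test_expected_fraction_at_stage_zero(self, hirid_dist):
        """P(stage=0) = p1 + p2/2 + p3/3 + p4/3 ≈ 0.733 at initialization."""
        p = hirid_dist.probs
        target = p[0] + p[1] / 2 + p[2] / 3 + p[3] / 3
        rng = np.random.default_rng(SUITE_SEED)
        counts = []
        for _ in range(400):
            state = initialize_ward(small_cfg(), hirid_dist, PERFECT, rng)
            counts.append(np.mean(state.stage == 0))
        se = 3 * np.sqrt(target * (1 - target) / (400 * 50))
        assert np.mean(counts) == pytest.approx(target, abs=se)


class TestKPICounting:
    def test_partition_always_holds(self, hirid_dist, rng):
        model = naive_from_distribution(hirid_dist)
        state = initialize_ward(small_cfg(), hirid_dist, model, rng)
        rec = count_kpis(state)
        assert rec.Ncor + rec.Nov + rec.Nun == rec.Npat

    def test_perfect_predictor_never_errs(self, hirid_dist, rng):
        state = initialize_ward(small_cfg(), hirid_dist, PERFECT, rng)
        rec = count_kpis(state)
        assert rec.Nov == 0 and rec.Nun == 0

    def test_naive_initial_over_under_match_enumeration(self, hirid_dist):
        """E[Nov] = 50(p2/2 + p3/3) ≈ 6.25, E[Nun] = 50(p2/2 + p3/3 + p4/3)
        ≈ 9.16 — cell-by-cell enumeration of (los, stage, pred, truth)."""
        p = hirid_dist.probs
        e_nov = 50 * (p[1] / 2 + p[2] / 3)
        e_nun = 50 * (p[1] / 2 + p[2] / 3 + p[3] / 3)
        model = naive_from_distribution(hirid_dist)
        rng = np.random.default_rng(SUITE_SEED)
        novs, nuns = [], []
        for _ in range(600):
            rec = count_kpis(initialize_ward(small_cfg(), hirid_dist, model, rng))
            novs.append(rec.Nov)
            nuns.append(rec.Nun)
        assert np.mean(novs) == pytest.approx(e_nov, abs=3 * np.std(novs) / 24.5)
        assert np.mean(nuns) == pytest.approx(e_nun, abs=3 * np.std(nuns) / 24.5)

    def test_stage_three_judged_by_retained_prediction(self):
        state = WardState(
            t=5,
            los=np.array([4, 4]),
            stage=np.array([3, 3]),
            pred=np.array([1, 0]),
            latent_u=np.zeros(2),
        )
        rec = count_kpis(state)
        # truth at tau=2 is 1 (los=4): pred 1 correct, pred 0 underestimates
        assert (rec.Ncor, rec.Nov, rec.Nun) == (1, 0, 1)


class TestPredictedFreeBeds:
    def test_all_predicted_to_stay(self):
        state = WardState(t=0, los=np.array([4, 4]), stage=np.array([0, 1]),
                          pred=np.array([1, 1]), latent_u=np.zeros(2))
        assert predicted_free_beds(state) == 0

    def test_stage_three_frees_with_certainty(self):
        state = WardState(t=0, los=np.array([4]), stage=np.array([3]),
                          pred=np.array([1]), latent_u=np.zeros(1))
        assert predicted_free_beds(state) == 1

    def test_naive_initial_expectation(self, hirid_dist):
        """F̂ at t=0 ≈ B × P(stage = 0) ≈ 36.6 under the naive rule."""
        p = hirid_dist.probs
        target = 50 * (p[0] + p[1] / 2 + p[2] / 3 + p[3] / 3)
        model = naive_from_distribution(hirid_dist)
        rng = np.random.default_rng(SUITE_SEED)
        vals = [
            predicted_free_beds(initialize_ward(small_cfg(), hirid_dist, model, rng))
            for _ in range(600)
        ]
        assert np.mean(vals) == pytest.approx(target, abs=3 * np.std(vals) / 24.5)


class TestAdvanceDay:
    def test_perfect_predictor_keeps_ward_full(self, hirid_dist, rng):
        cfg = small_cfg()
        state = initialize_ward(cfg, hirid_dist, PERFECT, rng)
        for _ in range(5):
            state = advance_day(state, cfg, hirid_dist, PERFECT, rng)
            assert state.n_patients == cfg.beds

    def test_full_ward_no_predicted_discharges_admits_none(self, rng):
        dist = LOSDistribution((0.0, 0.0, 0.0, 1.0))
        always_stay = NaivePredictor((1, 1, 1), name="stay")
        cfg = small_cfg(beds=30)
        state = WardState(t=0, los=np.full(30, 4), stage=np.zeros(30, dtype=int),
                          pred=np.ones(30, dtype=int), latent_u=np.zeros(30))
        nxt = advance_day(state, cfg, dist, always_stay, rng)
        assert nxt.n_patients == 30  # no departures, no admissions
        assert np.all(nxt.stage == 1)

    def test_always_discharge_rule_state_stays_legal(self, hirid_dist, rng):
        """Predict-0 everywhere: admissions refill toward B each day and no
        patient ever outlives their true discharge day."""
        always_leave = NaivePredictor((0, 0, 0), name="leave")
        cfg = small_cfg()
        state = initialize_ward(cfg, hirid_dist, always_leave, rng)
        for _ in range(10):
            state = advance_day(state, cfg, hirid_dist, always_leave, rng)
            state.validate()
            rec = count_kpis(state)
            assert min(rec.Npat, rec.Ncor, rec.Nov, rec.Nun) >= 0

    def test_naive_one_step_expectation(self, hirid_dist):
        """E[Npat at t=1] = B − E[departures] + E[F̂] ≈ 52.9."""
        model = naive_from_distribution(hirid_dist)
        oracle = expected_kpis(hirid_dist.probs, naive_marginal(model.majority),
                               beds=50, horizon=1)
        cfg = small_cfg(runs=400, horizon=1)
        frame = trajectories_to_frame(run_experiment(cfg, hirid_dist, [model]))
        npat1 = frame.loc[frame.t == 1, "Npat"]
        mc_se = npat1.std() / np.sqrt(len(npat1))
        assert oracle.loc[1, "Npat"] == pytest.approx(52.9, abs=0.1)
        assert npat1.mean() == pytest.approx(oracle.loc[1, "Npat"], abs=3 * mc_se)


class TestRunSimulation:
    def test_zero_horizon_single_record(self, hirid_dist, rng):
        cfg = small_cfg(horizon=0)
        traj = run_simulation(cfg, hirid_dist, PERFECT, rng)
        assert len(traj.records) == 1
        assert traj.records[0].Npat == cfg.beds

    def test_perfect_predictor_conservation(self, hirid_dist):
        """Npat ≡ B exactly at every (run, t) for any seed."""
        for seed in (0, 1, SUITE_SEED):
            cfg = small_cfg(runs=20, seed=seed)
            frame = trajectories_to_frame(
                run_experiment(cfg, hirid_dist, [PERFECT]))
            assert (frame["Npat"] == cfg.beds).all()

    def test_kpi_partition_every_record(self, hirid_dist):
        models = [
            naive_from_distribution(hirid_dist),
            emulator_from_confusion(REFERENCE_CONFUSION_SPECS["XGB"], name="XGB"),
        ]
        frame = trajectories_to_frame(
            run_experiment(small_cfg(runs=30), hirid_dist, models))
        assert (frame["Ncor"] + frame["Nov"] + frame["Nun"] == frame["Npat"]).all()


class TestRunExperiment:
    def test_shape(self, hirid_dist):
        cfg = small_cfg(runs=5, horizon=3)
        models = [naive_from_distribution(hirid_dist), PERFECT]
        trajs = run_experiment(cfg, hirid_dist, models)
        assert len(trajs) == 10
        assert all(len(t.records) == 4 for t in trajs)

    def test_identical_seed_identical_output(self, hirid_dist):
        cfg = small_cfg(runs=8, horizon=4)
        model = emulator_from_confusion(REFERENCE_CONFUSION_SPECS["LRc"],
                                        name="LRc")
        f1 = trajectories_to_frame(run_experiment(cfg, hirid_dist, [model]))
        f2 = trajectories_to_frame(run_experiment(cfg, hirid_dist, [model]))
        pd.testing.assert_frame_equal(f1, f2)

    def test_appending_a_model_preserves_existing_draws(self, hirid_dist):
        cfg = small_cfg(runs=5, horizon=3)
        np_model = naive_from_distribution(hirid_dist)
        xgb = emulator_from_confusion(REFERENCE_CONFUSION_SPECS["XGB"],
                                      name="XGB")
        solo = trajectories_to_frame(run_experiment(cfg, hirid_dist, [np_model]))
        both = trajectories_to_frame(
            run_experiment(cfg, hirid_dist, [np_model, xgb]))
        pd.testing.assert_frame_equal(solo, both[both.model == "NP"]
                                      .reset_index(drop=True))

    def test_substreams_differ_across_runs(self):
        a = model_run_rng(1, 0, 0).random(4)
        b = model_run_rng(1, 0, 1).random(4)
        assert not np.allclose(a, b)


class TestAnalyticOracleAgreement:
    def test_naive_means_match_expectation_recursion(self, hirid_dist):
        """Simulated per-t mean KPIs match the sampling-free expectation
        recursion within 3 Monte Carlo standard errors."""
        model = naive_from_distribution(hirid_dist)
        oracle = expected_kpis(hirid_dist.probs, naive_marginal(model.majority),
                               beds=50, horizon=10)
        cfg = small_cfg(runs=400)
        frame = trajectories_to_frame(run_experiment(cfg, hirid_dist, [model]))
        for t in range(11):
            at_t = frame[frame.t == t]
            for kpi in ("Npat", "Ncor", "Nov", "Nun"):
                vals = at_t[kpi].to_numpy(float)
                mc_se = max(vals.std() / np.sqrt(len(vals)), 1e-9)
                assert vals.mean() == pytest.approx(
                    oracle.loc[t, kpi], abs=3 * mc_se
                ), f"{kpi} diverges from the oracle at t={t}"

    def test_emulator_means_match_marginal_recursion(self, hirid_dist):
        spec = REFERENCE_CONFUSION_SPECS["XGB"]
        model = emulator_from_confusion(spec, name="XGB")
        oracle = expected_kpis(
            hirid_dist.probs,
            emulator_marginal(spec.sensitivity, spec.specificity),
            beds=50, horizon=10,
        )
        frame = trajectories_to_frame(
            run_experiment(small_cfg(runs=400), hirid_dist, [model]))
        for t in (0, 3, 6, 10):
            vals = frame.loc[frame.t == t, "Npat"].to_numpy(float)
            mc_se = vals.std() / np.sqrt(len(vals))
            assert vals.mean() == pytest.approx(oracle.loc[t, "Npat"],
                                                abs=3 * mc_se)

    def test_mean_invariance_to_emulator_coupling(self, hirid_dist):
        """Independent vs comonotone cross-τ coupling: identical per-τ
        marginals, so per-t mean Npat agrees within Monte Carlo error."""
        spec = REFERENCE_CONFUSION_SPECS["LRs"]
        cfg = small_cfg(runs=400)
        frames = {}
        for coupling in ("independent", "comonotone"):
            model = emulator_from_confusion(spec, name="LRs", coupling=coupling)
            frames[coupling] = trajectories_to_frame(
                run_experiment(cfg, hirid_dist, [model]))
        for t in range(11):
            a = frames["independent"].loc[lambda f: f.t == t, "Npat"].to_numpy(float)
            b = frames["comonotone"].loc[lambda f: f.t == t, "Npat"].to_numpy(float)
            se = np.sqrt(a.var() / len(a) + b.var() / len(b))
            if se == 0:
                assert a.mean() == b.mean()
            else:
                assert abs(a.mean() - b.mean()) < 3 * se
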