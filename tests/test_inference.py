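import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cardexplore import agents as ag
from cardexplore import inference as inf
from cardexplore.task import TaskConfig, SMALL_SCHEDULE


def make_design(n=200, seed=0, **cols):
    """Hand-built design table for exercising edge paths."""
    rng = np.random.default_rng(seed)
    base = {
        "participant_id": np.repeat(np.arange(4), n // 4),
        "session": 0, "round_id": 0,
        "y": rng.integers(0, 2, n).astype(float),
        "r": rng.choice([-1, 0, 1], n).astype(float),
        "overall_uncertainty": rng.uniform(0.1, 1.38, n),
        "z_delta_eig": rng.normal(size=n),
        "z_delta_uncertainty": rng.normal(size=n),
        "z_delta_exposure": rng.normal(size=n),
    }
    base.update(cols)
    df = pd.DataFrame(base)
    df["z_overall_uncertainty"] = (df.overall_uncertainty - df.overall_uncertainty.mean()) \
        / df.overall_uncertainty.std()
    return df


class TestRidgeLogit:
    def test_matches_statsmodels_at_negligible_penalty(self):
        """Independent oracle: with lam -> 0 the solver is plain ML logistic."""
        rng = np.random.default_rng(40)
        n = 2000
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        eta = 0.3 - 0.8 * X[:, 1] + 0.5 * X[:, 2]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        ours = inf.ridge_logit(X, y, lam=1e-8)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(ours.coef, ref.params, atol=1e-5)
        np.testing.assert_allclose(ours.se, ref.bse, rtol=1e-3)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_separable_data_stays_finite(self):
        x = np.linspace(-1, 1, 50)
        X = np.column_stack([np.ones(50), x])
        y = (x > 0).astype(float)  # perfectly separable
        res = inf.ridge_logit(X, y, lam=1.0)
        assert res.converged and np.all(np.isfinite(res.coef)) and np.all(np.isfinite(res.se))

    def test_light_mode_matches_full(self):
        rng = np.random.default_rng(41)
        X = np.column_stack([np.ones(300), rng.normal(size=300)])
        y = rng.integers(0, 2, 300).astype(float)
        full = inf.ridge_logit(X, y)
        light = inf.ridge_logit(X, y, light=True)
        np.testing.assert_allclose(light.coef, full.coef, atol=1e-8)
        assert light.se is None


class TestPreparePredictors:
    def test_empirical_scaling_standardizes(self, uncertainty_dataset):
        design = inf.prepare_predictors(uncertainty_dataset, scaling=None)
        for kind in ("eig", "uncertainty", "exposure"):
            col = design[f"z_delta_{kind}"]
            assert abs(col.mean()) < 1e-10
            assert col.std(ddof=0) == pytest.approx(1.0, abs=1e-6)

    def test_stored_scaling_shared_with_generation(self, uncertainty_dataset):
        design = inf.prepare_predictors(uncertainty_dataset)
        assert design.attrs["scaling"] == pytest.approx(uncertainty_dataset.scaling)
        raw = uncertainty_dataset.trials.loc[
            ~uncertainty_dataset.trials.is_practice, "delta_uncertainty"].to_numpy()
        np.testing.assert_allclose(design["z_delta_uncertainty"],
                                   raw / uncertainty_dataset.scaling["uncertainty"])

    def test_practice_rounds_are_excluded(self, uncertainty_dataset):
        design = inf.prepare_predictors(uncertainty_dataset)
        n_exp = (~uncertainty_dataset.trials.is_practice).sum()
        assert len(design) == n_exp

    def test_zero_variance_predictor_warns(self, uncertainty_dataset):
        trials = uncertainty_dataset.trials.copy()
        trials["delta_exposure"] = 0.0
        with pytest.warns(RuntimeWarning, match="zero variance"):
            design = inf.prepare_predictors(trials, scaling=None)
        assert (design["z_delta_exposure"] == 0).all()

    def test_uncertainty_exclusion_flag(self, uncertainty_dataset):
        design = inf.prepare_predictors(uncertainty_dataset, max_overall_uncertainty=1.0)
        assert design["overall_uncertainty"].max() <= 1.0


class TestFitChoiceModel:
    def test_recovers_generative_parameters(self, uncertainty_dataset):
        """beta_dv = 1.0, beta_side = 0.1, beta_rep = 0.3 planted."""
        design = inf.prepare_predictors(uncertainty_dataset)
        fit = inf.fit_choice_model(design, "uncertainty")
        assert abs(fit.dv_slope - 1.0) < 2 * fit.dv_slope_se
        assert abs(fit.population.loc["repeat", "estimate"] - 0.3) \
            < 3 * fit.population.loc["repeat", "se"]
        assert len(fit.per_participant) == 30

    def test_null_recovery_on_pure_lapse_agents(self):
        rng = np.random.default_rng(42)
        spec = ag.DatasetSpec(task=TaskConfig(session_schedule=((1, 3),)),
                              n_participants=15,
                              population=ag.AgentParams(strategy="random", lapse=1.0))
        design = inf.prepare_predictors(ag.simulate_dataset(spec, rng))
        for kind in ("eig", "uncertainty", "exposure"):
            fit = inf.fit_choice_model(design, kind)
            assert abs(fit.dv_slope) < 3 * fit.dv_slope_se

    def test_refit_is_deterministic(self, uncertainty_dataset):
        design = inf.prepare_predictors(uncertainty_dataset)
        a = inf.fit_choice_model(design, "uncertainty")
        b = inf.fit_choice_model(design, "uncertainty")
        pd.testing.assert_frame_equal(a.population, b.population)

    def test_unknown_dv_rejected(self, uncertainty_dataset):
        design = inf.prepare_predictors(uncertainty_dataset)
        with pytest.raises(ValueError):
            inf.fit_choice_model(design, "entropy")


class TestCompareStrategies:
    def test_generating_strategy_wins(self, uncertainty_dataset):
        design = inf.prepare_predictors(uncertainty_dataset)
        comp = inf.compare_strategies(design, k_folds=10, seed=7)
        assert comp.best == "uncertainty"
        assert comp.ranking[0] == "uncertainty"
        assert sorted(comp.ranking) == sorted(("eig", "uncertainty", "exposure"))

    def test_exposure_agents_rank_exposure_first(self):
        rng = np.random.default_rng(43)
        spec = ag.DatasetSpec(task=TaskConfig(session_schedule=SMALL_SCHEDULE),
                              n_participants=20,
                              population=ag.AgentParams(strategy="exposure", beta_dv=1.0))
        design = inf.prepare_predictors(ag.simulate_dataset(spec, rng))
        comp = inf.compare_strategies(design, k_folds=5, seed=8)
        assert comp.best == "exposure"

    def test_lapse_agents_are_indistinguishable(self):
        rng = np.random.default_rng(44)
        spec = ag.DatasetSpec(task=TaskConfig(session_schedule=((1, 3),)),
                              n_participants=15,
                              population=ag.AgentParams(strategy="random", lapse=1.0))
        design = inf.prepare_predictors(ag.simulate_dataset(spec, rng))
        comp = inf.compare_strategies(design, k_folds=5, seed=9)
        for _, row in comp.pairwise.iterrows():
            assert abs(row["diff"]) < 3 * row["se"]

    def test_single_class_folds_are_merged(self):
        design = make_design(n=200, seed=45)
        design["y"] = 1.0
        design.loc[:2, "y"] = 0.0  # three zeros: some folds will be single-class
        comp = inf.compare_strategies(design, k_folds=8, seed=10, min_trials=10)
        assert comp.k_folds < 8

    def test_fold_assignment_stratified_by_participant(self, uncertainty_dataset):
        design = inf.prepare_predictors(uncertainty_dataset)
        comp = inf.compare_strategies(design, k_folds=10, seed=11)
        folds = pd.Series(comp.fold_assignment, index=design.participant_id.to_numpy())
        per_pid_folds = folds.groupby(level=0).nunique()
        assert (per_pid_folds == 10).all()

    def test_invalid_k_rejected(self, uncertainty_dataset):
        design = inf.prepare_predictors(uncertainty_dataset)
        with pytest.raises(ValueError):
            inf.compare_strategies(design, k_folds=1)


class TestRecovery:
    def test_small_recovery_matrix_is_diagonal_and_reproducible(self):
        task = TaskConfig(session_schedule=((1, 3),))
        specs = {
            s: ag.DatasetSpec(task=task, n_participants=20,
                              population=ag.AgentParams(strategy=s, beta_dv=1.0),
                              name=f"gen-{s}")
            for s in ("uncertainty", "exposure")
        }
        rm1 = inf.recover_models(specs, n_replicates=2,
                                 rng=np.random.default_rng(46), k_folds=5,
                                 dv_kinds=("uncertainty", "exposure"))
        rm2 = inf.recover_models(specs, n_replicates=2,
                                 rng=np.random.default_rng(46), k_folds=5,
                                 dv_kinds=("uncertainty", "exposure"))
        assert rm1.diagonal_dominates()
        pd.testing.assert_frame_equal(rm1.counts, rm2.counts)
        assert (rm1.counts.sum(axis=1) == 2).all()


class TestExposureEpiphenomenon:
    def test_random_agents_show_no_exposure_effect(self):
        rng = np.random.default_rng(47)
        spec = ag.DatasetSpec(task=TaskConfig(session_schedule=((1, 3),)),
                              n_participants=15,
                              population=ag.AgentParams(strategy="random", lapse=1.0))
        design = inf.prepare_predictors(ag.simulate_dataset(spec, rng))
        slope, se = inf.exposure_epiphenomenon_check(design)
        assert abs(slope) < 3 * se

    def test_exposure_seeking_agents_show_positive_slope(self):
        """Direct construction: agents following the least-exposure heuristic."""
        rng = np.random.default_rng(48)
        spec = ag.DatasetSpec(task=TaskConfig(session_schedule=((1, 3),)),
                              n_participants=15,
                              population=ag.AgentParams(strategy="exposure", beta_dv=1.0))
        design = inf.prepare_predictors(ag.simulate_dataset(spec, rng))
        slope, se = inf.exposure_epiphenomenon_check(design)
        assert slope > 2 * se
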