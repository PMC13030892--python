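import math

import numpy as np
import pandas as pd
import pytest

from cardexplore import agents as ag
from cardexplore import observer as o
from cardexplore.inference import ridge_logit
from cardexplore.task import TaskConfig, RoundConfig, SMALL_SCHEDULE, make_round


def logistic(x):
    return 1.0 / (1.0 + math.exp(-x))


class TestChoiceProbability:
    def test_pure_lapse_agent_is_coin_flip(self):
        a = ag.AgentParams(strategy="random", lapse=1.0)
        assert ag.choice_probability(a, 3.0, 1.2, 1) == 0.5

    def test_indifference_at_zero_delta(self):
        a = ag.AgentParams(beta_dv=1.0)
        assert ag.choice_probability(a, 0.0, 0.5, 0) == 0.5

    def test_above_threshold_hinge_hand_value(self):
        """s(U) = 1 + (-40)(1.1 - 1.0) = -3; logit = -3 * 0.5 = -1.5."""
        a = ag.AgentParams(beta_dv=1.0, tau=1.0, beta_int=-40.0)
        p = ag.choice_probability(a, 0.5, 1.1, 0)
        assert p == pytest.approx(logistic(-1.5), abs=1e-12)
        assert p == pytest.approx(0.1824, abs=2e-4)

    def test_below_threshold_slope_unchanged(self):
        a = ag.AgentParams(beta_dv=1.0, tau=1.0, beta_int=-40.0)
        assert ag.choice_probability(a, 0.5, 0.9, 0) == pytest.approx(logistic(0.5))

    def test_step_form(self):
        a = ag.AgentParams(beta_dv=1.0, tau=1.0, beta_int=-3.0, threshold_form="step")
        assert ag.choice_probability(a, 1.0, 1.01, 0) == pytest.approx(logistic(-2.0))

    def test_side_and_repeat_biases_enter_the_logit(self):
        a = ag.AgentParams(beta_dv=0.0, beta_side=0.4, beta_rep=0.3)
        assert ag.choice_probability(a, 0.0, 1.0, 1) == pytest.approx(logistic(0.7))
        assert ag.choice_probability(a, 0.0, 1.0, -1) == pytest.approx(logistic(0.1))

    def test_random_strategy_forces_zero_slope(self):
        a = ag.AgentParams(strategy="random", beta_dv=5.0)
        assert a.beta_dv == 0.0

    @pytest.mark.parametrize("bad", [{"lapse": 1.5}, {"tau": 3.0}, {"strategy": "greedy"},
                                     {"deck_policy": "x"}, {"threshold_form": "x"}])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            ag.AgentParams(**bad)


class TestSimulateRound:
    def _round(self, seed=0, length=60):
        rng = np.random.default_rng(seed)
        rc = make_round(rng, TaskConfig(), 0)
        return rng, RoundConfig(rc.round_id, rc.color_pair, rc.true_proportions, length)

    def test_greedy_agent_tracks_delta_uncertainty(self):
        """With a near-infinite slope the chosen table is the more uncertain one."""
        rng, rc = self._round(1, 400)
        agent = ag.AgentParams(strategy="uncertainty", beta_dv=300.0)
        beliefs = [o.TableBelief.fresh() for _ in range(4)]
        trials, _ = ag.simulate_round(agent, rc, beliefs, rng)
        df = pd.DataFrame([{"d": t.delta_uncertainty, "y": t.choice_side} for t in trials])
        decided = df[np.abs(df.d) / ag.DEFAULT_SCALING["uncertainty"] > 0.02]
        agree = ((decided.y == 1) == (decided.d > 0)).mean()
        assert agree >= 0.99

    def test_full_lapse_agent_chooses_sides_evenly(self):
        rng, rc = self._round(2, 5000)
        agent = ag.AgentParams(strategy="random", lapse=1.0)
        trials, _ = ag.simulate_round(agent, rc, [o.TableBelief.fresh()] * 4, rng)
        frac_right = np.mean([t.choice_side for t in trials])
        assert abs(frac_right - 0.5) < 4 * math.sqrt(0.25 / len(trials))

    def test_exposure_conservation_and_belief_consistency(self):
        rng, rc = self._round(3, 80)
        agent = ag.AgentParams()
        trials, beliefs = ag.simulate_round(agent, rc, [o.TableBelief.fresh()] * 4, rng)
        assert len(trials) == 80
        assert sum(o.exposure(tb) for tb in beliefs) == 80
        # replaying the observed cards reproduces the final beliefs
        replay = [o.TableBelief.fresh() for _ in range(4)]
        for t in trials:
            replay[t.chosen_table] = replay[t.chosen_table].with_card(
                t.chosen_deck, t.observed_color)
        assert replay == beliefs

    def test_decision_variables_are_pre_choice(self):
        """First trial always shows fresh-table values: all deltas 0, U = 2 ln 2."""
        rng, rc = self._round(4, 5)
        trials, _ = ag.simulate_round(ag.AgentParams(), rc,
                                      [o.TableBelief.fresh()] * 4, rng)
        first = trials[0]
        assert first.delta_uncertainty == 0.0 and first.delta_exposure == 0.0
        assert first.overall_uncertainty == pytest.approx(2 * math.log(2))
        assert first.repeat_side == 0

    def test_repeat_side_tracks_most_recent_choice(self):
        rng, rc = self._round(5, 200)
        trials, _ = ag.simulate_round(ag.AgentParams(beta_rep=0.0), rc,
                                      [o.TableBelief.fresh()] * 4, rng)
        last = {}
        for t in trials:
            lt, rt = t.left_table, t.right_table
            l, r = last.get(lt, -1), last.get(rt, -1)
            expected = 0 if l == r else (1 if r > l else -1)
            assert t.repeat_side == expected
            last[t.chosen_table] = t.trial_index

    def test_belief_table_count_mismatch_rejected(self):
        rng, rc = self._round(6, 10)
        with pytest.raises(ValueError):
            ag.simulate_round(ag.AgentParams(), rc, [o.TableBelief.fresh()] * 3, rng)


class TestTestPhase:
    def _rc(self):
        return RoundConfig(0, ("orange", "blue"),
                           ((0.8, 0.2), (0.2, 0.8), (0.6, 0.4), (0.4, 0.6)), 12)

    def test_confident_correct_belief_is_nearly_always_right(self):
        rng = np.random.default_rng(20)
        beliefs = [o.TableBelief.from_counts(60, 10, 10, 60),   # theta_true = +1
                   o.TableBelief.from_counts(10, 60, 60, 10),   # theta_true = -1
                   o.TableBelief.from_counts(40, 20, 20, 40),
                   o.TableBelief.from_counts(20, 40, 40, 20)]
        recs = []
        for _ in range(25):
            recs.extend(ag.simulate_test_phase(beliefs, self._rc(), rng))
        assert np.mean([r.correct for r in recs]) > 0.95
        assert all(r.confidence == 5 for r in recs)

    def test_fresh_table_is_at_chance_with_lowest_confidence(self):
        rng = np.random.default_rng(21)
        beliefs = [o.TableBelief.fresh()] * 4
        recs = []
        for _ in range(500):
            recs.extend(ag.simulate_test_phase(beliefs, self._rc(), rng))
        acc = np.mean([r.correct for r in recs])
        assert abs(acc - 0.5) < 4 * math.sqrt(0.25 / len(recs))
        assert all(r.confidence == 1 and r.unsolvable for r in recs)

    def test_entropy_recorded_matches_beliefs(self):
        rng = np.random.default_rng(22)
        beliefs = [o.TableBelief.from_counts(5, 1, 1, 5)] * 4
        recs = ag.simulate_test_phase(beliefs, self._rc(), rng)
        for r in recs:
            assert r.end_of_round_entropy == pytest.approx(o.entropy_theta(beliefs[0]))


class TestSimulateDataset:
    def _spec(self, **kw):
        defaults = dict(
            task=TaskConfig(session_schedule=((1, 2),)),
            n_participants=6,
            population=ag.AgentParams(strategy="uncertainty", beta_dv=1.0),
        )
        defaults.update(kw)
        return ag.DatasetSpec(**defaults)

    def test_fixed_seed_reproduces_byte_identical_csv(self, tmp_path):
        for d in ("a", "b"):
            ds = ag.simulate_dataset(self._spec(), np.random.default_rng(30))
            ds.write(tmp_path / d)
        for name in ("trials.csv", "tests.csv", "agents.csv", "meta.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_row_counts_match_round_lengths(self):
        ds = ag.simulate_dataset(self._spec(), np.random.default_rng(31))
        per_round = ds.trials.groupby(["participant_id", "round_id"]).agg(
            n=("trial_index", "size"), last=("trial_index", "max"))
        assert (per_round["n"] == per_round["last"] + 1).all()
        # one practice + two experimental rounds per participant, 4 test records each
        assert ds.trials.groupby("participant_id").round_id.nunique().eq(3).all()
        assert len(ds.tests) == 6 * 3 * 4
        assert ds.trials[ds.trials.round_id == 0].is_practice.all()

    def test_dataset_round_trips_through_disk(self, tmp_path):
        ds = ag.simulate_dataset(self._spec(), np.random.default_rng(32))
        ds.write(tmp_path / "ds")
        back = ag.SimDataset.read(tmp_path / "ds")
        assert back.scaling == ds.scaling
        pd.testing.assert_frame_equal(back.trials, ds.trials, check_dtype=False)

    def test_threshold_agents_reverse_slope_at_high_uncertainty(self):
        """Approach below threshold, avoid above: the planted reversal is visible
        in simple split-sample logistic slopes."""
        rng = np.random.default_rng(33)
        spec = self._spec(
            task=TaskConfig(session_schedule=SMALL_SCHEDULE), n_participants=30,
            population=ag.AgentParams(strategy="uncertainty", beta_dv=1.0,
                                      tau=1.0, beta_int=-20.0))
        ds = ag.simulate_dataset(spec, rng)
        tr = ds.trials[~ds.trials.is_practice]
        z = tr.delta_uncertainty.to_numpy() / ds.scaling["uncertainty"]
        y = tr.choice_side.to_numpy(float)
        u = tr.overall_uncertainty.to_numpy()
        lo, hi = u <= 0.8, u >= 1.25
        for mask, sign in ((lo, 1), (hi, -1)):
            X = np.column_stack([np.ones(mask.sum()), z[mask]])
            res = ridge_logit(X, y[mask])
            assert sign * res.coef[1] > 2 * res.se[1]

    def test_populations(self):
        rng = np.random.default_rng(34)
        jit = ag.jittered_population(ag.AgentParams(beta_dv=1.0, lapse=0.02),
                                     sd={"beta_dv": 0.3, "lapse": 0.05})
        draws = [jit(rng, i) for i in range(200)]
        assert all(0.0 <= a.lapse <= 1.0 for a in draws)
        assert np.std([a.beta_dv for a in draws]) > 0.2

        pop = ag.threshold_population(rho=0.5, beta_int_sd=4.0, beta_low_sd=0.4)
        draws = [pop(rng, i) for i in range(400)]
        lows = np.array([a.beta_dv for a in draws])
        mags = np.array([-a.beta_int for a in draws])
        assert (mags >= 0).all()
        assert np.corrcoef(lows, mags)[0, 1] > 0.3
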