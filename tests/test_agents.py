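"""Unit tests for the four valuation models and agent simulation."""

import numpy as np
import pandas as pd
import pytest

from goalpursuit import agents, task_engine
from goalpursuit.agents import (
    TreeSearchConfig,
    myopic_values,
    offer_max_values,
    prospective_values,
    simulate_agent,
    tree_search_values,
)
from goalpursuit.task_engine import GOOD_LABELS, TaskState



def make_state(offers, accumulated=0.0, net_size=20.0, current_good="A", invested=1):
    return TaskState(
        block_id=0,
        trial_index=1 if current_good is None else 2,
        net_size=net_size,
        accumulated=accumulated,
        current_good=current_good,
        offers=np.asarray(offers, dtype=float),
        trials_invested=0 if current_good is None else invested,
    )


class TestOfferMax:
    def test_values_are_raw_offers(self):
        val = offer_max_values(make_state((5.0, 2.0, 7.0)))
        assert np.array_equal(val.values, [5.0, 2.0, 7.0])

    def test_ignores_accumulated_contents(self):
        low = offer_max_values(make_state((5.0, 2.0, 7.0), accumulated=0.0, net_size=60.0))
        high = offer_max_values(make_state((5.0, 2.0, 7.0), accumulated=50.0, net_size=60.0))
        assert np.array_equal(low.values, high.values)

    def test_negative_offers_pass_through(self):
        val = offer_max_values(make_state((-1.0, -1.0, -1.0)))
        assert np.array_equal(val.values, [-1.0, -1.0, -1.0])


class TestMyopic:
    def test_goal_includes_accumulated(self):
        val = myopic_values(make_state((4.0, 12.0, 3.0), accumulated=10.0))
        assert np.array_equal(val.values, [14.0, 12.0, 3.0])
        assert val.sv_abandon == pytest.approx(-2.0)  # greedy persists

    def test_switch_when_alternative_beats_holdings(self):
        val = myopic_values(make_state((4.0, 9.0, 0.0), accumulated=2.0))
        assert val.values[0] == 6.0
        assert val.sv_abandon == pytest.approx(3.0)  # greedy abandons

    def test_empty_net_matches_offer_max_ranking(self):
        state = make_state((3.0, 8.0, 5.0), accumulated=0.0)
        assert np.argmax(myopic_values(state).values) == np.argmax(
            offer_max_values(state).values
        )

    def test_first_trial_degenerates_to_offers(self):
        state = make_state((3.0, 8.0, 5.0), current_good=None)
        assert np.array_equal(myopic_values(state).values, [3.0, 8.0, 5.0])


class TestProspective:
    def test_positive_offers_scored_as_proportions(self):
        val = prospective_values(make_state((5.0, 8.0, 0.0), accumulated=10.0, net_size=20.0))
        assert val.values[0] == pytest.approx(0.5)  # 5 / (20 - 10)
        assert val.values[1] == pytest.approx(0.4)  # 8 / 20
        assert val.sv_abandon == pytest.approx(-0.1)  # greedy persists

    def test_negative_goal_offer_is_progress_lost(self):
        val = prospective_values(make_state((-4.0, 1.0, 1.0), accumulated=10.0, net_size=20.0))
        assert val.values[0] == pytest.approx(-0.4)

    def test_negative_alternative_offer_is_raw(self):
        val = prospective_values(make_state((5.0, -3.0, 1.0), accumulated=10.0, net_size=20.0))
        assert val.values[1] == pytest.approx(-3.0)

    def test_negative_goal_offer_with_empty_net_is_zero(self):
        val = prospective_values(make_state((-4.0, 1.0, 1.0), accumulated=0.0, net_size=20.0))
        assert val.values[0] == 0.0


class TestTreeSearch:
    def test_zero_variance_closed_form(self, zero_noise_params):
        cfg = TreeSearchConfig(n_rollouts=5, params=zero_noise_params)
        state = make_state((3.0, 5.0, 5.0), accumulated=6.0, net_size=12.0)
        val = tree_search_values(state, cfg, np.random.default_rng(0))
        assert val.values[0] == -2.0  # ceil((12 - 6) / 3)
        assert val.values[1] == -3.0  # ceil(12 / 5), net forfeited on switch
        assert val.sv_abandon == pytest.approx(-1.0)  # greedy persists

    def test_closed_form_over_random_states(self, zero_noise_params):
        cfg = TreeSearchConfig(n_rollouts=4, params=zero_noise_params)
        rng = np.random.default_rng(11)
        for _ in range(25):
            net = rng.uniform(12, 72)
            acc = rng.uniform(0, net - 1e-6)
            offers = rng.uniform(1.0, 10.0, 3)
            state = make_state(offers, accumulated=acc, net_size=net)
            val = tree_search_values(state, cfg, rng)
            expected = [
                -np.ceil((net - acc) / offers[0]),
                -np.ceil(net / offers[1]),
                -np.ceil(net / offers[2]),
            ]
            np.testing.assert_array_equal(val.values, expected)

    def test_censoring_bound(self, zero_noise_params):
        cfg = TreeSearchConfig(n_rollouts=5, max_horizon=40, params=zero_noise_params)
        state = make_state((-1.0, 0.0, 0.5), accumulated=0.0, net_size=50.0)
        val = tree_search_values(state, cfg, np.random.default_rng(0))
        assert np.all(val.values >= -cfg.max_horizon)
        assert val.values[0] == -40.0  # never completes: fully censored

    def test_symmetric_state_symmetric_values(self, zero_noise_params):
        cfg = TreeSearchConfig(n_rollouts=5, params=zero_noise_params)
        state = make_state((4.0, 4.0, 4.0), accumulated=0.0, current_good=None, net_size=20.0)
        val = tree_search_values(state, cfg, np.random.default_rng(0))
        assert val.values[0] == val.values[1] == val.values[2]

    def test_monte_carlo_convergence(self):
        params = task_engine.GenerativeParams()
        state = make_state((6.0, 4.0, 8.0), accumulated=12.0, net_size=24.0)
        values = {}
        for n in (1000, 10_000):
            cfg = TreeSearchConfig(n_rollouts=n, params=params)
            values[n] = tree_search_values(state, cfg, np.random.default_rng(99)).values
        assert np.max(np.abs(values[1000] - values[10_000])) < 0.2

    def test_goal_offer_monotonicity_all_models(self, zero_noise_params):
        """Raising the current goal's offer weakly decreases sv_abandon."""
        rng = np.random.default_rng(21)
        cfg = TreeSearchConfig(n_rollouts=4, params=zero_noise_params)
        for _ in range(10):
            net = rng.uniform(15, 60)
            acc = rng.uniform(0, net / 2)
            offers = rng.uniform(1.0, 9.0, 3)
            for model in agents.MODEL_NAMES:
                svs = []
                for bump in (0.0, 2.0, 5.0):
                    o = offers.copy()
                    o[0] += bump
                    state = make_state(o, accumulated=acc, net_size=net)
                    svs.append(
                        agents.compute_values(state, model, cfg, np.random.default_rng(5)).sv_abandon
                    )
                assert svs[0] >= svs[1] >= svs[2]


class TestSimulateAgent:
    def test_greedy_offer_max_always_picks_largest_offer(self, small_schedule):
        log = simulate_agent(
            small_schedule, "offer_max", rng=np.random.default_rng(0), n_session_trials=60
        )
        offers = log[["offer_A", "offer_B", "offer_C"]].to_numpy()
        chosen = log["choice"].map({l: i for i, l in enumerate(GOOD_LABELS)}).to_numpy()
        np.testing.assert_allclose(
            offers[np.arange(len(log)), chosen], offers.max(axis=1)
        )

    def test_large_inverse_temperature_approaches_greedy(self, small_schedule, small_ts_cfg):
        log = simulate_agent(
            small_schedule,
            "tree_search",
            policy=("softmax", 0.0, 1e6),
            cfg=small_ts_cfg,
            rng=np.random.default_rng(1),
            n_session_trials=80,
        )
        rows = log.dropna(subset=["abandon"])
        sv = rows["V_altbest"] - rows["V_goal"]
        # abandon exactly when the abandonment value is positive
        assert (rows["abandon"].astype(bool) == (sv > 0)).all()

    def test_seeded_run_reproducible(self, small_schedule, small_ts_cfg):
        logs = [
            simulate_agent(
                small_schedule,
                "tree_search",
                policy=("softmax", -1.0, 0.8),
                cfg=small_ts_cfg,
                rng=np.random.default_rng(7),
                n_session_trials=50,
            )
            for _ in range(2)
        ]
        pd.testing.assert_frame_equal(logs[0], logs[1])

    def test_session_invariants(self, small_schedule, small_ts_cfg):
        log = simulate_agent(
            small_schedule,
            "tree_search",
            policy=("softmax", -1.0, 0.8),
            cfg=small_ts_cfg,
            rng=np.random.default_rng(3),
            n_session_trials=100,
        )
        assert (log["accumulated"] >= 0).all()
        assert (log["progress"] < 1).all()
        assert 0 < len(log) <= 100  # capped by the session or the schedule
        first_trials = log[log["trial"] == 1]
        assert first_trials["current_good"].isna().all()
        assert first_trials["abandon"].isna().all()

    def test_unknown_model_or_policy_rejected(self, small_schedule):
        with pytest.raises(ValueError):
            simulate_agent(small_schedule, "bayes_opt")
        with pytest.raises(ValueError):
            simulate_agent(small_schedule, "offer_max", policy="epsilon")
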