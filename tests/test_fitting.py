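"""Unit tests for logistic fitting, indifference points, CV and recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from goalpursuit import agents, fitting
from goalpursuit.fitting import (
    PersistenceLogit,
    build_dataset,
    dataset_from_logged_values,
    fit_logistic,
    loo_cv_compare,
)


def logistic_sample(rng, n, beta0, beta1, sv_loc=0.0, sv_scale=2.0):
    sv = rng.normal(sv_loc, sv_scale, n)
    y = (rng.random(n) < agents.sigmoid(beta0 + beta1 * sv)).astype(float)
    return pd.DataFrame({"abandon": y, "sv_tree_search": sv})


class TestPersistenceLogit:
    def test_recovers_known_coefficients(self):
        rng = np.random.default_rng(0)
        df = logistic_sample(rng, 10_000, beta0=-2.0, beta1=1.0, sv_loc=2.0)
        fit = fit_logistic(df)
        assert fit.converged
        assert fit.beta0 == pytest.approx(-2.0, abs=0.15)
        assert fit.beta1 == pytest.approx(1.0, abs=0.15)

    def test_matches_statsmodels_logit(self):
        rng = np.random.default_rng(1)
        df = logistic_sample(rng, 2000, beta0=-1.0, beta1=0.7)
        mine = fit_logistic(df)
        ref = sm.Logit(
            df["abandon"], sm.add_constant(df["sv_tree_search"])
        ).fit(disp=0)
        np.testing.assert_allclose(mine.params, ref.params, atol=2e-3)

    def test_constant_outcome_flagged_as_separation(self):
        df = pd.DataFrame({"abandon": np.zeros(50), "sv_tree_search": np.random.randn(50)})
        fit = fit_logistic(df)
        assert not fit.converged and fit.flag == "separation"

    def test_constant_predictor_flagged(self):
        df = pd.DataFrame(
            {"abandon": np.r_[np.zeros(25), np.ones(25)], "sv_tree_search": np.zeros(50)}
        )
        fit = fit_logistic(df)
        assert not fit.converged and fit.flag == "degenerate_predictor"

    def test_perfectly_separated_data_flagged(self):
        sv = np.linspace(-3, 3, 60)
        df = pd.DataFrame({"abandon": (sv > 0).astype(float), "sv_tree_search": sv})
        fit = fit_logistic(df)
        assert not fit.converged and fit.flag in ("separation", "non_convergence")


class TestIndifferencePoint:
    def test_arithmetic(self):
        rng = np.random.default_rng(2)
        df = logistic_sample(rng, 5000, beta0=-2.0, beta1=1.0, sv_loc=2.0)
        fit = fit_logistic(df)
        assert fit.indifference_point() == pytest.approx(-fit.beta0 / fit.beta1)

    def test_probability_one_half_at_ip(self):
        rng = np.random.default_rng(3)
        fit = fit_logistic(logistic_sample(rng, 2000, beta0=1.0, beta1=-0.8))
        assert fit.predict(fit.indifference_point()) == pytest.approx(0.5, abs=1e-6)

    def test_unbiased_case(self):
        res = fitting.PersistenceLogitResults(
            model=PersistenceLogit([0, 1], [-1.0, 1.0]),
            params=np.array([0.0, 1.3]),
            cov=np.eye(2),
            converged=True,
            flag=None,
            n_iter=1,
        )
        assert res.indifference_point() == 0.0

    def test_scale_equivariance(self):
        """Rescaling sv rescales beta1 reciprocally; IP in original units is fixed."""
        rng = np.random.default_rng(4)
        df = logistic_sample(rng, 4000, beta0=-1.5, beta1=0.9, sv_loc=1.0)
        ip = fit_logistic(df).indifference_point()
        for c in (0.25, 4.0):
            scaled = df.assign(sv_tree_search=df["sv_tree_search"] * c)
            assert fit_logistic(scaled).indifference_point() / c == pytest.approx(
                ip, rel=1e-6
            )

    def test_flat_slope_raises(self):
        res = fitting.PersistenceLogitResults(
            model=PersistenceLogit([0, 1], [-1.0, 1.0]),
            params=np.array([1.0, 1e-9]),
            cov=np.eye(2),
            converged=True,
            flag=None,
            n_iter=1,
        )
        with pytest.raises(ValueError):
            res.indifference_point()


class TestGridSearchOracle:
    def test_irls_matches_loglikelihood_grid(self):
        """Brute-force grid maximisation agrees with IRLS to grid resolution."""
        rng = np.random.default_rng(5)
        df = logistic_sample(rng, 50, beta0=-1.0, beta1=1.2, sv_loc=1.0)
        model = PersistenceLogit.from_dataframe(df)
        fit = model.fit()
        grid = np.arange(-4.0, 4.0 + 1e-9, 0.01)
        sv = model.sv
        y = model.endog
        best = (-np.inf, None, None)
        for b0 in grid:
            eta = b0 + grid[:, None] * sv[None, :]
            ll = (y[None, :] * eta - np.logaddexp(0.0, eta)).sum(axis=1)
            ll -= 0.5 * model.ridge * (b0**2 + grid**2)
            j = int(np.argmax(ll))
            if ll[j] > best[0]:
                best = (ll[j], b0, grid[j])
        assert fit.beta0 == pytest.approx(best[1], abs=0.011)
        assert fit.beta1 == pytest.approx(best[2], abs=0.011)


class TestBuildDataset:
    def test_row_count_and_abandon_definition(self, small_schedule, small_ts_cfg):
        rng = np.random.default_rng(6)
        log = agents.simulate_agent(
            small_schedule, "offer_max", rng=rng, n_session_trials=80
        )
        ds = build_dataset(log, small_schedule, small_ts_cfg, rng)
        n_blocks_entered = log.groupby("block").ngroups
        assert len(ds) == len(log) - n_blocks_entered
        # greedy offer-max abandons exactly when the goal lacks the max offer
        merged = ds[["block", "trial", "abandon"]].merge(
            log[["block", "trial", "offer_A", "offer_B", "offer_C", "current_good"]],
            on=["block", "trial"],
        )
        offers = merged[["offer_A", "offer_B", "offer_C"]].to_numpy()
        goal_idx = merged["current_good"].map({"A": 0, "B": 1, "C": 2}).to_numpy()
        goal_is_max = offers[np.arange(len(merged)), goal_idx] >= offers.max(axis=1)
        assert (merged["abandon"].to_numpy() == (~goal_is_max).astype(float)).all()

    def test_never_switching_agent_has_zero_abandon(self, small_schedule, small_ts_cfg):
        rng = np.random.default_rng(7)
        log = agents.simulate_agent(
            small_schedule,
            "tree_search",
            policy=("softmax", -100.0, 0.0),
            cfg=small_ts_cfg,
            rng=rng,
            n_session_trials=60,
        )
        ds = build_dataset(log, small_schedule, small_ts_cfg, rng, models=("offer_max",))
        assert (ds["abandon"] == 0).all()

    def test_corrupted_log_raises_integrity_error(self, small_schedule, small_ts_cfg):
        rng = np.random.default_rng(8)
        log = agents.simulate_agent(small_schedule, "offer_max", rng=rng, n_session_trials=30)
        log.loc[5, "offer_A"] += 1.0
        with pytest.raises(fitting.DataIntegrityError):
            build_dataset(log, small_schedule, small_ts_cfg, rng, models=("offer_max",))

    def test_logged_values_shortcut_matches_log(self, small_schedule, small_ts_cfg):
        rng = np.random.default_rng(9)
        log = agents.simulate_agent(
            small_schedule,
            "tree_search",
            policy=("softmax", -1.0, 0.8),
            cfg=small_ts_cfg,
            rng=rng,
            n_session_trials=50,
        )
        ds = dataset_from_logged_values(log)
        rows = log.dropna(subset=["abandon"])
        np.testing.assert_allclose(
            ds["sv_tree_search"].to_numpy(),
            (rows["V_altbest"] - rows["V_goal"]).to_numpy(),
        )


class TestLooCv:
    @staticmethod
    def _toy_dataset(rng, n_pid=6, n_trials=200):
        frames = []
        for i in range(n_pid):
            sv = rng.normal(0.0, 2.0, n_trials)
            noise = rng.normal(0.0, 2.0, n_trials)
            y = (rng.random(n_trials) < agents.sigmoid(-1.0 + 1.2 * sv)).astype(float)
            frames.append(
                pd.DataFrame(
                    {
                        "pid": f"p{i}",
                        "abandon": y,
                        "sv_tree_search": sv,
                        "sv_offer_max": noise,  # uninformative comparator
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def test_generating_predictor_wins(self):
        rng = np.random.default_rng(10)
        cv = loo_cv_compare(
            self._toy_dataset(rng), models=("tree_search", "offer_max")
        )
        assert cv.mean_accuracy["tree_search"] > cv.mean_accuracy["offer_max"]
        assert ((cv.accuracy >= 0) & (cv.accuracy <= 1)).all().all()

    def test_all_persist_participant_scores_near_one(self):
        rng = np.random.default_rng(11)
        ds = self._toy_dataset(rng)
        quiet = pd.DataFrame(
            {
                "pid": "quiet",
                "abandon": np.zeros(100),
                "sv_tree_search": np.full(100, -8.0),
                "sv_offer_max": rng.normal(size=100),
            }
        )
        cv = loo_cv_compare(pd.concat([ds, quiet], ignore_index=True),
                            models=("tree_search",))
        assert cv.accuracy.loc["quiet", "tree_search"] > 0.97

    def test_requires_two_participants(self):
        ds = self._toy_dataset(np.random.default_rng(0), n_pid=1)
        with pytest.raises(ValueError):
            loo_cv_compare(ds)


class TestRecovery:
    def test_smoke_recovery_report(self, small_schedule, small_ts_cfg):
        from goalpursuit import synthetic_cohort

        hyper = synthetic_cohort.CohortHyperparams(
            n=5, atten_cur_mean=0, atten_cur_sd=0, atten_gap_mean=0, atten_gap_sd=0
        )
        report = fitting.recover_parameters(
            hyper,
            small_schedule,
            np.random.default_rng(12),
            ts_cfg=small_ts_cfg,
            n_session_trials=120,
        )
        assert report.true_ip.size >= 3
        assert np.isfinite(report.ip_pearson)
        assert "Parameter recovery" in report.summary()

    def test_deterministic_choices_skip_recovery(self, small_schedule, small_ts_cfg):
        from goalpursuit import synthetic_cohort

        hyper = synthetic_cohort.CohortHyperparams(
            n=4,
            ip_mean=60.0,  # biases beyond any sv: nobody ever abandons
            ip_sd=0.1,
            atten_cur_mean=0,
            atten_cur_sd=0,
            atten_gap_mean=0,
            atten_gap_sd=0,
        )
        with pytest.warns(UserWarning):
            with pytest.raises(fitting.RecoverySkipped):
                fitting.recover_parameters(
                    hyper,
                    small_schedule,
                    np.random.default_rng(13),
                    ts_cfg=small_ts_cfg,
                    n_session_trials=60,
                )
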