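"""Cox fitting, diagnostics and IPCW performance metrics."""

import numpy as np
import pandas as pd
import pytest

import imnlr
from imnlr import survival as sv

from oracles import cox_mle_1d

# Six-record fixture: distinct times, one censored record, and a covariate
# mixed across early/late deaths so the partial-likelihood MLE is finite.
TINY = pd.DataFrame(
    {
        "time": [2.0, 3.0, 5.0, 7.0, 11.0, 13.0],
        "event": [1, 1, 0, 1, 1, 1],
        "x": [0, 1, 0, 1, 1, 0],
    },
    index=[f"S{i}" for i in range(6)],
)


def _two_group_records(rng, n_per_group, hr, censor=False):
    x = np.repeat([0, 1], n_per_group)
    t = rng.exponential(1.0 / (0.1 * hr**x))
    event = np.ones_like(x)
    if censor:
        c = rng.exponential(15.0, size=len(x))
        event = (t <= c).astype(int)
        t = np.minimum(t, c)
    return pd.DataFrame({"time": t, "event": event, "x": x})


class TestCoxFit:
    def test_tiny_fixture_matches_brute_force_mle(self):
        fit = imnlr.fit_cox(TINY, ["x"])
        oracle = cox_mle_1d(TINY["time"], TINY["event"], TINY["x"])
        assert fit.summary.loc["x", "coef"] == pytest.approx(oracle, abs=1e-6)

    def test_hr_recovery_under_planted_effect(self):
        rng = np.random.default_rng(42)
        hrs = [
            imnlr.fit_cox(_two_group_records(rng, 200, 2.0), ["x"])
            .summary.loc["x", "hr"]
            for _ in range(100)
        ]
        assert 1.9 <= np.mean(hrs) <= 2.1

    def test_wald_ci_coverage_for_null_covariate(self):
        rng = np.random.default_rng(43)
        covered = 0
        reps = 200
        for _ in range(reps):
            rec = _two_group_records(rng, 60, 1.0, censor=True)
            s = imnlr.fit_cox(rec, ["x"]).summary.loc["x"]
            covered += s["hr_lower"] <= 1.0 <= s["hr_upper"]
        assert 0.90 <= covered / reps <= 0.98

    def test_rejects_constant_covariate_and_no_events(self):
        rec = TINY.copy()
        rec["z"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            imnlr.fit_cox(rec, ["z"])
        dead = TINY.assign(event=0)
        with pytest.raises(ValueError, match="event"):
            imnlr.fit_cox(dead, ["x"])

    def test_record_order_invariance(self, survival_records):
        covs = ["age", "male", "tert_only", "mdnlr_high"]
        a = imnlr.fit_cox(survival_records, covs).summary
        shuffled = survival_records.sample(frac=1.0, random_state=0)
        b = imnlr.fit_cox(shuffled, covs).summary
        pd.testing.assert_frame_equal(a, b, atol=1e-10, check_exact=False)


class TestProportionality:
    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(44)
        reps, rejections = 200, 0
        for _ in range(reps):
            rec = _two_group_records(rng, 75, 2.0, censor=True)
            fit = imnlr.fit_cox(rec, ["x"])
            p = imnlr.test_proportionality(fit, rec).loc["GLOBAL", "p"]
            rejections += p < 0.05
        assert 0.02 <= rejections / reps <= 0.08

    def test_detects_planted_time_varying_effect(self):
        rng = np.random.default_rng(45)
        reps, hits = 100, 0
        for _ in range(reps):
            # effect flips sign at the time median: early hazard ratio e,
            # late hazard ratio 1/e
            n = 300
            x = rng.integers(0, 2, n)
            t0 = 5.0
            rate1 = 0.1 * np.exp(1.0 * x)
            t = rng.exponential(1.0 / rate1)
            late = t > t0
            rate2 = 0.1 * np.exp(-1.0 * x[late])
            t[late] = t0 + rng.exponential(1.0 / rate2)
            rec = pd.DataFrame({"time": t, "event": 1, "x": x})
            fit = imnlr.fit_cox(rec, ["x"])
            p = imnlr.test_proportionality(fit, rec).loc["x", "p"]
            hits += p < 0.05
        assert hits / reps >= 0.8

    def test_single_covariate_global_equals_marginal(self, survival_records):
        fit = imnlr.fit_cox(survival_records, ["mdnlr_high"])
        table = imnlr.test_proportionality(fit, survival_records)
        assert table.loc["GLOBAL", "chi2"] == pytest.approx(
            table.loc["mdnlr_high", "chi2"], abs=1e-8
        )

    def test_rejects_too_few_events(self):
        rec = TINY.copy()
        rec["event"] = [1, 1, 0, 0, 0, 0]
        fit = imnlr.fit_cox(rec, ["x"])
        with pytest.raises(ValueError, match="3 events"):
            imnlr.test_proportionality(fit, rec)


class TestConcordance:
    def test_perfectly_anti_ordered_scores(self):
        t = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        scores = np.array([1.0, 2.0, 3.0, 4.0, 5.0])  # higher risk dies first
        c, se, n_pairs = imnlr.concordance_index(scores, t, np.ones(5, dtype=int))
        assert c == 1.0
        assert n_pairs == 10

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(46)
        cs = []
        for _ in range(200):
            t = rng.exponential(1.0, 100)
            c, _, _ = imnlr.concordance_index(rng.normal(size=100), t, np.ones(100))
            cs.append(c)
        assert abs(np.mean(cs) - 0.5) < 0.02

    def test_four_record_fixture_hand_enumerated(self):
        # comparable pairs: (t1,e1) vs t2,t3,t4 and (t3,e1) vs t4 -> 4 pairs;
        # scores 4,3,2,2.5 with times 1,2,3,4 (record at t2 censored):
        # concordant 3, discordant 1 -> c = 0.75
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 1, 1])
        scores = np.array([4.0, 3.0, 2.0, 2.5])
        c, se, n_pairs = imnlr.concordance_index(scores, t, e)
        assert n_pairs == 4
        assert c == pytest.approx(0.75)

    def test_matches_lifelines_on_random_data(self):
        from lifelines.utils import concordance_index as ll_cindex

        rng = np.random.default_rng(47)
        t = rng.exponential(1.0, 150)
        e = rng.integers(0, 2, 150)
        s = rng.normal(size=150)
        c, _, _ = imnlr.concordance_index(s, t, e)
        # lifelines orients by predicted survival time (negate the risk)
        assert c == pytest.approx(ll_cindex(t, -s, e), abs=1e-12)

    def test_no_comparable_pairs_undefined(self):
        c, se, n_pairs = imnlr.concordance_index([1.0, 2.0], [5.0, 5.0], [0, 0])
        assert np.isnan(c)
        assert n_pairs == 0


class TestBrier:
    def test_perfect_predictions_score_zero(self):
        rec = pd.DataFrame({"time": [1.0, 2.0, 10.0, 11.0], "event": 1,
                            "x": [1, 1, 0, 0]})
        surv = pd.DataFrame(
            {i: [0.0, 0.0] if rec.loc[i, "x"] else [1.0, 1.0] for i in rec.index},
            index=[3.0, 5.0],
        )
        scores, integrated = imnlr.brier_score(surv, rec, [3.0, 5.0])
        assert (scores == 0.0).all()
        assert integrated == 0.0

    def test_constant_half_prediction_is_quarter(self):
        rec = pd.DataFrame({"time": np.arange(1.0, 21.0), "event": 1})
        surv = pd.DataFrame(np.full((1, 20), 0.5), index=[10.5], columns=rec.index)
        scores, _ = imnlr.brier_score(surv, rec, [10.5])
        assert scores.loc[10.5] == pytest.approx(0.25)

    def test_censored_fixture_matches_hand_computation(self):
        # censoring KM: G drops to 0.8 at t=4 and 0.4 at t=10; at t=5 the
        # single early death weighs 1/G(2-)=1 and four at-risk subjects
        # weigh 1/G(5)=1/0.8: (0.36 + 4*0.16/0.8)/6 = 0.193333
        rec = pd.DataFrame(
            {"time": [2.0, 4.0, 6.0, 8.0, 10.0, 12.0],
             "event": [1, 0, 1, 1, 0, 1]}
        )
        surv = pd.DataFrame(np.full((1, 6), 0.6), index=[5.0], columns=rec.index)
        scores, _ = imnlr.brier_score(surv, rec, [5.0])
        assert scores.loc[5.0] == pytest.approx(0.193333, abs=1e-6)

    def test_matches_scikit_survival(self, survival_records):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        rec = survival_records
        fit = imnlr.fit_cox(rec, ["age", "tert_only", "mdnlr_high"])
        times = np.quantile(rec.loc[rec.event == 1, "time"], [0.2, 0.4, 0.6])
        surv = fit.predict_survival(rec, times)
        ours, _ = imnlr.brier_score(surv, rec, times)
        y = np.array(
            [(bool(e), t) for e, t in zip(rec["event"], rec["time"])],
            dtype=[("event", "?"), ("time", "<f8")],
        )
        _, theirs = sksurv_metrics.brier_score(y, y, surv.to_numpy().T, times)
        np.testing.assert_allclose(ours.to_numpy(), theirs, atol=1e-10)


class TestTimeDependentAuroc:
    def test_perfect_separation_gives_one(self):
        rec = pd.DataFrame({"time": [1.0, 2.0, 8.0, 9.0], "event": 1})
        scores = np.array([10.0, 9.0, 1.0, 0.5])
        aucs, summary = imnlr.time_dependent_auroc(scores, rec, [3.0, 5.0])
        assert (aucs == 1.0).all()
        assert summary == 1.0

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(48)
        means = []
        for _ in range(200):
            rec = pd.DataFrame({"time": rng.exponential(1.0, 80), "event": 1})
            _, summary = imnlr.time_dependent_auroc(
                rng.normal(size=80), rec, [np.median(rec["time"])]
            )
            means.append(summary)
        assert abs(np.mean(means) - 0.5) < 0.02

    def test_equals_pair_enumeration_when_uncensored(self):
        rng = np.random.default_rng(49)
        rec = pd.DataFrame({"time": rng.exponential(1.0, 40), "event": 1})
        scores = rng.normal(size=40)
        t = np.sort(rec["time"])[-2] + 1e-9  # largest evaluable time
        aucs, _ = imnlr.time_dependent_auroc(scores, rec, [t])
        cases = rec["time"].to_numpy() <= t
        rc, rk = scores[cases], scores[~cases]
        direct = ((rc[:, None] > rk[None, :]).mean()
                  + 0.5 * (rc[:, None] == rk[None, :]).mean())
        assert aucs.iloc[0] == pytest.approx(direct, abs=1e-12)

    def test_matches_scikit_survival(self, survival_records):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        rec = survival_records
        fit = imnlr.fit_cox(rec, ["age", "tert_only", "mdnlr_high"])
        scores = fit.risk_score(rec).to_numpy()
        times = np.quantile(rec.loc[rec.event == 1, "time"], [0.25, 0.5])
        ours, _ = imnlr.time_dependent_auroc(scores, rec, times)
        y = np.array(
            [(bool(e), t) for e, t in zip(rec["event"], rec["time"])],
            dtype=[("event", "?"), ("time", "<f8")],
        )
        theirs, _ = sksurv_metrics.cumulative_dynamic_auc(y, y, scores, times)
        np.testing.assert_allclose(ours.to_numpy(), theirs, atol=1e-10)


class TestLikelihoodRatio:
    def test_identical_models_give_zero(self, survival_records):
        a = imnlr.fit_cox(survival_records, ["age", "tert_only"])
        b = imnlr.fit_cox(survival_records, ["age", "tert_only"])
        stat, df, p = imnlr.likelihood_ratio_test(a, b)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == 1.0

    def test_null_covariate_p_uniform(self):
        rng = np.random.default_rng(50)
        reps, rejections = 200, 0
        for _ in range(reps):
            rec = _two_group_records(rng, 60, 2.0, censor=True)
            rec["noise"] = rng.normal(size=len(rec))
            full = imnlr.fit_cox(rec, ["x", "noise"])
            nested = imnlr.fit_cox(rec, ["x"])
            rejections += imnlr.likelihood_ratio_test(full, nested)[2] < 0.05
        assert 0.02 <= rejections / reps <= 0.08

    def test_power_against_planted_effect(self):
        rng = np.random.default_rng(51)
        reps, hits = 100, 0
        for _ in range(reps):
            rec = _two_group_records(rng, 150, 2.0, censor=True)
            rec["noise"] = rng.normal(size=len(rec))
            full = imnlr.fit_cox(rec, ["noise", "x"])
            nested = imnlr.fit_cox(rec, ["noise"])
            hits += imnlr.likelihood_ratio_test(full, nested)[2] < 0.05
        assert hits / reps >= 0.8

    def test_rejects_non_nested(self, survival_records):
        a = imnlr.fit_cox(survival_records, ["age"])
        b = imnlr.fit_cox(survival_records, ["tert_only"])
        with pytest.raises(ValueError, match="nested"):
            imnlr.likelihood_ratio_test(a, b)


class TestKaplanMeier:
    def test_uncensored_steps_and_median(self):
        rec = pd.DataFrame({"time": np.arange(1.0, 11.0), "event": 1})
        km = imnlr.kaplan_meier(rec)
        curve = km["curves"]["all"]
        assert curve.loc[5.0] == pytest.approx(0.5)
        assert km["median"]["all"] == 5.0  # first time with S <= 0.5

    def test_all_censored_median_not_reached(self):
        rec = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": 0})
        km = imnlr.kaplan_meier(rec)
        assert np.isinf(km["median"]["all"])

    def test_log_rank_power_for_rate_ratio_two(self):
        rng = np.random.default_rng(52)
        hits = 0
        reps = 50
        for _ in range(reps):
            rec = _two_group_records(rng, 200, 2.0)
            rec["g"] = np.where(rec["x"] == 1, "fast", "slow")
            km = imnlr.kaplan_meier(rec, group_by="g")
            hits += km["logrank_p"] < 0.05
        assert hits / reps >= 0.9
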