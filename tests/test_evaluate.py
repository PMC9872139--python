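"""Signature evaluation: concordance, R^2, cutoff, KM/log-rank, AUC, calibration."""

import numpy as np
import pandas as pd
import pytest

from snvsig import evaluate as ev
from snvsig.genotype import SurvivalData

from conftest import make_surv


def brute_force_c(time, event, score):
    """O(n^2) pure-loop Harrell concordance: independent oracle."""
    conc = usable = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if event[i] == 1 and (time[i] < time[j] or (time[i] == time[j] and event[j] == 0)):
                usable += 1
                if score[i] > score[j]:
                    conc += 1
                elif score[i] == score[j]:
                    conc += 0.5
    return conc / usable


class TestHarrellC:
    def test_perfect_ordering(self):
        surv = make_surv([1, 2, 3], [1, 1, 1])
        assert ev.harrell_c(surv, np.array([3.0, 2.0, 1.0]))["c"] == 1.0

    def test_constant_score_is_half(self):
        surv = make_surv([1, 2, 3, 4], [1, 1, 1, 0])
        assert ev.harrell_c(surv, np.zeros(4))["c"] == 0.5

    def test_matches_brute_force_on_random_censored_data(self, rng):
        for _ in range(10):
            n = 50
            t = np.round(rng.exponential(5, n), 1) + 0.1  # induce ties
            e = (rng.random(n) < 0.7).astype(int)
            s = np.round(rng.standard_normal(n), 1)
            surv = make_surv(t, e)
            mine = ev.harrell_c(surv, s)["c"]
            assert np.isclose(mine, brute_force_c(t, e, s))

    def test_agrees_with_scikit_survival(self, rng):
        from sksurv.metrics import concordance_index_censored

        n = 80
        t = rng.exponential(5, n)
        e = (rng.random(n) < 0.7).astype(int)
        s = rng.standard_normal(n)
        surv = make_surv(t, e)
        ref = concordance_index_censored(e.astype(bool), t, s)[0]
        assert np.isclose(ev.harrell_c(surv, s)["c"], ref)

    def test_standard_error_magnitude(self, censored_surv):
        surv, x = censored_surv
        res = ev.harrell_c(surv, x)
        # bootstrap reference for the SE of C
        rng = np.random.default_rng(1)
        boots = []
        for _ in range(300):
            idx = rng.integers(0, len(x), len(x))
            try:
                boots.append(ev.harrell_c(surv.subset(idx), x[idx])["c"])
            except ValueError:
                pass
        assert 0.5 * np.std(boots) < res["se"] < 2.0 * np.std(boots)

    def test_no_usable_pairs_is_an_error(self):
        with pytest.raises(ValueError):
            ev.harrell_c(make_surv([1, 2], [0, 0]), np.array([1.0, 2.0]))


class TestNagelkerkeR2:
    def test_null_fit_gives_zero(self):
        out = ev.nagelkerke_r2(-100.0, -100.0, 50)
        assert out["nagelkerke"] == 0.0 and out["cox_snell"] == 0.0

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            l0 = -float(rng.uniform(50, 200))
            l1 = l0 + float(rng.uniform(0, 40))
            out = ev.nagelkerke_r2(l0, l1, 100)
            assert 0.0 <= out["cox_snell"] <= out["nagelkerke"] <= 1.0

    def test_increases_with_simulated_effect_size(self):
        from lifelines import CoxPHFitter

        r2s = []
        rng = np.random.default_rng(3)
        n = 400
        x = rng.standard_normal(n)
        for beta in (0.0, 0.5, 1.0, 2.0):
            t = rng.exponential(1, n) * np.exp(-beta * x)
            surv = make_surv(t, np.ones(n, int))
            cph = CoxPHFitter().fit(pd.DataFrame({"x": x, "time": t, "event": 1}), "time", "event")
            r2s.append(ev.nagelkerke_r2(ev.cox_null_loglik(surv), cph.log_likelihood_, n)["nagelkerke"])
        assert all(np.diff(r2s) > 0)

    def test_below_null_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            out = ev.nagelkerke_r2(-50.0, -51.0, 30)
        assert out["nagelkerke"] == 0.0


class TestSignatureAndStepAIC:
    def _sim(self, seed=0, n=300, noise_cols=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 2 + noise_cols))
        eta = 1.0 * X[:, 0] - 1.0 * X[:, 1]
        t = rng.exponential(1, n) * np.exp(-eta)
        c = rng.exponential(3, n)
        surv = make_surv(np.minimum(t, c), (t <= c).astype(int))
        cols = ["f1", "f2"] + [f"noise{i}" for i in range(noise_cols)]
        return pd.DataFrame(X, columns=cols), surv

    def test_score_is_centered_and_order_preserving(self):
        feats, surv = self._sim()
        sig = ev.fit_signature(feats, surv)
        assert abs(sig.score.mean()) < 1e-10
        xb = feats.to_numpy() @ sig.coef.to_numpy()
        assert np.array_equal(np.argsort(xb), np.argsort(sig.score))

    def test_single_feature_score_is_centered_feature_times_beta(self):
        feats, surv = self._sim()
        sig = ev.fit_signature(feats[["f1"]], surv)
        beta = sig.coef["f1"]
        expected = beta * (feats["f1"] - feats["f1"].mean())
        assert np.allclose(sig.score, expected)

    def test_collinear_feature_dropped_with_warning(self):
        feats, surv = self._sim()
        feats = feats.copy()
        feats["dup"] = 2.0 * feats["f1"]
        with pytest.warns(UserWarning, match="collinear"):
            sig = ev.fit_signature(feats, surv)
        assert "dup" not in sig.feature_ids

    def test_stepwise_aic_removes_noise_keeps_signal(self):
        # a pure-noise covariate survives backward-AIC only when its Wald z
        # exceeds ~1.4 by chance (~16% of replicates); signal always stays
        removed = 0
        for seed in range(20):
            feats, surv = self._sim(seed=seed, n=500, noise_cols=1)
            kept, fit = ev.stepwise_aic(feats, surv)
            assert {"f1", "f2"} <= set(kept)
            if "noise0" not in kept:
                removed += 1
        assert removed >= 12  # clear majority of seeds

    def test_stepwise_aic_never_increases_aic_and_is_stable_on_minimal_model(self):
        feats, surv = self._sim(n=400)
        full = ev._fit_cox(feats, surv)
        kept, fit = ev.stepwise_aic(feats, surv)
        assert fit.AIC_partial_ <= full.AIC_partial_
        kept2, fit2 = ev.stepwise_aic(feats[kept], surv)
        assert kept2 == kept


class TestCvEvaluate:
    def test_null_score_gives_chance_c(self):
        rng = np.random.default_rng(5)
        n = 250
        feats = pd.DataFrame({"x": rng.standard_normal(n)})
        t = rng.exponential(1, n)
        surv = make_surv(t, (rng.random(n) < 0.8).astype(int))
        out = ev.cv_evaluate(feats, surv, k=5, seed=1, use_stepwise_aic=False)
        assert abs(out["c_mean"] - 0.5) < 0.08

    def test_perfect_separation_reaches_c_one(self):
        n = 100
        t = np.linspace(1, 10, n)
        feats = pd.DataFrame({"x": -t})  # risk score reproduces -time exactly
        surv = make_surv(t, np.ones(n, int))
        out = ev.cv_evaluate(feats, surv, k=5, seed=2, use_stepwise_aic=False)
        assert out["c_mean"] > 0.99

    def test_fold_count_and_dispersion_fields(self):
        rng = np.random.default_rng(9)
        n = 120
        feats = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.standard_normal(n)})
        t = rng.exponential(1, n)
        surv = make_surv(t, (rng.random(n) < 0.7).astype(int))
        out = ev.cv_evaluate(feats, surv, k=4, seed=3)
        assert len(out["c_per_fold"]) == 4
        assert np.isclose(out["c_se"], out["c_sd"] / 2.0)


class TestOptimalCutoff:
    def test_cutoff_falls_between_separated_groups(self):
        rng = np.random.default_rng(11)
        n = 100
        score = np.r_[rng.normal(-2, 0.3, n // 2), rng.normal(2, 0.3, n // 2)]
        # survival times that do not overlap between the two risk groups
        t = np.r_[rng.uniform(5, 10, n // 2), rng.uniform(0.1, 1.0, n // 2)]
        surv = make_surv(t, np.ones(n, int))
        out = ev.optimal_cutoff(score, surv)
        assert -1.0 < out["cutoff"] < 1.0

    def test_minprop_half_leaves_only_median_boundary(self, rng):
        score = rng.standard_normal(40)
        t = rng.exponential(1, 40)
        surv = make_surv(t, np.ones(40, int))
        out = ev.optimal_cutoff(score, surv, minprop=0.5)
        assert len(out["candidates"]) == 1
        s = np.sort(score)
        assert s[19] < out["cutoff"] < s[20]

    def test_groups_respect_minprop(self, rng):
        score = rng.standard_normal(60)
        t = rng.exponential(1, 60)
        surv = make_surv(t, (rng.random(60) < 0.8).astype(int))
        out = ev.optimal_cutoff(score, surv, minprop=0.2)
        high = (score > out["cutoff"]).sum()
        assert high >= 12 and 60 - high >= 12

    def test_constant_scores_rejected(self):
        surv = make_surv([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError):
            ev.optimal_cutoff(np.ones(3), surv)

    def test_maxstat_z_matches_lifelines_logrank_chi2(self, rng):
        # dual route: the internal standardized statistic squared equals the
        # lifelines log-rank chi2 for the same split
        from snvsig.evaluate import _logrank_z

        n = 60
        t = rng.exponential(1, n)
        e = (rng.random(n) < 0.8).astype(int)
        g = rng.random(n) < 0.4
        z = _logrank_z(t, e, g)
        surv = make_surv(t, e)
        ref = ev.logrank_test(surv, np.where(g, "a", "b"))
        assert np.isclose(z**2, ref["chi2"], rtol=1e-6)


class TestKaplanMeierAndLogrank:
    def test_km_matches_hand_worked_six_point_table(self):
        surv = make_surv([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 1])
        curves = ev.km_estimate(surv, np.zeros(6, int))
        est = curves[0].set_index("time")["estimate"]
        assert np.isclose(est.loc[1.0], 5 / 6)
        assert np.isclose(est.loc[2.0], 5 / 6 * 4 / 5)
        assert np.isclose(est.loc[4.0], 5 / 6 * 4 / 5 * 2 / 3)
        assert np.isclose(est.loc[6.0], 0.0)

    def test_km_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(1, 40)
        surv = make_surv(t, np.ones(40, int))
        curves = ev.km_estimate(surv, np.zeros(40, int))
        df = curves[0]
        for _, row in df.iloc[1:].iterrows():
            assert np.isclose(row["estimate"], np.mean(t > row["time"]))

    def test_km_all_censored_stays_at_one(self):
        surv = make_surv([1, 2, 3], [0, 0, 0])
        curves = ev.km_estimate(surv, np.zeros(3, int))
        assert (curves[0]["estimate"] == 1.0).all()

    def test_logrank_duplicated_group_chi2_zero(self):
        t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        surv = make_surv(t, e)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        out = ev.logrank_test(surv, groups)
        assert out["chi2"] < 1e-10 and out["p"] > 0.999

    def test_logrank_null_p_roughly_uniform(self):
        rng = np.random.default_rng(17)
        ps = []
        for _ in range(200):
            t = rng.exponential(1, 40)
            e = (rng.random(40) < 0.8).astype(int)
            g = np.where(rng.random(40) < 0.5, "a", "b")
            if len(np.unique(g)) < 2:
                continue
            ps.append(ev.logrank_test(make_surv(t, e), g)["p"])
        assert 0.30 < np.mean(np.array(ps) < 0.5) < 0.70
        assert abs(np.mean(np.array(ps) < 0.05) - 0.05) < 0.06

    def test_logrank_strong_separation_is_significant(self):
        rng = np.random.default_rng(19)
        t = np.r_[rng.exponential(5, 50), rng.exponential(0.5, 50)]
        surv = make_surv(t, np.ones(100, int))
        g = np.array(["low"] * 50 + ["high"] * 50)
        assert ev.logrank_test(surv, g)["p"] < 1e-4


class TestTimeDependentAUC:
    def test_no_censoring_equals_plain_auc(self, rng):
        from sklearn.metrics import roc_auc_score

        n = 150
        score = rng.standard_normal(n)
        t = rng.exponential(1, n) * np.exp(-score)
        surv = make_surv(t, np.ones(n, int))
        tq = float(np.quantile(t, 0.4))
        out = ev.time_dependent_auc(score, surv, times=np.array([tq]), n_boot=10, seed=0)
        ref = roc_auc_score((t <= tq).astype(int), score)
        assert np.isclose(out["auc"].iloc[0], ref, atol=1e-9)

    def test_random_score_near_half(self, rng):
        n = 200
        t = rng.exponential(1, n)
        surv = make_surv(t, (rng.random(n) < 0.8).astype(int))
        out = ev.time_dependent_auc(rng.standard_normal(n), surv, n_boot=10, seed=1)
        assert np.all(np.abs(out["auc"] - 0.5) < 0.15)

    def test_monotone_risk_gives_high_auc_at_all_times(self, rng):
        n = 300
        score = rng.standard_normal(n)
        t = rng.exponential(1, n) ** 0.3 * np.exp(-2.0 * score)
        c = rng.exponential(np.median(t) * 3, n)
        surv = make_surv(np.minimum(t, c), (t <= c).astype(int))
        out = ev.time_dependent_auc(score, surv, n_boot=20, seed=2)
        assert np.all(out["auc"] > 0.8)

    def test_times_beyond_follow_up_dropped(self, rng):
        n = 50
        t = rng.exponential(1, n)
        surv = make_surv(t, np.ones(n, int))
        with pytest.warns(UserWarning, match="follow-up"):
            out = ev.time_dependent_auc(
                rng.standard_normal(n), surv, times=np.array([np.median(t), t.max() * 10]),
                n_boot=5, seed=3,
            )
        assert len(out) == 1


class TestBreslowAndCalibration:
    def test_null_model_reduces_to_nelson_aalen(self, rng):
        from lifelines import NelsonAalenFitter

        t = rng.exponential(1, 60)
        e = (rng.random(60) < 0.7).astype(int)
        surv = make_surv(t, e)
        base = ev.breslow_baseline(np.zeros(60), surv)
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False).fit(t, e)
        ref = naf.cumulative_hazard_.loc[base["time"], "NA_estimate"].to_numpy()
        assert np.allclose(base["cumhaz"].to_numpy(), ref)

    def test_predicted_survival_starts_at_one_and_decreases(self, censored_surv):
        surv, x = censored_surv
        base = ev.breslow_baseline(x - x.mean(), surv)
        S = ev.predict_survival(base, np.array([0.0]), np.r_[0.0, base["time"].to_numpy()])
        assert S[0, 0] == 1.0
        assert np.all(np.diff(S[0]) <= 1e-12)

    def test_baseline_is_nondecreasing_step_function(self, censored_surv):
        surv, x = censored_surv
        base = ev.breslow_baseline(x, surv)
        assert np.all(np.diff(base["cumhaz"]) >= 0)

    def test_perfect_predictions_have_zero_deviation(self):
        surv = make_surv([1, 2, 3, 4], [1, 1, 1, 1])
        groups = np.zeros(4, int)
        times = np.array([1.0, 2.0, 3.0])
        km = ev.km_estimate(surv, groups)[0].set_index("time")["estimate"]
        pred = np.tile(km.loc[times].to_numpy(), (4, 1))
        table = ev.calibration(pred, surv, groups, times)
        assert np.allclose(table["deviation"], 0.0)
        assert np.all(table["deviation"].abs() <= 1.0)

    def test_well_specified_simulation_calibrates_within_ci(self):
        rng = np.random.default_rng(23)
        n = 400
        x = rng.standard_normal(n)
        t = rng.exponential(1, n) * np.exp(-x)
        c = rng.exponential(3, n)
        surv = make_surv(np.minimum(t, c), (t <= c).astype(int))
        lp = x - x.mean()
        base = ev.breslow_baseline(lp, surv)
        groups = np.where(lp > 0, "high", "low")
        times = np.quantile(surv.time, [0.2, 0.4, 0.6])
        pred = ev.predict_survival(base, lp, times)
        table = ev.calibration(pred, surv, groups, times)
        inside = (table["predicted"] >= table["obs_lower"]) & (table["predicted"] <= table["obs_upper"])
        assert inside.mean() >= 0.8


def test_evaluate_signature_full_report(censored_surv):
    surv, x = censored_surv
    rng = np.random.default_rng(31)
    feats = pd.DataFrame({"f1": x, "f2": rng.standard_normal(len(x))})
    report = ev.evaluate_signature(feats, surv, cv_folds=3, seed=0, full=True)
    s = report.summary()
    assert 0.0 <= s["apparent_c"] <= 1.0
    assert 0.0 <= s["r2_nagelkerke"] <= 1.0
    assert "cv_c_mean" in s
    assert report.groups is not None and set(report.groups) == {"high", "low"}
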