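"""Maximum-entropy model: features, fit, prediction, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from entrange.maxent import (MaxentModel, auc_rank, build_features,
                             cross_validate, jackknife_gain, mtsps_threshold)


def _tables(rng, n_pres=60, n_bg=300, n_var=3, signal=None):
    """Background ~ N(0,1); presences drawn by a logistic tilt on var_0."""
    bg = pd.DataFrame(rng.normal(size=(n_bg, n_var)),
                      columns=[f"v{i}" for i in range(n_var)])
    if signal is None:
        pres = bg.sample(n=n_pres, random_state=1).reset_index(drop=True)
    else:
        pool = pd.DataFrame(rng.normal(size=(n_bg * 30, n_var)),
                            columns=bg.columns)
        p = 1 / (1 + np.exp(-(signal * pool["v0"] - 1.0)))
        pick = rng.random(len(pool)) < p
        pres = pool[pick].head(n_pres).reset_index(drop=True)
    return pres, bg


class TestFeatureCounts:
    @pytest.mark.parametrize("fc,expected", [("L", 5), ("LQ", 10)])
    def test_linear_quadratic(self, fc, expected, rng):
        bg = pd.DataFrame(rng.normal(size=(50, 5)),
                          columns=list("abcde"))
        assert len(build_features(bg, fc, n_knots=10)) == expected

    def test_lqhp_five_vars_ten_knots(self, rng):
        # 5 linear + 5 quadratic + 10 pairs + 5 vars * 2 directions * 10 knots
        bg = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
        assert len(build_features(bg, "LQHP", n_knots=10)) == 120

    def test_threshold_class_counts(self, rng):
        bg = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        assert len(build_features(bg, "T", n_knots=7)) == 14

    def test_unknown_letter_rejected(self, rng):
        bg = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="letters"):
            build_features(bg, "LX")

    def test_features_bounded_zero_one_with_clamping(self, rng):
        bg = pd.DataFrame(rng.normal(size=(80, 3)), columns=["a", "b", "c"])
        fs = build_features(bg, "LQHPT", n_knots=6)
        wild = pd.DataFrame(rng.normal(scale=50, size=(40, 3)),
                            columns=["a", "b", "c"])
        F = fs.transform(wild, clamp=True)
        assert F.min() >= 0.0 and F.max() <= 1.0

    def test_hinge_threshold_knots_inside_training_range(self, rng):
        bg = pd.DataFrame(rng.normal(size=(80, 2)), columns=["a", "b"])
        fs = build_features(bg, "HT", n_knots=9)
        assert all(0.0 < d.knot < 1.0 for d in fs.defs)


class TestFit:
    def test_raw_background_scores_sum_to_one(self, results):
        assert results._raw_background.sum() == pytest.approx(1.0, abs=1e-9)
        # and through the public raw-prediction path on the training table
        raw = results.predict(results.model._bg_all, mode="raw")
        assert raw.sum() == pytest.approx(1.0, abs=1e-9)

    def test_full_shrinkage_limit_uniform(self, rng):
        pres, bg = _tables(rng, signal=2.0)
        res = MaxentModel(pres, bg, fc="LQ", rm=1e6, n_knots=5).fit()
        assert res.n_nonzero == 0
        assert res.entropy == pytest.approx(np.log(len(res.model._bg_all)))
        raw = res.predict(bg, mode="raw")
        np.testing.assert_allclose(raw, raw[0])

    def test_null_presences_give_flat_model(self, rng):
        pres, bg = _tables(rng, signal=None)
        res = MaxentModel(pres, bg, fc="L", rm=1.0, n_knots=5).fit()
        s_p = res.predict(pres)
        s_b = res.predict(bg)
        assert abs(auc_rank(s_p, s_b) - 0.5) < 0.12
        assert np.abs(res.params.to_numpy()).max() < 1.0

    def test_positive_signal_recovers_positive_weight(self, rng):
        pres, bg = _tables(rng, n_pres=150, signal=2.0)
        res = MaxentModel(pres, bg, fc="L", rm=0.5, n_knots=5).fit()
        assert res.params["linear(v0)"] > 0

    def test_ranking_agrees_with_logistic_regression_oracle(self, rng):
        from scipy.stats import spearmanr
        from sklearn.linear_model import LogisticRegression
        pres, bg = _tables(rng, n_pres=150, signal=2.0)
        res = MaxentModel(pres, bg, fc="L", rm=0.05, n_knots=5).fit()
        X = pd.concat([pres, bg], ignore_index=True)
        y = np.r_[np.ones(len(pres)), np.zeros(len(bg))]
        lr = LogisticRegression(C=1e3, max_iter=2000).fit(X, y)
        rho = spearmanr(res.predict(X, mode="raw"),
                        lr.predict_proba(X)[:, 1]).statistic
        assert rho > 0.95

    def test_regularization_monotone_in_sparsity(self, rng):
        pres, bg = _tables(rng, n_pres=100, signal=2.0)
        counts = [MaxentModel(pres, bg, fc="LQH", rm=rm, n_knots=6).fit().n_nonzero
                  for rm in (0.5, 1.0, 2.0, 4.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_zero_variance_feature_set_rejected(self):
        pres = pd.DataFrame({"a": [1.0, 1.0, 1.0]})
        bg = pd.DataFrame({"a": np.ones(20)})
        with pytest.raises(ValueError, match="zero-variance"):
            MaxentModel(pres, bg, fc="L")


class TestPredict:
    def test_training_cell_scores_identically(self, results, model):
        one = model.background.iloc[[5]]
        direct = results.predict(model.background)[5]
        again = results.predict(one)[0]
        assert direct == pytest.approx(again)

    def test_logistic_in_unit_interval(self, results, model):
        s = results.predict(model.background, mode="logistic")
        assert (s > 0).all() and (s < 1).all()

    def test_monotone_response_on_ramp(self, rng):
        pres, bg = _tables(rng, n_pres=100, signal=2.0)
        res = MaxentModel(pres, bg, fc="L", rm=0.5, n_knots=5).fit()
        ramp = pd.DataFrame({"v0": np.linspace(bg["v0"].min(), bg["v0"].max(), 50),
                             "v1": 0.0, "v2": 0.0})
        s = res.predict(ramp[["v0", "v1", "v2"]], mode="logistic")
        assert np.all(np.diff(s) >= -1e-12)

    def test_missing_variable_raises(self, results):
        with pytest.raises(KeyError):
            results.predict(pd.DataFrame({"env_1": [0.0]}))


class TestAuc:
    def test_perfect_separation(self):
        assert auc_rank([5, 6, 7], [1, 2, 3]) == 1.0

    def test_all_tied(self):
        assert auc_rank([1, 1], [1, 1, 1]) == 0.5

    def test_matches_brute_force_pair_counting(self, rng):
        p = rng.normal(size=6)
        b = rng.normal(size=7)
        wins = sum((pi > bi) + 0.5 * (pi == bi) for pi in p for bi in b)
        assert auc_rank(p, b) == pytest.approx(wins / (6 * 7))

    def test_invariant_under_monotone_transform(self, rng):
        p = rng.normal(size=15)
        b = rng.normal(size=40)
        f = lambda x: np.exp(3 * np.asarray(x)) + 1
        assert auc_rank(p, b) == pytest.approx(auc_rank(f(p), f(b)))


class TestEvaluate:
    def test_or10_definition(self, results, model):
        m = results.evaluate(model.presences)
        train_scores = results.predict(model.presences)
        thr = np.percentile(train_scores, 10)
        assert m.or10 == pytest.approx(np.mean(train_scores < thr))

    def test_diff_auc_identity(self, results, model):
        m = results.evaluate(model.presences.head(40))
        assert m.diff_auc == pytest.approx(m.auc_train - m.auc_test)

    def test_aicc_formula_and_undefined_flag(self, rng):
        pres, bg = _tables(rng, n_pres=50, signal=2.0)
        res = MaxentModel(pres, bg, fc="L", rm=1.0, n_knots=5).fit()
        aicc, defined = res.aicc()
        k, n = res.n_nonzero, len(pres)
        ll = res.log_likelihood()
        assert defined
        assert aicc == pytest.approx(2 * k - 2 * ll + 2 * k * (k + 1) / (n - k - 1))
        # more parameters than presences allow -> undefined
        tiny_pres, _ = _tables(rng, n_pres=3, signal=2.0)
        res2 = MaxentModel(tiny_pres.head(3), bg, fc="LQHPT", rm=0.01,
                           n_knots=8).fit(max_iter=60)
        if res2.n_nonzero >= len(tiny_pres) - 1:
            assert not res2.aicc()[1]

    def test_empty_test_set_raises(self, results, model):
        with pytest.raises(ValueError, match="empty"):
            results.evaluate(model.presences.head(0))


class TestMtsps:
    def test_matches_exhaustive_scan_on_hand_scores(self):
        p = np.array([0.9, 0.8, 0.55, 0.3])
        b = np.array([0.6, 0.4, 0.2, 0.1])
        # brute force over every candidate cut
        cands = np.unique(np.r_[0.0, p, b])
        best = max(cands, key=lambda t: (np.mean(p > t) + np.mean(b <= t), -t))
        vals = [np.mean(p > t) + np.mean(b <= t) for t in cands]
        lowest_best = cands[np.argmax(np.isclose(vals, max(vals)))]
        got = mtsps_threshold(p, b)
        assert got == pytest.approx(lowest_best)
        assert np.mean(p > got) + np.mean(b <= got) == pytest.approx(max(vals))

    def test_perfect_separation_returns_lowest_gap_value(self):
        assert mtsps_threshold([0.7, 0.9], [0.1, 0.3]) == pytest.approx(0.3)

    def test_degenerate_single_score_flagged(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            t = mtsps_threshold([0.5, 0.5], [0.5])
        assert t == 0.5


class TestResponseCurves:
    def test_positive_linear_curve_nondecreasing(self, rng):
        pres, bg = _tables(rng, n_pres=100, signal=2.0)
        res = MaxentModel(pres, bg, fc="L", rm=0.5, n_knots=5).fit()
        curve = res.response_curve("v0", mode="marginal")
        assert np.all(np.diff(curve["logistic"]) >= -1e-12)

    def test_constant_model_flat_curve(self, rng):
        pres, bg = _tables(rng)
        res = MaxentModel(pres, bg, fc="L", rm=1e6, n_knots=5).fit()
        curve = res.response_curve("v1", mode="marginal")
        assert curve["logistic"].std() < 1e-12

    def test_curve_spans_training_range(self, results):
        fs = results.model.feature_set
        curve = results.response_curve("env_1")
        assert curve["value"].iloc[0] == pytest.approx(fs.var_min["env_1"])
        assert curve["value"].iloc[-1] == pytest.approx(fs.var_max["env_1"])

    def test_plot_response_returns_axis(self, results):
        import matplotlib
        matplotlib.use("Agg")
        ax = results.plot_response("env_1")
        assert ax.get_xlabel() == "env_1"

    def test_univariate_mode_refits(self, rng):
        pres, bg = _tables(rng, n_pres=80, signal=2.0)
        res = MaxentModel(pres, bg, fc="L", rm=0.5, n_knots=5).fit()
        curve = res.response_curve("v0", mode="univariate")
        assert curve["logistic"].iloc[-1] > curve["logistic"].iloc[0]


class TestImportance:
    def test_permutation_importance_sums_to_100(self, results):
        imp = results.permutation_importance(seed=1)
        assert imp.sum() == pytest.approx(100.0)

    def test_informative_variable_dominates_noise(self, rng):
        pres, bg = _tables(rng, n_pres=150, signal=2.5)
        res = MaxentModel(pres, bg, fc="L", rm=0.5, n_knots=5).fit()
        imp = res.permutation_importance(seed=2)
        assert imp["v0"] > 60.0
        assert imp.drop("v0").max() < imp["v0"]

    def test_percent_contribution_sums_to_100(self, results):
        pc = results.percent_contribution()
        assert pc.sum() == pytest.approx(100.0)

    def test_generating_variable_gets_most_contribution(self, results):
        pc = results.percent_contribution()
        assert pc.idxmax() in ("env_1", "env_2", "env_3")


class TestJackknife:
    def test_gains_structure(self, rng):
        pres, bg = _tables(rng, n_pres=80, n_var=2, signal=2.0)
        jk = jackknife_gain(pres, bg, fc="L", rm=1.0, n_knots=5)
        assert set(jk["variable"]) == {"v0", "v1"}
        assert (jk["full_gain"] >= -1e-9).all()

    def test_single_variable_without_gain_is_zero(self, rng):
        pres, bg = _tables(rng, n_pres=60, n_var=1, signal=2.0)
        jk = jackknife_gain(pres, bg, fc="L", rm=1.0, n_knots=5)
        assert jk["gain_without"].iloc[0] == 0.0

    def test_duplicated_decisive_variable_leaves_gain_intact(self, rng):
        pres, bg = _tables(rng, n_pres=80, n_var=1, signal=2.5)
        pres = pres.assign(v0_copy=pres["v0"])
        bg = bg.assign(v0_copy=bg["v0"])
        jk = jackknife_gain(pres, bg, fc="L", rm=1.0, n_knots=5).set_index("variable")
        full = jk["full_gain"].iloc[0]
        for v in ("v0", "v0_copy"):
            assert full - jk.loc[v, "gain_without"] < 0.15 * max(full, 1e-9)

    def test_informative_beats_noise_with_only(self, rng):
        pres, bg = _tables(rng, n_pres=100, n_var=3, signal=2.5)
        jk = jackknife_gain(pres, bg, fc="L", rm=1.0, n_knots=5).set_index("variable")
        assert jk.loc["v0", "gain_with_only"] > jk.loc["v1", "gain_with_only"]


class TestCrossValidate:
    def test_seed_controls_fold_assignment(self, rng):
        pres, bg = _tables(rng, n_pres=40, signal=2.0)
        a = cross_validate(pres, bg, fc="L", folds=4, seed=9, n_knots=5)
        b = cross_validate(pres, bg, fc="L", folds=4, seed=9, n_knots=5)
        pd.testing.assert_frame_equal(a, b)

    def test_leave_one_out_runs(self, rng):
        pres, bg = _tables(rng, n_pres=8, signal=2.0)
        cv = cross_validate(pres, bg, fc="L", folds=8, seed=0, n_knots=4)
        assert (cv["fold"] != "mean").sum() == 8

    def test_more_folds_than_presences_rejected(self, rng):
        pres, bg = _tables(rng, n_pres=5)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(pres, bg, folds=6)

    def test_strong_signal_mean_test_auc_above_08(self, signal_tables):
        pres, bg = signal_tables
        cv = cross_validate(pres, bg, fc="LQ", folds=5, seed=3, n_knots=8)
        mean = cv[cv["fold"] == "mean"].iloc[0]
        assert mean["auc_test"] > 0.8
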