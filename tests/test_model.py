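"""Prefilter, z-transform, LASSO fitting and scoring."""

import numpy as np
import pandas as pd
import pytest

from sasang_shi import model as M
from sasang_shi import published, synth


class TestPrefilter:
    def test_identical_groups_excluded_noisy_label_included(self, rng):
        healthy = np.repeat([True, False], 30)
        feats = pd.DataFrame({
            "flat": np.tile(np.arange(30.0), 2),       # same in both
            "signal": healthy + 0.01 * rng.standard_normal(60),
        })
        kept = M.prefilter_features(feats, healthy)
        assert kept == ["signal"]

    def test_matches_textbook_t_statistic(self):
        # Six subjects, hand-computed Student's t on equal variances.
        from scipy import stats

        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.5, 3.5, 4.5])
        sp2 = (np.var(a, ddof=1) * 2 + np.var(b, ddof=1) * 2) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=4)
        feats = pd.DataFrame({"x": np.concatenate([a, b])})
        healthy = np.array([True] * 3 + [False] * 3)
        kept = M.prefilter_features(feats, healthy, p_threshold=p_hand + 1e-9)
        assert kept == ["x"]
        kept2 = M.prefilter_features(feats, healthy, p_threshold=p_hand - 1e-9)
        assert kept2 == []

    def test_tiny_group_rejected(self):
        feats = pd.DataFrame({"x": np.arange(5.0)})
        with pytest.raises(ValueError):
            M.prefilter_features(feats, np.array([True] + [False] * 4))


class TestZScorer:
    def test_sample_sd_convention(self):
        z = M.ZScorer().fit_apply(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert np.allclose(z["x"], [-1.0, 0.0, 1.0])

    def test_apply_reproduces_fit_output(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 4)),
                         columns=list("abcd"))
        scaler = M.ZScorer().fit(X)
        pd.testing.assert_frame_equal(
            scaler.apply(X), scaler.fit_apply(X))

    def test_constant_column_excluded_with_warning(self):
        X = pd.DataFrame({"c": np.ones(10), "x": np.arange(10.0)})
        with pytest.warns(UserWarning, match="zero-variance"):
            z = M.ZScorer().fit_apply(X)
        assert list(z.columns) == ["x"]


class TestLasso:
    def test_zero_penalty_limit_equals_least_squares(self, rng):
        # The coordinate-descent solver at a vanishing penalty must
        # agree with the normal-equations oracle on full-rank problems.
        import warnings

        from sklearn.linear_model import Lasso

        for _ in range(10):
            X = rng.standard_normal((50, 3))
            y = X @ rng.normal(size=3) + 0.5 * rng.standard_normal(50)
            b0, b = M.ols_fit(X, y)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = Lasso(alpha=1e-12, max_iter=1_000_000, tol=1e-14)
                m.fit(X, y)
            assert abs(m.intercept_ - b0) < 1e-8
            assert np.max(np.abs(m.coef_ - b)) < 1e-8

    def test_full_shrinkage_at_top_of_grid(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 3)),
                         columns=list("abc"))
        y = X["a"].to_numpy() + 0.1 * rng.standard_normal(40)
        from sklearn.linear_model import Lasso

        alpha_max = M._lasso_path_grid(X.to_numpy(), y)[0]
        m = Lasso(alpha=alpha_max * 1.001).fit(X.to_numpy(), y)
        assert np.all(m.coef_ == 0.0)
        assert m.intercept_ == pytest.approx(y.mean())

    def test_noiseless_linear_fit_is_perfect(self, rng):
        X = pd.DataFrame(rng.standard_normal((60, 3)),
                         columns=list("abc"))
        y = (2.0 * X["a"] - 1.0 * X["b"]).to_numpy() + 50.0
        _, coefs, report = M.fit_lasso_cv(X, y, seed=0)
        assert report.cv_r2 > 0.99
        assert report.train_r2 > 0.999
        assert report.cv_adj_r2 <= report.cv_r2

    def test_collinear_duplicate_not_both_selected(self, rng):
        x = rng.standard_normal(80)
        X = pd.DataFrame({
            "a": x, "dup": x, "b": rng.standard_normal(80)})
        y = x + 0.05 * rng.standard_normal(80)
        _, coefs, _ = M.fit_lasso_cv(X, y, seed=1)
        # The L1 penalty spreads or concentrates the collinear pair's
        # weight, but never keeps both at full size.
        both_large = (abs(coefs.get("a", 0.0)) > 0.6
                      and abs(coefs.get("dup", 0.0)) > 0.6)
        assert not both_large

    def test_fold_assignment_is_partition(self, rng):
        X = pd.DataFrame(rng.standard_normal((55, 2)), columns=["a", "b"])
        y = rng.standard_normal(55)
        _, _, report = M.fit_lasso_cv(X, y, seed=2)
        assert len(report.fold_assignment) == 55
        assert set(report.fold_assignment) == set(range(10))

    def test_one_se_rule_selects_larger_penalty(self, rng):
        X = pd.DataFrame(rng.standard_normal((60, 5)),
                         columns=list("abcde"))
        y = X["a"].to_numpy() + rng.standard_normal(60)
        _, _, rep_min = M.fit_lasso_cv(X, y, seed=3, rule="min")
        _, _, rep_1se = M.fit_lasso_cv(X, y, seed=3, rule="1se")
        assert rep_1se.alpha >= rep_min.alpha


class TestComponentFit:
    def test_sample_size_guard(self, rng):
        feats = pd.DataFrame({"x": rng.standard_normal(10)})
        with pytest.raises(ValueError, match="20"):
            M.fit_component_model(
                feats, np.linspace(0, 100, 10), "TE", "face")

    def test_recovers_published_face_model_structure(self):
        # Cohort simulated from the published TE face model at low
        # noise: the refit must rediscover the three generating
        # variables with the right signs and magnitude order.
        cohort = synth.generate_cohort(synth.SyntheticConfig(
            seed=21, feature_noise_sd=1.0,
            group_sizes={"TE": 150, "SE": 0, "SY": 0}))
        frames = synth.cohort_frames(cohort)
        vas = frames["subjects"]["vas_mean"].to_numpy()
        m, rep = M.fit_component_model(
            frames["face"], vas, "TE", "face", seed=4)
        truth = {"FhL_Cr_std": 2.75, "ChLD_Y_std": -1.18,
                 "Nose_Y_avg": 3.36}
        for var, coef in truth.items():
            assert var in m.coefficients
            assert np.sign(m.coefficients[var]) == np.sign(coef)
        got_rank = sorted(truth, key=lambda v: -abs(m.coefficients[v]))
        true_rank = sorted(truth, key=lambda v: -abs(truth[v]))
        assert got_rank == true_rank
        assert rep.cv_r2 > 0.9


class TestIntegrativeFit:
    def test_constant_component_dropped(self, rng):
        n = 60
        scores = pd.DataFrame({
            "face": rng.standard_normal(n) * 10 + 60,
            "skin": np.full(n, 67.71),           # intercept-only model
        })
        vas = scores["face"].to_numpy() + rng.standard_normal(n)
        m, _ = M.fit_integrative_model(
            scores, rng.uniform(50, 70, n), rng.uniform(20, 30, n),
            vas, "SE", seed=5)
        assert "skin" not in m.coefficients
        assert "face" in m.coefficients

    def test_generative_r2_recovered(self, rng):
        # Component scores carrying a shared signal with noise scaled
        # for a population R^2 of 0.65 at n = 72.
        n, r2 = 72, 0.65
        d = rng.standard_normal(n) * 20
        tau = np.sqrt(3 * 400 * (1 - r2) / r2)
        scores = pd.DataFrame({
            c: 65 + d + tau * rng.standard_normal(n)
            for c in ("face", "pulse", "questionnaire")})
        vas = 65 + d
        _, rep = M.fit_integrative_model(
            scores, rng.uniform(50, 70, n), rng.uniform(20, 30, n),
            vas, "SE", seed=6)
        assert rep.cv_r2 == pytest.approx(r2, abs=0.18)


class TestScoring:
    def test_published_intercepts_at_zero_z(self):
        comps, _ = M.load_published_models()
        zero_face = {v: 0.0 for v in
                     comps[("TE", "face")].coefficients}
        assert comps[("TE", "face")].score(zero_face) == 63.28

    def test_one_z_unit_shift(self):
        comps, _ = M.load_published_models()
        m = comps[("TE", "face")]
        feats = {v: 0.0 for v in m.coefficients}
        feats["FhL_Cr_std"] = 1.0
        assert m.score(feats) == pytest.approx(63.28 + 2.75)

    def test_category_boundaries(self):
        assert published.categorize_vas(80.0) == "healthy"
        assert published.categorize_vas(79.999) == "subhealthy"
        assert published.categorize_vas(40.0) == "subhealthy"
        assert published.categorize_vas(39.99) == "diseased"

    def test_missing_variable_error_lists_names(self):
        comps, _ = M.load_published_models()
        with pytest.raises(KeyError, match="Nose_Y_avg"):
            comps[("TE", "face")].score({"FhL_Cr_std": 0.0,
                                         "ChLD_Y_std": 0.0})

    def test_score_subject_component_only(self):
        comps, integ = M.load_published_models()
        te_models = {c: comps[("TE", c)] for c in published.COMPONENTS}
        feats = {
            c: {v: 0.0 for v in te_models[c].coefficients}
            for c in published.COMPONENTS}
        out = M.score_subject(te_models, feats, integ["TE"])
        assert out["components"]["pulse"] == pytest.approx(59.89)
        assert out["SHI_sum"] is None     # age/BMI betas unpublished

    def test_integrative_requires_age_bmi_terms(self):
        _, integ = M.load_published_models()
        frame = pd.DataFrame({c: [0.0] for c in
                              integ["TE"].coefficients})
        with pytest.raises(ValueError, match="unpublished|age"):
            integ["TE"].score(frame, age=np.array([55.0]),
                              bmi=np.array([24.0]))


class TestPublishedModels:
    def test_se_pulse_single_coefficient(self):
        comps, _ = M.load_published_models()
        m = comps[("SE", "pulse")]
        assert m.intercept == 68.90
        assert m.coefficients == {"L_PDI": -4.83}

    def test_sy_voice_single_negative_predictor(self):
        comps, _ = M.load_published_models()
        m = comps[("SY", "voice")]
        assert list(m.coefficients) == ["sFHL"]
        assert m.coefficients["sFHL"] < 0

    def test_te_integrative_has_five_components(self):
        _, integ = M.load_published_models()
        assert len(integ["TE"].coefficients) == 5
        assert len(integ["SE"].coefficients) == 3

    def test_intercepts_close_to_group_mean_vas(self):
        # On z-scored predictors the LASSO intercept equals the mean
        # response, so every published intercept must sit near its
        # constitution's mean VAS.
        comps, _ = M.load_published_models()
        for (const, _comp), m in comps.items():
            group_mean = published.VAS_MEAN_SD[const][0]
            assert abs(m.intercept - group_mean) <= 5.0

    def test_checksum_guard(self, monkeypatch):
        monkeypatch.setattr(M, "_PUBLISHED_SHA256", "0" * 64)
        with pytest.raises(ValueError, match="checksum"):
            M.load_published_models()


def test_adjusted_r2_formula():
    assert M.adjusted_r2(0.58, 100, 7) == pytest.approx(
        1 - (1 - 0.58) * 99 / 92)
    assert np.isnan(M.adjusted_r2(0.5, 5, 4))
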