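import numpy as np
import pandas as pd
import pytest

from steroidopls import (OplsConfig, choose_orthogonal_components,
                         compute_vip, cross_validate, fit_opls, hotelling_t2,
                         predict_llr, prune_predictors)
from steroidopls.cohort import CohortTable, VariableSpec
from steroidopls.opls import OplsError, _core_fit, _standardize
from steroidopls.transform import TransformFit

FAST = OplsConfig(n_orth=0, prune=False, hotelling_screen=False, seed=0)


def matrix_cohort(X, y01, prefix="v"):
    """Wrap a raw (X, 0/1 outcome) pair as a two-group cohort table."""
    n, p = X.shape
    names = [f"{prefix}{j}" for j in range(p)]
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "age", 70.0)
    df.insert(0, "group", np.where(y01 == 1, "A+D-", "A-D-"))
    df.insert(0, "sex", "F")
    df.insert(0, "subject_id", [f"s{i}" for i in range(n)])
    spec = [VariableSpec(name=c, label=c, unit="", block="synthetic",
                         assay="synthetic", positive_only=False)
            for c in names]
    return CohortTable(df, spec), names


def identity_transforms(names):
    return {n: TransformFit(n, 1.0, 0.0, np.nan, 0) for n in names}


def class_data(rng, n=40, p=5, effect=1.0):
    y01 = np.repeat([1.0, 0.0], n // 2)
    X = rng.standard_normal((n, p))
    X += effect * np.outer(y01 - y01.mean(), rng.uniform(0.5, 1.5, p))
    return X, y01


class TestCoreDecomposition:
    def fit(self, seed=41, n_orth=2, n=40, p=6):
        rng = np.random.default_rng(seed)
        X, y01 = class_data(rng, n=n, p=p)
        X[:, :3] += 2.0 * np.outer(rng.standard_normal(n), [1.0, 0.8, 0.6])
        table, names = matrix_cohort(X, y01)
        cfg = OplsConfig(n_orth=n_orth, prune=False, hotelling_screen=False)
        return fit_opls(table, ("A+D-", "A-D-"), names,
                        identity_transforms(names), cfg), X, y01

    def test_reconstruction_identity(self):
        model, X, _ = self.fit()
        Z, _, _ = _standardize(X)
        Xhat = (np.outer(model.t_p, model.p_p)
                + model.t_orth @ model.p_orth.T + model.E)
        assert np.abs(Xhat - Z).max() < 1e-8

    def test_orthogonal_scores_mutually_and_predictively_orthogonal(self):
        model, _, _ = self.fit()
        assert model.n_orth >= 1
        gram = model.t_orth.T @ model.t_orth
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        assert np.abs(model.t_orth.T @ model.t_p).max() < 1e-8

    def test_r2y_equals_squared_correlation_with_t_p(self):
        model, _, _ = self.fit()
        assert model.r2y == pytest.approx(
            np.corrcoef(model.y, model.t_p)[0, 1] ** 2, abs=1e-9)
        assert 0.0 <= model.r2y <= 1.0

    def test_y_residual_is_least_squares(self):
        model, _, _ = self.fit()
        np.testing.assert_allclose(
            model.F_resid, model.y - model.b * model.t_p, atol=1e-12)
        # residual orthogonal to the score: b is the LS slope
        assert abs(model.F_resid @ model.t_p) < 1e-8

    def test_single_component_matches_nipals_oracle(self):
        """With no orthogonal components the predictive score is X w with
        w = X'y/||X'y|| -- the one-step NIPALS PLS1 solution."""
        rng = np.random.default_rng(42)
        X, y01 = class_data(rng, n=20, p=5)
        table, names = matrix_cohort(X, y01)
        model = fit_opls(table, ("A+D-", "A-D-"), names,
                         identity_transforms(names), FAST)
        Z, _, _ = _standardize(X)
        y = y01 - y01.mean()
        w = Z.T @ y
        w /= np.linalg.norm(w)
        np.testing.assert_allclose(model.t_p, Z @ w, atol=1e-8)
        np.testing.assert_allclose(model.w, w, atol=1e-8)

    def test_perfect_separation_proxy(self):
        y01 = np.repeat([1.0, 0.0], 10)
        X = y01.reshape(-1, 1).copy()
        table, names = matrix_cohort(X, y01)
        model = fit_opls(table, ("A+D-", "A-D-"), names,
                         identity_transforms(names), FAST)
        assert model.r2y == pytest.approx(1.0, abs=1e-12)
        preds = predict_llr(model, table)
        calls = {p.subject_id: p.predicted_class for p in preds}
        truth = dict(zip(table.df["subject_id"], y01))
        assert all(calls[s] == truth[s] for s in calls)

    def test_null_predictors_flag_non_informative(self):
        reps, neg = 200, 0
        for seed in range(reps):
            rng = np.random.default_rng(100 + seed)
            y01 = np.repeat([1.0, 0.0], 30)
            X = rng.standard_normal((60, 5))
            table, names = matrix_cohort(X, y01)
            model = fit_opls(table, ("A+D-", "A-D-"), names,
                             identity_transforms(names), FAST)
            neg += (model.q2 <= 0) and not model.informative
        assert neg / reps >= 0.90


class TestChooseOrthogonal:
    def test_pure_signal_noise_needs_no_orthogonal_component(self):
        hits, reps = 0, 20
        for seed in range(reps):
            rng = np.random.default_rng(200 + seed)
            X, y01 = class_data(rng, n=60, p=8)
            hits += choose_orthogonal_components(X, y01, OplsConfig()) == 0
        assert hits / reps >= 0.80

    def test_strong_class_unrelated_factor_adds_component(self):
        hits, reps = 0, 20
        for seed in range(reps):
            rng = np.random.default_rng(300 + seed)
            X, y01 = class_data(rng, n=60, p=8, effect=0.8)
            latent = rng.standard_normal(60)
            X += 2.5 * np.outer(latent, rng.uniform(0.5, 1.0, 8)
                                * np.sign(rng.standard_normal(8)))
            hits += choose_orthogonal_components(X, y01,
                                                 OplsConfig()) >= 1
        assert hits / reps >= 0.80

    def test_infinite_tolerance_degenerates_to_zero(self):
        rng = np.random.default_rng(44)
        X, y01 = class_data(rng)
        cfg = OplsConfig(q2_tol=np.inf)
        assert choose_orthogonal_components(X, y01, cfg) == 0


class TestVip:
    def test_single_predictor_vip_is_one(self):
        rng = np.random.default_rng(45)
        X, y01 = class_data(rng, n=30, p=1)
        table, names = matrix_cohort(X, y01)
        model = fit_opls(table, ("A+D-", "A-D-"), names,
                         identity_transforms(names), FAST)
        assert compute_vip(model)[0] == pytest.approx(1.0, abs=1e-12)

    def test_vip_matches_literal_summation_oracle(self):
        rng = np.random.default_rng(46)
        X, y01 = class_data(rng, n=30, p=5)
        table, names = matrix_cohort(X, y01)
        model = fit_opls(table, ("A+D-", "A-D-"), names,
                         identity_transforms(names), FAST)
        # literal formula over the (single) predictive component
        ss_y = [model.b ** 2 * float(model.t_p @ model.t_p)]
        w_cols = [model.w]
        p = len(model.predictors)
        oracle = np.sqrt(
            p * sum(s * (w / np.linalg.norm(w)) ** 2
                    for s, w in zip(ss_y, w_cols)) / sum(ss_y))
        np.testing.assert_allclose(compute_vip(model), oracle, atol=1e-10)
        assert np.mean(compute_vip(model) ** 2) == pytest.approx(1.0,
                                                                 abs=1e-9)

    def test_zero_weight_predictor_has_zero_vip(self):
        rng = np.random.default_rng(47)
        y01 = np.repeat([1.0, 0.0], 20)
        y = y01 - y01.mean()
        X = rng.standard_normal((40, 3))
        X += np.outer(y, [1.0, 0.8, 0.0])
        # orthogonalise the last column against the coded outcome
        X[:, 2] -= np.outer(y, y @ X[:, 2] / (y @ y))[:, 0]
        X[:, 2] -= X[:, 2].mean()
        X[:, 2] /= X[:, 2].std(ddof=1)
        table, names = matrix_cohort(X, y01)
        model = fit_opls(table, ("A+D-", "A-D-"), names,
                         identity_transforms(names), FAST)
        assert compute_vip(model)[2] == pytest.approx(0.0, abs=1e-8)


class TestPrune:
    def test_exchangeable_informative_predictors_all_survive(self):
        rng = np.random.default_rng(48)
        y01 = np.repeat([1.0, 0.0], 50)
        X = 1.5 * np.outer(y01 - 0.5, np.ones(6)) + \
            0.8 * rng.standard_normal((100, 6))
        table, names = matrix_cohort(X, y01)
        cfg = OplsConfig(n_orth=0, hotelling_screen=False)
        model = fit_opls(table, ("A+D-", "A-D-"), names,
                         identity_transforms(names), cfg)
        assert set(model.predictors) == set(names)
        assert np.allclose(compute_vip(model), 1.0, atol=0.1)

    def test_informative_predictors_survive_noise_elimination(self):
        reps, hits = 100, 0
        informative = {"v0", "v1", "v2"}
        for seed in range(reps):
            rng = np.random.default_rng(500 + seed)
            y01 = np.repeat([1.0, 0.0], 50)
            X = rng.standard_normal((100, 10))
            X[:, :3] += 1.2 * np.outer(y01 - 0.5, [1.0, 1.0, 1.0])
            table, names = matrix_cohort(X, y01)
            cfg = OplsConfig(n_orth=0, hotelling_screen=False)
            model = fit_opls(table, ("A+D-", "A-D-"), names,
                             identity_transforms(names), cfg)
            hits += informative <= set(model.predictors)
        assert hits / reps >= 0.90

    def test_zero_threshold_is_identity(self):
        rng = np.random.default_rng(49)
        X, y01 = class_data(rng, n=40, p=6)
        table, names = matrix_cohort(X, y01)
        model = fit_opls(table, ("A+D-", "A-D-"), names,
                         identity_transforms(names), FAST)
        pruned = prune_predictors(model, table, threshold=0.0)
        assert pruned.predictors == model.predictors

    def test_pruning_to_nothing_raises(self):
        rng = np.random.default_rng(50)
        y01 = np.repeat([1.0, 0.0], 20)
        X = rng.standard_normal((40, 4))
        table, names = matrix_cohort(X, y01)
        model = fit_opls(table, ("A+D-", "A-D-"), names,
                         identity_transforms(names), FAST)
        with pytest.raises(OplsError, match="no relevant predictors"):
            prune_predictors(model, table, threshold=50.0)


class TestHotelling:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(51)
        scores = rng.standard_normal((200, 2))
        flags, t2, limit = hotelling_t2(scores, alpha=0.05)
        mu = scores.mean(axis=0)
        S = np.cov(scores, rowvar=False, ddof=1)
        Sinv = np.linalg.inv(S)
        t2_oracle = np.array([(s - mu) @ Sinv @ (s - mu) for s in scores])
        np.testing.assert_allclose(t2, t2_oracle, atol=1e-10)
        from scipy import stats
        n, d = scores.shape
        lim_oracle = (d * (n - 1) * (n + 1)) / (n * (n - d)) \
            * stats.f.ppf(0.95, d, n - d)
        assert limit == pytest.approx(lim_oracle)
        np.testing.assert_array_equal(flags, t2_oracle > lim_oracle)

    def test_centroid_subject_never_flagged(self):
        rng = np.random.default_rng(52)
        scores = rng.standard_normal((50, 2))
        scores[0] = scores[1:].mean(axis=0) * 0  # near-centroid
        scores = np.vstack([scores, scores.mean(axis=0)])
        flags, t2, _ = hotelling_t2(scores, alpha=0.05)
        assert t2[-1] == pytest.approx(0.0, abs=1e-20)
        assert not flags[-1]

    def test_alpha_limits(self):
        rng = np.random.default_rng(53)
        scores = rng.standard_normal((100, 2))
        all_flags, _, _ = hotelling_t2(scores, alpha=1.0)
        assert all_flags.all()
        no_flags, _, _ = hotelling_t2(scores, alpha=1e-12)
        assert not no_flags.any()

    def test_singular_covariance_raises(self):
        scores = np.ones((20, 2))
        scores[:, 1] = scores[:, 0]
        with pytest.raises(OplsError, match="singular"):
            hotelling_t2(scores)


class TestCrossValidation:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(54)
        X, y01 = class_data(rng)
        q2a, la, fa = cross_validate(X, y01, 1, seed=9)
        q2b, lb, fb = cross_validate(X, y01, 1, seed=9)
        assert q2a == q2b
        np.testing.assert_array_equal(la, lb)
        np.testing.assert_array_equal(fa, fb)

    def test_q2_never_exceeds_r2y_over_random_datasets(self):
        for seed in range(50):
            rng = np.random.default_rng(700 + seed)
            n = int(rng.integers(24, 60))
            p = int(rng.integers(2, 10))
            effect = float(rng.uniform(0, 1.5))
            X, y01 = class_data(rng, n=n - n % 2, p=p, effect=effect)
            table, names = matrix_cohort(X, y01)
            model = fit_opls(table, ("A+D-", "A-D-"), names,
                             identity_transforms(names), FAST)
            assert model.q2 <= model.r2y + 1e-9

    def test_noise_only_q2_nonpositive_in_median(self):
        q2s = []
        for seed in range(100):
            rng = np.random.default_rng(900 + seed)
            y01 = np.repeat([1.0, 0.0], 20)
            X = rng.standard_normal((40, 4))
            q2, _, _ = cross_validate(X, y01, 0, seed=seed)
            q2s.append(q2)
        assert np.median(q2s) <= 0

    def test_tiny_class_reduces_fold_count_with_warning(self):
        rng = np.random.default_rng(55)
        y01 = np.array([1.0] * 4 + [0.0] * 20)
        X = rng.standard_normal((24, 3))
        with pytest.warns(UserWarning, match="reducing CV folds"):
            _, _, folds = cross_validate(X, y01, 0, n_folds=7, seed=1)
        assert folds.max() + 1 == 4


class TestPredictLlr:
    def fit_simple(self, seed=56):
        rng = np.random.default_rng(seed)
        X, y01 = class_data(rng, n=40, p=4, effect=1.2)
        table, names = matrix_cohort(X, y01)
        model = fit_opls(table, ("A+D-", "A-D-"), names,
                         identity_transforms(names), FAST)
        return model, table

    def test_probability_is_logistic_of_llr(self):
        model, table = self.fit_simple()
        for p in predict_llr(model, table):
            assert p.probability == pytest.approx(
                np.exp(p.llr) / (1 + np.exp(p.llr)), abs=1e-12)

    def test_midpoint_score_maps_to_probability_half(self):
        model, table = self.fit_simple()
        a, slope = model.calibration
        df = table.df.head(1).copy()
        # place the subject exactly at the calibration midpoint
        target = -a / slope
        base = predict_llr(model, df)[0]
        shift = (target - base.t_p_score) / np.sum(model.w ** 2)
        for j, name in enumerate(model.predictors):
            df[name] = df[name] + shift * model.w[j] * model.x_std[j]
        p = predict_llr(model, df)[0]
        assert p.llr == pytest.approx(0.0, abs=1e-6)
        assert p.probability == pytest.approx(0.5, abs=1e-6)

    def test_separated_training_scores_hit_the_cap(self):
        y01 = np.repeat([1.0, 0.0], 10)
        X = y01.reshape(-1, 1) + 0.01 * np.random.default_rng(
            57).standard_normal((20, 1))
        table, names = matrix_cohort(X, y01)
        model = fit_opls(table, ("A+D-", "A-D-"), names,
                         identity_transforms(names), FAST)
        preds = predict_llr(model, table)
        assert all(abs(p.llr) == pytest.approx(model.llr_cap) for p in preds)
        assert all(0.0 < p.probability < 1.0 for p in preds)

    def test_missing_predictor_raises_naming_it(self):
        model, table = self.fit_simple()
        df = table.df.drop(columns=["v2"])
        with pytest.raises(OplsError, match="v2"):
            predict_llr(model, df)

    def test_too_few_subjects_per_class_raises(self):
        rng = np.random.default_rng(58)
        y01 = np.array([1.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        X = rng.standard_normal((6, 2))
        table, names = matrix_cohort(X, y01)
        with pytest.raises(OplsError, match="3 subjects"):
            fit_opls(table, ("A+D-", "A-D-"), names,
                     identity_transforms(names), FAST)
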