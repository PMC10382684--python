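import numpy as np
import pytest
from scipy.special import expit, logit

from cl2pt.datasets_io import DataError
from cl2pt.evaluation import roc_auc
from cl2pt.featsel import select_features
from cl2pt.predictors import (
    TrainingConfig,
    cv_auc,
    default_p_grid,
    fit_logistic_ridge,
    knn_scores,
    predict_proba,
    ridge_objective_value,
    spearman_distance,
    stage1_exponents,
    stage2_exponents,
    train_knnda,
    train_logitda,
    tune_lambda_two_stage,
)
from conftest import make_dataset
from helpers import knn_neighbor_oracle


class TestLogisticRidge:
    def test_huge_penalty_shrinks_to_prevalence(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 3))
        y = (rng.random(200) < 0.3).astype(int)
        b0, b = fit_logistic_ridge(X, y, lam=1e8)
        assert np.abs(b).max() < 1e-4
        assert b0 == pytest.approx(logit(y.mean()), abs=1e-3)

    def test_separable_data_stays_finite_with_perfect_auc(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        b0, b = fit_logistic_ridge(X, y, lam=0.1)
        assert np.isfinite(b).all()
        scores = expit(b0 + X @ b)
        assert roc_auc(scores, y) == 1.0

    def test_parameter_recovery_near_mle(self):
        rng = np.random.default_rng(42)
        n, p = 5000, 5
        beta = np.array([1.0, -0.5, 0.25, 0.0, 0.75])
        X = rng.normal(size=(n, p))
        y = (rng.random(n) < expit(0.3 + X @ beta)).astype(int)
        b0, b = fit_logistic_ridge(X, y, lam=1e-6)
        # s.e. from the observed information of the unpenalized fit
        s = expit(b0 + X @ b)
        W = s * (1 - s)
        Xd = np.hstack([np.ones((n, 1)), X])
        cov = np.linalg.inv((Xd * W[:, None]).T @ Xd)
        se = np.sqrt(np.diag(cov))[1:]
        assert np.all(np.abs(b - beta) < 3 * se)

    def test_objective_is_local_minimum(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 4))
        y = (rng.random(60) < expit(X[:, 0])).astype(int)
        lam = 0.05
        b0, b = fit_logistic_ridge(X, y, lam)
        f_opt = ridge_objective_value(b0, b, X, y, lam)
        for _ in range(1000):
            d = rng.normal(size=5)
            d *= 1e-3 / np.linalg.norm(d)
            f_pert = ridge_objective_value(b0 + d[0], b + d[1:], X, y, lam)
            assert f_pert >= f_opt - 1e-12

    def test_single_class_errors(self):
        with pytest.raises(DataError):
            fit_logistic_ridge(np.ones((4, 1)), np.ones(4), 0.1)


class TestCVAUC:
    @staticmethod
    def _first_feature_factory(Xtr, ytr):
        return lambda Xte: Xte[:, 0]

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 3))
        y = (rng.random(60) < 0.5).astype(int)
        a = cv_auc(X, y, self._first_feature_factory, folds=5, repeats=4, seed=3)
        b = cv_auc(X, y, self._first_feature_factory, folds=5, repeats=4, seed=3)
        np.testing.assert_array_equal(a[2], b[2])

    def test_label_equal_feature_gives_auc_one(self):
        rng = np.random.default_rng(3)
        y = np.array([0, 1] * 20)
        X = np.column_stack([y.astype(float), rng.normal(size=40)])
        mean, _, _ = cv_auc(X, y, self._first_feature_factory, repeats=2, seed=0)
        assert mean == 1.0

    def test_null_features_give_chance_auc(self):
        # grand mean over many seeds on pure-noise features concentrates at 0.5
        means = []
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(200, 4))
            y = np.array([0, 1] * 100)
            mean, _, _ = cv_auc(X, y, self._first_feature_factory, repeats=2, seed=seed)
            means.append(mean)
        assert 0.45 <= np.mean(means) <= 0.55

    def test_class_smaller_than_folds_errors(self):
        X = np.zeros((10, 1))
        y = np.array([1] * 3 + [0] * 7)
        with pytest.raises(DataError, match="folds"):
            cv_auc(X, y, self._first_feature_factory, folds=5)


class TestLambdaGrids:
    def test_stage_grids_have_eleven_points(self):
        assert len(stage1_exponents()) == 11
        assert len(stage2_exponents(-1.2)) == 11

    def test_stage2_centered_on_stage1_winner(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 3))
        y = (rng.random(50) < expit(1.5 * X[:, 0])).astype(int)
        cfg = TrainingConfig(p_grid=(3,), repeats=2, seed=1)
        lam, score, info = tune_lambda_two_stage(X, y, cfg)
        a1 = info["a1"]
        assert 10 ** (a1 - 0.05) - 1e-12 <= lam <= 10 ** (a1 + 0.05) + 1e-12
        assert score == max(s for _, s in info["stage2"])

    def test_default_p_grid_composition(self):
        grid = default_p_grid()
        assert grid[0] == 50 and grid[-1] == 1000
        assert list(grid) == sorted(set(grid))
        assert 200 in grid and 220 in grid and 400 in grid and 500 in grid


class TestTrainLogitDA:
    def test_degenerate_grids_return_that_configuration(self, small_pair):
        src, tgt, _ = small_pair
        ranking = select_features(src, tgt, alpha=0.6)
        cfg = TrainingConfig(
            p_grid=(3,), repeats=2, seed=0, lambda_stage1_exponents=(-1.0,)
        )
        model = train_logitda(src, ranking, cfg)
        assert model.hyperparams["p"] == 3
        assert len(model.genes) == 3

    def test_cv_score_equals_table_max(self, small_pair, tiny_training):
        src, tgt, _ = small_pair
        ranking = select_features(src, tgt, alpha=0.6)
        model = train_logitda(src, ranking, tiny_training)
        assert model.cv_score == pytest.approx(
            max(r["cv_score"] for r in model.score_table)
        )

    def test_p_grid_above_ranking_errors(self, small_pair):
        src, tgt, _ = small_pair
        ranking = select_features(src, tgt, alpha=0.6)
        cfg = TrainingConfig(p_grid=(5000,), repeats=2)
        with pytest.raises(DataError):
            train_logitda(src, ranking, cfg)

    def test_selected_p_tracks_informative_genes(self):
        # ranking where exactly the top genes carry signal: p lands near truth
        from cl2pt.synthetic import SyntheticConfig, generate_domain_pair

        cfg = SyntheticConfig(
            n_source=300, n_target=100,
            n_invariant_informative=60, n_invariant_null=0, n_shifted=0,
            effect_size=1.0, seed=21,
        )
        src, tgt, _ = generate_domain_pair(cfg)
        ranking = select_features(src, tgt, alpha=0.6, use_da=False)
        tcfg = TrainingConfig(
            p_grid=(10, 60), repeats=2, seed=2,
            lambda_stage1_exponents=(-2.0, -1.0),
        )
        model = train_logitda(src, ranking, tcfg)
        assert model.hyperparams["p"] == 60  # more informative genes help CV


class TestSpearmanKNN:
    def test_identical_profiles_distance_zero(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        assert spearman_distance(u, u) == pytest.approx(0.0)

    def test_reversed_profiles_distance_two(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        assert spearman_distance(u, u[::-1]) == pytest.approx(2.0)

    def test_hand_computed_rho(self):
        d = spearman_distance(np.array([1, 2, 3, 4.0]), np.array([1, 3, 2, 4.0]))
        assert d == pytest.approx(0.2)

    def test_constant_profile_errors(self):
        with pytest.raises(DataError):
            spearman_distance(np.ones(4), np.array([1.0, 2.0, 3.0, 4.0]))

    @pytest.mark.parametrize("seed", range(5))
    def test_neighbor_sets_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        X_ref = rng.normal(size=(rng.integers(5, 30), 8))
        X_query = rng.normal(size=(4, 8))
        k = int(rng.integers(1, 5))
        oracle = knn_neighbor_oracle(X_ref, X_query, k)
        y = rng.integers(0, 2, size=X_ref.shape[0])
        got = knn_scores(X_ref, y, X_query, k)
        expected = [y[idx].mean() for idx in oracle]
        np.testing.assert_allclose(got, expected)

    def test_k1_duplicate_returns_duplicate_label(self):
        rng = np.random.default_rng(7)
        X_ref = rng.normal(size=(6, 5))
        y = np.array([0, 1, 0, 1, 0, 1])
        got = knn_scores(X_ref, y, X_ref[[1]], 1)
        assert got[0] == y[1]


class TestTrainKNNDA:
    def test_separable_clusters_high_cv_auc(self):
        rng = np.random.default_rng(8)
        n = 40
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        base = rng.normal(size=(2, 10))
        X = base[1 - y] + 0.05 * rng.normal(size=(n, 10))
        vals = X.T
        src = make_dataset(vals, y, "source")
        tgt = make_dataset(vals[:, :10], y[:10], "target", prefix="t")
        ranking = select_features(src, tgt, alpha=0.1, use_da=False)
        cfg = TrainingConfig(p_grid=(10,), repeats=2, seed=0, k_grid=(3, 5))
        model = train_knnda(src, ranking, cfg)
        assert model.cv_score >= 0.95

    def test_same_seed_same_selection(self, small_pair, tiny_training):
        src, tgt, _ = small_pair
        ranking = select_features(src, tgt, alpha=0.6)
        m1 = train_knnda(src, ranking, tiny_training)
        m2 = train_knnda(src, ranking, tiny_training)
        assert m1.hyperparams == m2.hyperparams
        assert m1.cv_score == m2.cv_score

    def test_oversized_k_skipped_with_warning(self, small_pair):
        src, tgt, _ = small_pair
        ranking = select_features(src, tgt, alpha=0.6)
        cfg = TrainingConfig(p_grid=(3,), repeats=2, k_grid=(3, 9999))
        with pytest.warns(UserWarning, match="9999"):
            model = train_knnda(src, ranking, cfg)
        assert model.hyperparams["K"] == 3


class TestPredictProba:
    def test_zero_model_scores_half(self, small_pair):
        from cl2pt.predictors import TrainedPredictor

        src, tgt, _ = small_pair
        genes = tgt.expr.gene_ids[:4]
        model = TrainedPredictor(
            kind="logitda", genes=genes, hyperparams={"p": 4, "lambda": 1.0},
            cv_score=0.5, cv_se=0.0, intercept=0.0, coef=np.zeros(4),
        )
        scores = predict_proba(model, tgt.expr)
        np.testing.assert_allclose(scores, 0.5)

    def test_knn_scores_are_vote_fractions(self, small_pair, tiny_training):
        src, tgt, _ = small_pair
        ranking = select_features(src, tgt, alpha=0.6)
        model = train_knnda(src, ranking, tiny_training)
        scores = predict_proba(model, tgt.expr)
        k = model.hyperparams["K"]
        allowed = np.arange(k + 1) / k
        assert np.all(np.isin(scores, allowed))

    def test_positive_coefficient_monotonicity(self, small_pair):
        from cl2pt.predictors import TrainedPredictor

        src, tgt, _ = small_pair
        genes = tgt.expr.gene_ids[:2]
        model = TrainedPredictor(
            kind="logitda", genes=genes, hyperparams={"p": 2, "lambda": 1.0},
            cv_score=0.5, cv_se=0.0, intercept=0.1, coef=np.array([2.0, -1.0]),
        )
        base = predict_proba(model, tgt.expr)
        bumped = tgt.expr.copy()
        bumped.values[0] += 1.0
        assert np.all(predict_proba(model, bumped) > base)

    def test_missing_gene_errors(self, small_pair):
        from cl2pt.predictors import TrainedPredictor

        src, tgt, _ = small_pair
        model = TrainedPredictor(
            kind="logitda", genes=["NOPE"], hyperparams={}, cv_score=0.5,
            cv_se=0.0, intercept=0.0, coef=np.zeros(1),
        )
        with pytest.raises(DataError, match="NOPE"):
            predict_proba(model, tgt.expr)

    def test_model_json_round_trip(self, small_pair, tiny_training, tmp_path):
        from cl2pt.predictors import TrainedPredictor

        src, tgt, _ = small_pair
        ranking = select_features(src, tgt, alpha=0.6)
        model = train_logitda(src, ranking, tiny_training)
        model.to_json(tmp_path / "m.json")
        back = TrainedPredictor.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(
            predict_proba(back, tgt.expr), predict_proba(model, tgt.expr)
        )
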