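"""Three-step model core: universal activity, the odds feature, modifier
fits, L1-logistic integration, and end-to-end score composition."""

import numpy as np
import pandas as pd
import pytest

from gram import model
from gram.io import GramModelBundle
from gram.model import (
    TrainingConfig,
    fit_l1_logistic,
    fit_step1,
    fit_step3,
    odds_feature,
    predict_U,
    predict_gram,
    predict_scores,
)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(200, 6))
    y = (X[:, 0] > 0).astype(int)
    return X, y


class TestStep1:
    def test_separable_design_training_auroc_one(self, separable):
        X, y = separable
        f1 = fit_step1(X, y, n_trees=100, seed=0)
        u = predict_U(f1, X)
        from gram.evaluate import auroc
        assert auroc(u, y) == 1.0
        assert u[y == 1].min() > 0.5 > u[y == 0].max()

    def test_probabilities_within_unit_interval(self, separable, rng):
        X, y = separable
        f1 = fit_step1(X, y, n_trees=50, seed=0)
        u = predict_U(f1, rng.uniform(-10, 10, size=(40, 6)))
        assert np.all((u >= 0) & (u <= 1))

    def test_prediction_is_mean_of_tree_votes(self, separable):
        X, y = separable
        f1 = fit_step1(X, y, n_trees=60, seed=0)
        x = X[:5]
        votes = np.mean(
            [t.predict_proba(x)[:, list(t.classes_).index(1)] for t in f1.estimators_],
            axis=0,
        )
        assert np.allclose(predict_U(f1, x), votes)

    def test_shuffled_labels_near_chance(self):
        from gram.evaluate import auroc, make_folds
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 6))
        y = rng.integers(0, 2, size=300)
        folds = make_folds([str(i) for i in range(300)], k=5, seed=0)
        aucs = []
        idx = {str(i): i for i in range(300)}
        for f in range(1, 6):
            te = [idx[v] for v in folds.fold_ids(f)]
            tr = [i for i in range(300) if i not in set(te)]
            f1 = fit_step1(X[tr], y[tr], n_trees=100, seed=f)
            aucs.append(auroc(predict_U(f1, X[te]), y[te]))
        assert 0.4 <= float(np.mean(aucs)) <= 0.6

    def test_single_class_rejected(self, separable):
        X, _ = separable
        with pytest.raises(ValueError, match="both classes"):
            fit_step1(X, np.ones(len(X)), n_trees=10, seed=0)

    def test_same_seed_identical_predictions(self, separable):
        X, y = separable
        a = predict_U(fit_step1(X, y, n_trees=50, seed=3), X)
        b = predict_U(fit_step1(X, y, n_trees=50, seed=3), X)
        assert np.array_equal(a, b)


class TestOddsFeature:
    def test_equal_scores_give_zero(self):
        assert odds_feature(0.7, 0.7) == 0.0

    def test_hand_evaluated(self):
        # odds 0.8/0.2 = 4 vs 0.5/0.5 = 1 -> |log2 4| = 2
        assert odds_feature(0.8, 0.5) == pytest.approx(2.0)

    def test_clipping_keeps_value_finite(self):
        val = odds_feature(1.0, 0.5, eps=1e-6)
        expected = abs(np.log2((1 - 1e-6) / 1e-6))
        assert val == pytest.approx(expected, rel=1e-9)
        assert np.isfinite(val)

    def test_symmetry(self, rng):
        for _ in range(20):
            a, b = rng.random(2)
            assert odds_feature(a, b) == pytest.approx(odds_feature(b, a))

    def test_zero_iff_equal_after_clipping(self):
        assert odds_feature(1.0, 1.0 - 1e-9, eps=1e-6) == 0.0
        assert odds_feature(0.6, 0.601) > 0.0

    def test_invalid_eps_rejected(self):
        with pytest.raises(ValueError):
            odds_feature(0.5, 0.5, eps=0.7)


class TestL1Logistic:
    def test_penalty_dominated_limit(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(400, 3))
        y = (rng.random(400) < 0.3).astype(float)
        b0, b = fit_l1_logistic(X, y, lam=1e6)
        assert np.allclose(b, 0.0)
        p = y.mean()
        assert b0 == pytest.approx(np.log(p / (1 - p)), abs=1e-4)

    def test_matches_sklearn_at_moderate_penalty(self):
        """Cross-check the proximal-gradient solver against an
        independent L1 implementation away from the extreme-penalty
        regimes it exists to handle."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(3)
        X = rng.normal(size=(500, 3))
        z = 1.5 * X[:, 0] - 1.0 * X[:, 1] + 0.3
        y = (rng.random(500) < 1 / (1 + np.exp(-z))).astype(float)
        lam = 0.01
        b0, b = fit_l1_logistic(X, y, lam)
        sk = LogisticRegression(
            l1_ratio=1.0, solver="saga", C=1.0 / (len(y) * lam),
            max_iter=50_000, tol=1e-10, random_state=0,
        ).fit(X, y.astype(int))
        assert np.allclose(b, sk.coef_.ravel(), atol=2e-3)
        assert b0 == pytest.approx(float(sk.intercept_[0]), abs=2e-3)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(4)
        n = 4000
        odds = np.abs(rng.normal(0, 1.5, n))
        s_b = rng.random(n)
        s_e = rng.random(n)
        z = 2.0 * odds + 1.0 * s_b + 1.0 * s_e - 2.0
        y = (rng.random(n) < 1 / (1 + np.exp(-z))).astype(int)
        fit = fit_step3(odds, s_b, s_e, y, lambda_grid=[1e-4, 1e-3], k=3, seed=0)
        for got, true in zip((fit.b_u, fit.b_s1, fit.b_s2, fit.b0), (2, 1, 1, -2)):
            assert got == pytest.approx(true, rel=0.2)

    def test_lambda_path_sparsity_monotone(self):
        rng = np.random.default_rng(5)
        n = 800
        odds = np.abs(rng.normal(0, 1.5, n))
        s_b = rng.random(n)
        s_e = rng.random(n)
        z = 1.5 * odds + 0.8 * s_b - 1.5
        y = (rng.random(n) < 1 / (1 + np.exp(-z))).astype(float)
        X = np.column_stack([odds, s_b, s_e])
        grid = np.logspace(-4, 1, 15)
        nnz = [
            int((np.abs(fit_l1_logistic(X, y, lam)[1]) > 1e-8).sum()) for lam in grid
        ]
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_empty_grid_and_single_class_rejected(self):
        odds = np.abs(np.random.default_rng(0).normal(size=50))
        s = np.random.default_rng(1).random(50)
        y = np.r_[np.zeros(25), np.ones(25)]
        with pytest.raises(ValueError, match="empty"):
            fit_step3(odds, s, s, y, lambda_grid=[])
        with pytest.raises(ValueError, match="both classes"):
            fit_step3(odds, s, s, np.zeros(50))

    def test_duplicating_rows_leaves_fit_unchanged(self):
        """The objective is normalized per row, so duplicating every row
        leaves the fit at any fixed penalty unchanged."""
        rng = np.random.default_rng(6)
        n = 400
        X = np.column_stack([
            np.abs(rng.normal(0, 1.5, n)), rng.random(n), rng.random(n)
        ])
        z = 2.0 * X[:, 0] - 1.5
        y = (rng.random(n) < 1 / (1 + np.exp(-z))).astype(float)
        for lam in (1e-3, 1e-2, 1e-1):
            b0_s, b_s = fit_l1_logistic(X, y, lam)
            b0_d, b_d = fit_l1_logistic(np.vstack([X, X]), np.r_[y, y], lam)
            assert b0_d == pytest.approx(b0_s, abs=1e-5)
            assert np.allclose(b_d, b_s, atol=1e-5)


class TestPredictGram:
    def test_null_coefficients_give_half(self, small_bundle, small_dataset):
        null = GramModelBundle(
            step1_model=small_bundle.step1_model,
            step2_binding_model=small_bundle.step2_binding_model,
            step2_expression_model=small_bundle.step2_expression_model,
            b_u=0.0, b_s1=0.0, b_s2=0.0, b0=0.0, lambda_=1.0,
            tf_ids=small_bundle.tf_ids,
        )
        df = predict_scores(null, small_dataset.bsm, small_dataset.profiles,
                            small_dataset.bsm.variant_ids[:5])
        assert np.allclose(df.m, 0.5)

    def test_m_respects_logistic_identity(self, small_bundle, small_dataset):
        df = predict_scores(small_bundle, small_dataset.bsm, small_dataset.profiles,
                            small_dataset.bsm.variant_ids[:20])
        z = (
            small_bundle.b_u * df.odds
            + small_bundle.b_s1 * df.s_b
            + small_bundle.b_s2 * df.s_e
            + small_bundle.b0
        )
        assert np.allclose(df.m, 1 / (1 + np.exp(-z)), atol=1e-15)
        assert np.all((df.m > 0) & (df.m < 1))

    def test_monotone_in_odds_with_positive_weight(self, small_bundle):
        b = small_bundle
        odds = np.linspace(0, 10, 50)
        z = abs(b.b_u) * odds + b.b_s1 * 0.5 + b.b_s2 * 0.5 + b.b0
        m = 1 / (1 + np.exp(-z))
        assert np.all(np.diff(m) >= 0)

    def test_single_scoring_matches_hand_composition(self, small_bundle, small_dataset):
        """predict_gram equals the explicit composition of the four
        sub-calls."""
        from gram.features import reorder_expression

        bsm = small_dataset.bsm
        vid = bsm.variant_ids[3]
        cell = sorted(small_dataset.profiles)[0]
        profile = small_dataset.profiles[cell]
        cfg = TrainingConfig()
        score = predict_gram(small_bundle, bsm, vid, profile, cfg=cfg)

        i = bsm.row_index(vid)
        u_wt = float(predict_U(small_bundle.step1_model, bsm.scores_ref[i])[0])
        u_mut = float(predict_U(small_bundle.step1_model, bsm.scores_alt[i])[0])
        odds = odds_feature(u_mut, u_wt, cfg.eps)
        s_b = float(predict_U(small_bundle.step2_binding_model, bsm.scores_ref[i])[0])
        xe = reorder_expression(bsm, vid, profile, cfg.key_allele).values
        s_e = float(predict_U(small_bundle.step2_expression_model, xe)[0])
        z = (
            small_bundle.b_u * odds + small_bundle.b_s1 * s_b
            + small_bundle.b_s2 * s_e + small_bundle.b0
        )
        assert score.u_wt == u_wt and score.u_mut == u_mut
        assert score.odds == pytest.approx(odds)
        assert score.s_b == s_b and score.s_e == s_e
        assert score.m == pytest.approx(1 / (1 + np.exp(-z)), abs=1e-15)


class TestTrainFull:
    def test_metadata_records_conditions(self, small_bundle, small_training_config):
        md = small_bundle.training_metadata
        assert md["seed"] == small_training_config.seed
        assert md["n_trees"] == small_training_config.n_trees
        assert md["n_training_variants"] == 150

    def test_reproducible_under_seed(self, small_gram_dataset, small_training_config,
                                     small_bundle, small_dataset):
        from gram.model import train_full
        again = train_full(small_gram_dataset, small_training_config)
        a = predict_scores(small_bundle, small_dataset.bsm, small_dataset.profiles,
                           small_dataset.bsm.variant_ids[:10])
        b = predict_scores(again, small_dataset.bsm, small_dataset.profiles,
                           small_dataset.bsm.variant_ids[:10])
        assert np.array_equal(a.m.to_numpy(), b.m.to_numpy())
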