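"""PLDA fitting, latent transform and closed-form predictive densities."""

import json

import numpy as np
import pytest
from scipy.stats import norm

from bayesteach import (
    FeatureDataset,
    GaussianFeatureSpec,
    PLDAModel,
    class_predictive_logdensity,
    classify,
    fit_plda,
    from_latent,
    make_gaussian_feature_dataset,
    to_latent,
    truncate_psi,
)


def scalar_ml_plda(x_by_class):
    """Independent 1-D ML solution: simultaneous diagonalization by hand.

    For scalar data the whitening basis is w = 1/sqrt(S_w), so
    A = sqrt(n/(n-1) * S_w) and psi = max(0, (n-1)/n * S_b/S_w - 1/n).
    """
    allx = np.concatenate(x_by_class)
    n_per = len(x_by_class[0])
    m = allx.mean()
    S_w = np.mean([np.mean((x - x.mean()) ** 2) for x in x_by_class])
    S_b = np.mean([(x.mean() - m) ** 2 for x in x_by_class])
    lam = S_b / S_w
    A = np.sqrt(n_per / (n_per - 1) * S_w)
    psi = max(0.0, (n_per - 1) / n_per * lam - 1.0 / n_per)
    return m, A, psi


class TestFit:
    def test_matches_scalar_ml_solution(self, rng):
        """D=1 fit agrees with independently coded scalar ML formulas."""
        x_by_class = [rng.normal(mu, 1.3, size=20) for mu in (-2.0, 0.5, 2.5)]
        X = np.concatenate(x_by_class)[:, None]
        labels = np.repeat(["a", "b", "c"], 20)
        model = fit_plda(FeatureDataset(X=X, labels=labels), regularization=0.0)
        m, A, psi = scalar_ml_plda(x_by_class)
        assert model.shift[0] == pytest.approx(m, abs=1e-10)
        assert abs(model.transform[0, 0]) == pytest.approx(A, rel=1e-8)
        assert model.psi[0] == pytest.approx(psi, rel=1e-8)

    def test_degenerate_within_class_variance(self):
        """Classes collapsed onto their means fit with regularization, psi huge."""
        means = np.array([[0.0, 0.0], [5.0, 1.0], [-3.0, 4.0]])
        X = np.repeat(means, 4, axis=0)
        labels = np.repeat(["a", "b", "c"], 4)
        model = fit_plda(FeatureDataset(X=X, labels=labels), regularization=1e-6)
        assert np.all(np.isfinite(model.psi))
        assert model.psi.max() > 1e3  # between-class variance dwarfs within

    def test_singular_scatter_without_regularization_names_dimension(self):
        X = np.column_stack([np.arange(8.0), np.zeros(8)])  # dim 1 constant
        labels = np.repeat(["a", "b"], 4)
        with pytest.raises(np.linalg.LinAlgError, match="dimension 1"):
            fit_plda(FeatureDataset(X=X, labels=labels), regularization=0.0)

    def test_small_category_rejected(self):
        X = np.arange(6.0)[:, None]
        labels = np.array(["a", "a", "a", "a", "a", "b"])
        with pytest.raises(ValueError, match="category 'b'"):
            fit_plda(FeatureDataset(X=X, labels=labels))

    def test_parameter_recovery_on_generative_model(self):
        """Fitted psi tracks the realized between-class variance of the draw."""
        psi_true = np.array([4.0, 1.0, 0.25])
        spec = GaussianFeatureSpec(
            n_categories=50, items_per_category=200, feature_dim=3,
            psi_true=psi_true, seed=0,
        )
        dataset, truth = make_gaussian_feature_dataset(spec)
        model = fit_plda(dataset)
        v = truth["centers"]
        realized = np.sort(((v - v.mean(0)) ** 2).mean(0))[::-1]
        rel = np.abs(np.sort(model.psi)[::-1] - realized) / realized
        assert np.all(rel < 0.15)

    def test_consistency_in_number_of_classes(self):
        """Error to the generating psi shrinks as the number of classes grows."""
        psi_true = np.array([4.0, 1.0, 0.25])
        errs = []
        for K in (50, 500):
            reps = []
            for r in range(4):
                spec = GaussianFeatureSpec(
                    n_categories=K, items_per_category=30, feature_dim=3,
                    psi_true=psi_true, seed=100 + r,
                )
                dataset, _ = make_gaussian_feature_dataset(spec)
                model = fit_plda(dataset)
                reps.append(
                    np.median(np.abs(np.sort(model.psi)[::-1] - psi_true) / psi_true)
                )
            errs.append(np.median(reps))
        assert errs[1] < errs[0]

    def test_model_json_round_trip(self, fitted, tmp_path):
        _, model = fitted
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = PLDAModel.from_json(path)
        np.testing.assert_array_equal(loaded.shift, model.shift)
        np.testing.assert_array_equal(loaded.transform, model.transform)
        np.testing.assert_array_equal(loaded.psi, model.psi)
        assert loaded.metadata == json.loads(json.dumps(model.metadata))

    def test_truncate_psi_keeps_top_k(self, fitted):
        _, model = fitted
        truncated = truncate_psi(model, 1)
        assert np.count_nonzero(truncated.psi) <= 1
        assert truncated.psi.max() == model.psi.max()


class TestLatentTransform:
    def test_identity_model_is_identity(self, rng):
        model = PLDAModel(np.zeros(3), np.eye(3), np.ones(3), 3)
        x = rng.standard_normal(3)
        np.testing.assert_allclose(to_latent(x, model), x)

    def test_shift_maps_to_origin(self):
        model = PLDAModel(np.array([1.0, -2.0]), 2 * np.eye(2), np.ones(2), 2)
        np.testing.assert_allclose(to_latent(model.shift, model), 0.0)

    def test_round_trip_random_affine(self, rng):
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        model = PLDAModel(rng.standard_normal(3), A, np.ones(3), 3)
        x = rng.standard_normal((5, 3))
        np.testing.assert_allclose(from_latent(to_latent(x, model), model), x, atol=1e-10)

    def test_length_mismatch_rejected(self, fitted):
        _, model = fitted
        with pytest.raises(ValueError, match="length"):
            to_latent(np.zeros(model.feature_dim + 1), model)


class TestPredictiveDensity:
    def test_zero_psi_is_standard_normal(self, rng):
        u_star = rng.standard_normal(4)
        examples = rng.standard_normal((3, 4))
        got = class_predictive_logdensity(u_star, examples, np.zeros(4))
        assert got == pytest.approx(norm.logpdf(u_star).sum(), abs=1e-12)

    def test_example_order_symmetry(self, rng):
        psi = np.array([1.0, 2.0])
        u1, u2, u_star = rng.standard_normal((3, 2))
        a = class_predictive_logdensity(u_star, [u1, u2], psi)
        b = class_predictive_logdensity(u_star, [u2, u1], psi)
        assert a == b

    def test_matches_direct_diagonal_gaussian(self):
        """Two-example closed form vs an independently coded density."""
        psi = np.array([1.0, 2.0])
        u1 = np.array([1.0, 0.0])
        u2 = np.array([0.0, 1.0])
        u_star = np.array([0.5, 0.5])
        mean = psi / (2 * psi + 1) * (u1 + u2)
        var = psi / (2 * psi + 1) + 1
        expected = norm.logpdf(u_star, loc=mean, scale=np.sqrt(var)).sum()
        got = class_predictive_logdensity(u_star, [u1, u2], psi)
        assert got == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("n", [1, 2, 5])
    def test_general_n_matches_literal_formula(self, rng, n):
        psi = np.abs(rng.standard_normal(3))
        U = rng.standard_normal((n, 3))
        u_star = rng.standard_normal(3)
        ubar = U.mean(axis=0)
        mean = n * psi / (n * psi + 1) * ubar
        var = psi / (n * psi + 1) + 1
        expected = norm.logpdf(u_star, loc=mean, scale=np.sqrt(var)).sum()
        got = class_predictive_logdensity(u_star, U, psi)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_large_psi_limit_moments(self):
        """psi -> inf with two examples: mode -> (u1+u2)/2, variance -> 3/2.

        Moments are recovered numerically from the density itself (mode by
        golden-section-free fine grid, variance by log-density curvature),
        independent of the implementation's internal formula.
        """
        psi = np.array([1e8])
        u1, u2 = np.array([0.6]), np.array([1.8])
        center = 1.2
        grid = np.linspace(center - 0.01, center + 0.01, 2001)
        logp = np.array(
            [class_predictive_logdensity(np.array([g]), [u1, u2], psi) for g in grid]
        )
        mode = grid[np.argmax(logp)]
        assert mode == pytest.approx((u1[0] + u2[0]) / 2, abs=1e-4)
        h = 1e-3
        d2 = (
            class_predictive_logdensity(np.array([center + h]), [u1, u2], psi)
            - 2 * class_predictive_logdensity(np.array([center]), [u1, u2], psi)
            + class_predictive_logdensity(np.array([center - h]), [u1, u2], psi)
        ) / h**2
        assert -1.0 / d2 == pytest.approx(1.5, abs=1e-4)

    def test_negative_psi_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            class_predictive_logdensity(np.zeros(1), [np.zeros(1)], np.array([-0.1]))


class TestClassify:
    def test_identical_example_sets_are_even(self, fitted, rng):
        _, model = fitted
        ex = rng.standard_normal((4, model.feature_dim))
        probs = classify(
            rng.standard_normal(model.feature_dim), model, {"a": ex, "b": ex}
        )
        assert probs["a"] == pytest.approx(0.5, abs=1e-12)

    def test_target_at_class_mean_wins(self):
        model = PLDAModel(np.zeros(2), np.eye(2), np.full(2, 100.0), 2)
        ex_a = np.array([[3.0, 3.0], [3.2, 2.8]])
        ex_b = np.array([[-3.0, -3.0], [-2.8, -3.2]])
        probs = classify(ex_a.mean(axis=0), model, {"a": ex_a, "b": ex_b})
        assert probs["a"] > probs["b"]
        # brute-force density comparison backs the argmax
        la = class_predictive_logdensity(ex_a.mean(axis=0), ex_a, model.psi)
        lb = class_predictive_logdensity(ex_a.mean(axis=0), ex_b, model.psi)
        assert la > lb

    def test_probabilities_sum_to_one(self, fitted, rng):
        _, model = fitted
        D = model.feature_dim
        ex = {c: rng.standard_normal((3, D)) for c in "abc"}
        probs = classify(rng.standard_normal(D), model, ex)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_category_rejected(self, fitted):
        _, model = fitted
        D = model.feature_dim
        with pytest.raises(ValueError, match="no examples"):
            classify(np.zeros(D), model, {"a": np.zeros((2, D)), "b": np.zeros((0, D))})
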