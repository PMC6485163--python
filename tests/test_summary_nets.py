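"""Network-ensemble summary statistics."""

import numpy as np
import pytest

from ghostabc.summary_nets import (
    FULL_SCALE,
    SummaryEnsemble,
    predict_ss,
    select_network_by_spearman,
    train_classifier,
    train_parameter_regressors,
)


def gaussian_blobs(rng, n_per_class, dim=12, sep=6.0, n_classes=2):
    X, y = [], []
    for c in range(n_classes):
        centre = np.zeros(dim)
        centre[c % dim] = sep * (1 + c // dim)
        X.append(rng.normal(size=(n_per_class, dim)) + centre)
        y.append(np.full(n_per_class, chr(ord("A") + c)))
    return np.vstack(X), np.concatenate(y)


@pytest.fixture(scope="module")
def separable_ensemble():
    rng = np.random.default_rng(0)
    X, y = gaussian_blobs(rng, 150)
    ens = train_classifier(X, y, n_networks=4, hidden=(16, 8, 8, 4),
                           rng_seed=1, max_iter=300)
    return ens, rng


class TestClassifier:
    def test_separable_classes_high_heldout_accuracy(self, separable_ensemble):
        ens, rng = separable_ensemble
        Xt, yt = gaussian_blobs(np.random.default_rng(99), 100)
        probs = predict_ss(ens, Xt)
        acc = (np.asarray(ens.classes)[probs.argmax(1)] == yt).mean()
        assert acc >= 0.95

    def test_permuted_labels_are_at_chance(self):
        """Six classes with shuffled labels: held-out accuracy ~ 1/6."""
        rng = np.random.default_rng(3)
        X, y = gaussian_blobs(rng, 120, n_classes=6)
        y = rng.permutation(y)
        ens = train_classifier(X[:600], y[:600], n_networks=3,
                               hidden=(16, 8, 8, 4), rng_seed=2, max_iter=100)
        probs = predict_ss(ens, X[600:])
        acc = (np.asarray(ens.classes)[probs.argmax(1)] == y[600:]).mean()
        n = len(y) - 600
        se = np.sqrt((1 / 6) * (5 / 6) / n)
        assert abs(acc - 1 / 6) < 3 * se

    def test_probabilities_sum_to_one(self, separable_ensemble):
        ens, _ = separable_ensemble
        X = np.random.default_rng(5).normal(size=(1000, 12))
        probs = predict_ss(ens, X)
        np.testing.assert_allclose(probs.sum(1), 1.0, atol=1e-9)

    def test_prediction_is_mean_of_members(self, separable_ensemble):
        """Manual member-by-member averaging oracle."""
        ens, _ = separable_ensemble
        X = np.random.default_rng(6).normal(size=(20, 12))
        manual = np.mean([m.predict_proba(X) for m in ens.members], axis=0)
        np.testing.assert_allclose(predict_ss(ens, X), manual)

    def test_retraining_same_seed_is_identical(self):
        rng = np.random.default_rng(7)
        X, y = gaussian_blobs(rng, 60)
        Xt = np.random.default_rng(8).normal(size=(30, 12))
        a = predict_ss(train_classifier(X, y, n_networks=2, rng_seed=4,
                                        hidden=(8, 8, 4, 4), max_iter=60), Xt)
        b = predict_ss(train_classifier(X, y, n_networks=2, rng_seed=4,
                                        hidden=(8, 8, 4, 4), max_iter=60), Xt)
        np.testing.assert_array_equal(a, b)

    def test_single_class_errors(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError):
            train_classifier(X, np.array(["A"] * 10))

    def test_zero_dimension_errors(self):
        with pytest.raises(ValueError):
            train_classifier(np.zeros((10, 0)), np.array(["A", "B"] * 5))

    def test_dimension_mismatch_on_predict(self, separable_ensemble):
        ens, _ = separable_ensemble
        with pytest.raises(ValueError, match="dimension"):
            predict_ss(ens, np.zeros((3, 5)))

    def test_full_scale_configuration(self):
        assert FULL_SCALE["classifier_sims_per_model"] == 15_000
        assert FULL_SCALE["classifier_sims_total"] == 90_000
        assert FULL_SCALE["regressor_sims_per_parameter"] == 20_000


class TestRegressor:
    def test_constant_target_predicts_constant(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(300, 6))
        ens = train_parameter_regressors(X, np.zeros(300), n_networks=3,
                                         hidden=(8, 8, 4, 4), rng_seed=0, max_iter=60)
        preds = predict_ss(ens, rng.normal(size=(50, 6)))
        assert np.abs(preds).max() < 0.1

    def test_linear_function_of_one_cell_is_learned(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(2000, 6))
        t = 3.0 * X[:, 2] + 5.0
        ens = train_parameter_regressors(X[:1600], t[:1600], n_networks=3,
                                         hidden=(32, 16, 8, 4), rng_seed=1,
                                         max_iter=500)
        preds = predict_ss(ens, X[1600:])
        ss_res = ((preds - t[1600:]) ** 2).sum()
        ss_tot = ((t[1600:] - t[1600:].mean()) ** 2).sum()
        assert 1 - ss_res / ss_tot >= 0.99

    def test_predictions_on_natural_scale(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(400, 4))
        t = 500.0 + 100.0 * X[:, 0]
        ens = train_parameter_regressors(X, t, n_networks=2, hidden=(16, 8, 4, 4),
                                         rng_seed=2, max_iter=300)
        preds = predict_ss(ens, X)
        assert abs(preds.mean() - 500.0) < 50


def spearman_by_definition(x, y):
    """Rank-correlation oracle straight from the definition."""
    rx = np.argsort(np.argsort(x)).astype(float)
    ry = np.argsort(np.argsort(y)).astype(float)
    return np.corrcoef(rx, ry)[0, 1]


class _StubMember:
    def __init__(self, outputs):
        self.outputs = np.asarray(outputs, dtype=float)

    def predict(self, X):
        return self.outputs[: len(X)]


def stub_ensemble(member_outputs, input_dim=3):
    return SummaryEnsemble(
        members=[_StubMember(o) for o in member_outputs],
        task="regress",
        input_dim=input_dim,
    )


class TestSpearmanSelection:
    def test_truth_tracking_member_wins(self):
        truth = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        noise = np.array([2.0, 1.0, 5.0, 3.0, 4.0])
        ens = stub_ensemble([noise, truth, noise[::-1]])
        X = np.zeros((5, 3))
        assert select_network_by_spearman(ens, X, truth) == 1
        assert ens.selected_member == 1
        # subsequent SS-DL uses the selected member alone
        np.testing.assert_array_equal(predict_ss(ens, X), truth)

    def test_tie_broken_by_lowest_index(self):
        truth = np.arange(5.0)
        ens = stub_ensemble([truth * 2, truth + 7, truth[::-1]])
        assert select_network_by_spearman(ens, np.zeros((5, 3)), truth) == 0

    def test_matches_rank_correlation_oracle(self):
        rng = np.random.default_rng(12)
        truth = rng.normal(size=10)
        outputs = [rng.normal(size=10) for _ in range(4)]
        ens = stub_ensemble(outputs, input_dim=2)
        best = select_network_by_spearman(ens, np.zeros((10, 2)), truth)
        rhos = [spearman_by_definition(o, truth) for o in outputs]
        assert best == int(np.argmax(rhos))

    def test_constant_predictions_error(self):
        ens = stub_ensemble([np.ones(5), np.zeros(5)])
        with pytest.raises(ValueError, match="constant"):
            select_network_by_spearman(ens, np.zeros((5, 3)), np.arange(5.0))

    def test_constant_truth_errors(self):
        ens = stub_ensemble([np.arange(5.0)])
        with pytest.raises(ValueError, match="distinct"):
            select_network_by_spearman(ens, np.zeros((5, 3)), np.ones(5))
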