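import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from waverisk.cnn import ConvNetClassifier, pooled_feature_count, repeat_train_select_best
from waverisk.metrics import auc
from waverisk.wavelet import decompose_cohort


@pytest.fixture(scope="module")
def trained():
    """One small trained network shared by the read-only forward-pass tests."""
    rng = np.random.default_rng(7)
    n, p = 120, 64
    y = np.array([0, 1] * (n // 2))
    X = np.exp(rng.normal(1.5, 0.5, size=(n, p)))
    X[:, :10] *= np.exp(1.2 * y)[:, None]
    tensor, _ = decompose_cohort(X.T, "db3")
    clf = ConvNetClassifier(n_filters=8, dense_units=8, epochs=15,
                            learning_rate=1e-3, random_state=0).fit(tensor, y)
    return clf, tensor, y


class TestPooledArithmetic:
    @pytest.mark.parametrize("p,w,f", [(26270, 8, 3284), (16, 8, 2), (17, 8, 3)])
    def test_examples(self, p, w, f):
        assert pooled_feature_count(p, w) == f

    @given(st.integers(8, 5000))
    @settings(max_examples=50, deadline=None)
    def test_ceiling_property(self, p):
        f = pooled_feature_count(p, 8)
        assert (f - 1) * 8 < p <= f * 8

    def test_too_short_input(self):
        with pytest.raises(ValueError):
            pooled_feature_count(4, 8)


class TestTraining:
    def test_separable_training_auc(self, separable_dataset):
        X, y = separable_dataset
        # signal strength benchmark: logistic on the planted genes alone
        sc = StandardScaler().fit(np.log2(X[:, :20] + 1))
        lr = LogisticRegression(max_iter=1000).fit(sc.transform(np.log2(X[:, :20] + 1)), y)
        assert auc(y, lr.predict_proba(sc.transform(np.log2(X[:, :20] + 1)))[:, 1]) >= 0.95

        tensor, _ = decompose_cohort(X.T, "db3")
        clf = ConvNetClassifier(n_filters=16, epochs=25, learning_rate=1e-3,
                                random_state=1).fit(tensor, y)
        assert auc(y, clf.decision_scores(tensor)) >= 0.95

    def test_loss_history_decreases(self, trained):
        clf, _, _ = trained
        assert len(clf.history_) == clf.epochs
        assert clf.history_[-1] <= clf.history_[0]

    def test_same_seed_identical(self, separable_dataset):
        X, y = separable_dataset
        tensor, _ = decompose_cohort(X[:60].T, "db1")
        a = ConvNetClassifier(n_filters=4, epochs=3, random_state=9).fit(tensor, y[:60])
        b = ConvNetClassifier(n_filters=4, epochs=3, random_state=9).fit(tensor, y[:60])
        np.testing.assert_array_equal(a.predict_proba(tensor), b.predict_proba(tensor))

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 16, 1))
        with pytest.raises(ValueError, match="two classes"):
            ConvNetClassifier(epochs=1).fit(X, np.zeros(10))

    def test_permuted_labels_near_chance(self, rng):
        n, p = 80, 32
        X = np.exp(rng.normal(1, 0.5, size=(n, p)))
        aucs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            y = r.permutation([0, 1] * (n // 2))
            tensor, _ = decompose_cohort(X[:60].T, "db1")
            tensor_va, _ = decompose_cohort(X[60:].T, "db1")
            clf = ConvNetClassifier(n_filters=4, dense_units=4, epochs=5,
                                    random_state=seed).fit(tensor, y[:60])
            aucs.append(auc(y[60:], clf.decision_scores(tensor_va)))
        assert abs(np.mean(aucs) - 0.5) <= 0.15


class TestPredictProba:
    def test_rows_sum_to_one(self, trained):
        clf, tensor, _ = trained
        pr = clf.predict_proba(tensor)
        np.testing.assert_allclose(pr.sum(axis=1), 1.0, atol=1e-12)
        assert (pr >= 0).all() and (pr <= 1).all()

    def test_duplicated_sample_identical(self, trained):
        clf, tensor, _ = trained
        dup = np.stack([tensor[3], tensor[3]])
        pr = clf.predict_proba(dup)
        np.testing.assert_array_equal(pr[0], pr[1])

    def test_batching_invariance(self, trained):
        clf, tensor, _ = trained
        whole = clf.predict_proba(tensor, batch=1000)
        tiny = clf.predict_proba(tensor, batch=7)
        np.testing.assert_allclose(whole, tiny, atol=1e-12)

    def test_shape_mismatch_errors(self, trained):
        clf, _, _ = trained
        with pytest.raises(ValueError, match="does not match"):
            clf.predict_proba(np.zeros((2, 32, 3)))


def forward_pass_oracle(clf, sample):
    """Direct single-sample recomputation of the representative features."""
    sample = (sample - clf.input_center_) / clf.input_scale_
    p, m = sample.shape
    K = clf.kernel_length
    pl = (K - 1) // 2
    xp = np.pad(sample, ((pl, K - 1 - pl), (0, 0)))
    conv = np.zeros((p, clf.n_filters))
    for i in range(p):
        for f in range(clf.n_filters):
            conv[i, f] = np.sum(xp[i : i + K] * clf.W_conv_[:, :, f]) + clf.b_conv_[f]
    act = np.maximum(conv, 0)
    nf = clf.n_pooled_features_
    pooled = np.full((nf, clf.n_filters), -np.inf)
    for j in range(nf):
        pooled[j] = act[j * clf.pool_window : (j + 1) * clf.pool_window].max(axis=0)
    return pooled.mean(axis=1)


class TestRepresentativeFeatures:
    def test_shape(self, trained):
        clf, tensor, _ = trained
        F = clf.representative_features(tensor)
        assert F.shape == (clf.n_pooled_features_, tensor.shape[0])

    def test_zero_conv_weights_give_zero_features(self, trained):
        import copy

        clf, tensor, _ = trained
        z = copy.deepcopy(clf)
        z.W_conv_ = np.zeros_like(z.W_conv_)
        z.b_conv_ = np.zeros_like(z.b_conv_)
        np.testing.assert_array_equal(z.representative_features(tensor), 0.0)

    def test_matches_forward_pass_oracle(self, trained):
        clf, tensor, _ = trained
        got = clf.representative_features(tensor[5:6])[:, 0]
        want = forward_pass_oracle(clf, tensor[5])
        np.testing.assert_allclose(got, want, atol=1e-10)


@pytest.fixture(scope="module")
def small():
    rng = np.random.default_rng(3)
    n, p = 80, 32
    y = np.array([0, 1] * (n // 2))
    X = np.exp(rng.normal(1, 0.5, size=(n, p)))
    X[:, :8] *= np.exp(1.5 * y)[:, None]
    tensor, _ = decompose_cohort(X.T, "db1")
    return tensor, y


class TestRepeatTrainSelectBest:
    def test_runs_one_equals_single_fit(self, small):
        tensor, y = small
        kw = dict(n_filters=4, dense_units=4, epochs=4)
        a = repeat_train_select_best(tensor, y, runs=1, random_state=2, **kw)
        b = ConvNetClassifier(random_state=2, **kw).fit(tensor, y)
        np.testing.assert_array_equal(a.predict_proba(tensor), b.predict_proba(tensor))

    def test_deterministic_winner(self, small):
        tensor, y = small
        kw = dict(n_filters=4, dense_units=4, epochs=4)
        a = repeat_train_select_best(tensor, y, runs=3, random_state=5, **kw)
        b = repeat_train_select_best(tensor, y, runs=3, random_state=5, **kw)
        np.testing.assert_array_equal(a.predict_proba(tensor), b.predict_proba(tensor))

    def test_winner_is_argmax(self, small):
        tensor, y = small
        kw = dict(n_filters=4, dense_units=4, epochs=4)
        best = repeat_train_select_best(tensor, y, runs=3, random_state=8, **kw)
        # recompute all candidate scores on the same inner split
        rng = np.random.default_rng(8)
        n = tensor.shape[0]
        n_inner = int(np.floor(0.7 * n))
        perm = rng.permutation(n)
        tr, va = perm[:n_inner], perm[n_inner:]
        scores = []
        for _ in range(3):
            seed = int(rng.integers(0, 2**31 - 1))
            clf = ConvNetClassifier(random_state=seed, **kw).fit(tensor[tr], y[tr])
            scores.append(auc(y[va], clf.decision_scores(tensor[va])))
        assert auc(y[va], best.decision_scores(tensor[va])) == pytest.approx(max(scores))


class TestSerialization:
    def test_round_trip(self, trained, tmp_path):
        clf, tensor, _ = trained
        path = tmp_path / "model.npz"
        clf.save(path)
        loaded = ConvNetClassifier.load(path)
        np.testing.assert_allclose(loaded.predict_proba(tensor), clf.predict_proba(tensor))
        assert loaded.get_params() == clf.get_params()
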