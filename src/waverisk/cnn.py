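"""One-convolutional-layer network for wavelet-coefficient tensors.

The architecture is fixed to: input (p positions x m channels) -> 1-D
convolution (length-preserving, relu) -> max pooling (ceiling padding) ->
flatten -> dense relu -> dense softmax over the two risk classes, trained
with RMSprop on the binary cross-entropy. The post-pooling activations,
averaged over the convolution filters, are the "representative features"
used for gene scoring.

Implemented directly on numpy (im2col convolution with manual backprop) so
training is fully deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin


@dataclass
class CNNConfig:
    """Hyperparameters of the one-layer convolutional classifier."""

    n_filters: int = 64
    kernel_length: int = 8
    pool_window: int = 8
    dense_units: int = 32
    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 16
    seed: int = 0


def pooled_feature_count(p: int, pool_window: int) -> int:
    """Number of pooled positions for a length-p input: ceil(p / pool_window)."""
    if p < pool_window:
        raise ValueError(f"input length {p} is shorter than the pooling window {pool_window}")
    return -(-p // pool_window)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ConvNetClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style classifier over (n, p, m) wavelet tensors.

    2-D input (n, p) is accepted and treated as a single channel. Fitted
    attributes: ``W_conv_`` (kernel_length, m, n_filters), ``b_conv_``,
    ``W1_``, ``b1_``, ``W2_``, ``b2_``, and ``history_`` (per-epoch mean
    training loss).
    """

    def __init__(
        self,
        n_filters: int = 64,
        kernel_length: int = 8,
        pool_window: int = 8,
        dense_units: int = 32,
        learning_rate: float = 1e-4,
        epochs: int = 50,
        batch_size: int = 16,
        input_norm: str = "global",
        random_state: int = 0,
    ):
        self.n_filters = n_filters
        self.kernel_length = kernel_length
        self.pool_window = pool_window
        self.dense_units = dense_units
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.input_norm = input_norm
        self.random_state = random_state

    # ---- shape plumbing -------------------------------------------------

    @staticmethod
    def _as_tensor(X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, :, None]
        if X.ndim != 3:
            raise ValueError("expected input of shape (n_samples, positions[, channels])")
        return X

    def _check_shape(self, X):
        if X.shape[1] != self.input_length_ or X.shape[2] != self.n_channels_:
            raise ValueError(
                f"input shape {X.shape[1:]} does not match the fitted model "
                f"({self.input_length_}, {self.n_channels_})"
            )

    def _normalize(self, X):
        """Single global affine transform learned on the training tensor.

        One scalar center and one scalar scale for the whole tensor: keeps
        the relative magnitudes of all genes/coefficients intact (so the
        network still sees magnitude structure) while bringing values to a
        range where gradient optimisation behaves.
        """
        return (X - self.input_center_) / self.input_scale_

    # ---- forward pieces -------------------------------------------------

    def _conv_cols(self, X):
        """im2col view for a length-preserving convolution: (n, p, K*m)."""
        n, p, m = X.shape
        K = self.kernel_length
        pl = (K - 1) // 2
        pr = K - 1 - pl
        Xp = np.pad(X, ((0, 0), (pl, pr), (0, 0)))
        idx = np.arange(p)[:, None] + np.arange(K)[None, :]
        return Xp[:, idx, :].reshape(n, p, K * m)

    def _forward(self, X, keep=False):
        n, p, m = X.shape
        cols = self._conv_cols(X)                                   # (n, p, K*m)
        Z = cols @ self.W_conv_.reshape(-1, self.n_filters) + self.b_conv_
        A = np.maximum(Z, 0.0)                                      # (n, p, F)
        f = pooled_feature_count(p, self.pool_window)
        pad = f * self.pool_window - p
        Ap = np.pad(A, ((0, 0), (0, pad), (0, 0)), constant_values=-np.inf)
        Ap = Ap.reshape(n, f, self.pool_window, self.n_filters)
        pool_arg = Ap.argmax(axis=2)
        P = np.take_along_axis(Ap, pool_arg[:, :, None, :], axis=2)[:, :, 0, :]
        flat = P.reshape(n, -1)
        H = np.maximum(flat @ self.W1_ + self.b1_, 0.0)
        logits = H @ self.W2_ + self.b2_
        probs = _softmax(logits)
        if keep:
            return probs, (cols, Z, A, pool_arg, P, flat, H)
        return probs

    # ---- estimator API --------------------------------------------------

    def fit(self, X, y):
        X = self._as_tensor(X)
        y = np.asarray(y).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("sample count of X and y differ")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"need exactly two classes, got {self.classes_!r}")
        y01 = (y == self.classes_[1]).astype(int)

        n, p, m = X.shape
        self.input_length_ = p
        self.n_channels_ = m
        self.n_pooled_features_ = pooled_feature_count(p, self.pool_window)
        if self.input_norm == "global":
            self.input_center_ = float(X.mean())
            self.input_scale_ = float(X.std()) or 1.0
        elif self.input_norm == "none":
            self.input_center_, self.input_scale_ = 0.0, 1.0
        else:
            raise ValueError(f"unknown input_norm {self.input_norm!r}")
        X = self._normalize(X)
        K, F, D = self.kernel_length, self.n_filters, self.dense_units
        rng = np.random.default_rng(self.random_state)

        def glorot(shape, fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape)

        flat_dim = self.n_pooled_features_ * F
        self.W_conv_ = glorot((K, m, F), K * m, F)
        self.b_conv_ = np.zeros(F)
        self.W1_ = glorot((flat_dim, D), flat_dim, D)
        self.b1_ = np.zeros(D)
        self.W2_ = glorot((D, 2), D, 2)
        self.b2_ = np.zeros(2)

        params = ["W_conv_", "b_conv_", "W1_", "b1_", "W2_", "b2_"]
        cache = {name: np.zeros_like(getattr(self, name)) for name in params}
        rho, eps, lr = 0.9, 1e-8, self.learning_rate

        onehot = np.zeros((n, 2))
        onehot[np.arange(n), y01] = 1.0

        self.history_ = []
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                b = order[start : start + self.batch_size]
                probs, (cols, Z, A, pool_arg, P, flat, H) = self._forward(X[b], keep=True)
                nb = len(b)
                losses.append(-np.log(np.clip(probs[np.arange(nb), y01[b]], 1e-12, None)).mean() * nb)

                grads = self._backward(X[b], onehot[b], probs, cols, Z, pool_arg, flat, H)
                for name in params:
                    g = grads[name]
                    c = cache[name]
                    c *= rho
                    c += (1 - rho) * g * g
                    getattr(self, name).__isub__(lr * g / (np.sqrt(c) + eps))
            self.history_.append(float(np.sum(losses) / n))
        return self

    def _backward(self, Xb, onehot_b, probs, cols, Z, pool_arg, flat, H):
        nb, p, m = Xb.shape
        F, K = self.n_filters, self.kernel_length
        f = self.n_pooled_features_

        dlogits = (probs - onehot_b) / nb
        gW2 = H.T @ dlogits
        gb2 = dlogits.sum(axis=0)
        dH = dlogits @ self.W2_.T
        dH[H <= 0] = 0.0
        gW1 = flat.T @ dH
        gb1 = dH.sum(axis=0)
        dflat = dH @ self.W1_.T
        dP = dflat.reshape(nb, f, F)

        # un-pool: route gradients to the argmax positions
        dAp = np.zeros((nb, f, self.pool_window, F))
        np.put_along_axis(dAp, pool_arg[:, :, None, :], dP[:, :, None, :], axis=2)
        dA = dAp.reshape(nb, f * self.pool_window, F)[:, :p, :]
        dA[Z <= 0] = 0.0

        gW_conv = np.einsum("npk,npf->kf", cols, dA).reshape(K, m, F)
        gb_conv = dA.sum(axis=(0, 1))
        return {
            "W_conv_": gW_conv, "b_conv_": gb_conv,
            "W1_": gW1, "b1_": gb1, "W2_": gW2, "b2_": gb2,
        }

    def predict_proba(self, X, batch: int = 256):
        X = self._as_tensor(X)
        self._check_shape(X)
        X = self._normalize(X)
        out = [self._forward(X[i : i + batch]) for i in range(0, X.shape[0], batch)]
        return np.vstack(out)

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] > 0.5).astype(int)]

    def decision_scores(self, X):
        """Positive-class probability, the continuous score used for AUC."""
        return self.predict_proba(X)[:, 1]

    def pooled_activations(self, X, batch: int = 256):
        """Post-pooling activations, shape (n, pooled_features, n_filters)."""
        X = self._as_tensor(X)
        self._check_shape(X)
        X = self._normalize(X)
        chunks = []
        for i in range(0, X.shape[0], batch):
            _, (_, _, _, _, P, _, _) = self._forward(X[i : i + batch], keep=True)
            chunks.append(P)
        return np.vstack(chunks)

    def representative_features(self, X):
        """Channel-averaged pooled activations, shape (pooled_features, n_samples).

        This is the matrix X of the least-squares gene-scoring step (features
        in rows, samples in columns).
        """
        return self.pooled_activations(X).mean(axis=2).T

    # ---- (de)serialization ---------------------------------------------

    def save(self, path):
        import json

        np.savez(
            path,
            config=np.frombuffer(json.dumps(self.get_params()).encode(), dtype=np.uint8),
            classes=self.classes_,
            meta=np.array([self.input_length_, self.n_channels_]),
            norm=np.array([self.input_center_, self.input_scale_]),
            W_conv=self.W_conv_, b_conv=self.b_conv_,
            W1=self.W1_, b1=self.b1_, W2=self.W2_, b2=self.b2_,
            history=np.array(self.history_),
        )

    @classmethod
    def load(cls, path):
        import json

        with np.load(path, allow_pickle=False) as z:
            params = json.loads(bytes(z["config"].tobytes()).decode())
            clf = cls(**params)
            clf.classes_ = z["classes"]
            clf.input_length_, clf.n_channels_ = (int(v) for v in z["meta"])
            clf.input_center_, clf.input_scale_ = (float(v) for v in z["norm"])
            clf.n_pooled_features_ = pooled_feature_count(clf.input_length_, clf.pool_window)
            clf.W_conv_, clf.b_conv_ = z["W_conv"], z["b_conv"]
            clf.W1_, clf.b1_ = z["W1"], z["b1"]
            clf.W2_, clf.b2_ = z["W2"], z["b2"]
            clf.history_ = z["history"].tolist()
        return clf


def repeat_train_select_best(
    X,
    y,
    runs: int = 100,
    random_state: int = 0,
    inner_fraction: float = 0.7,
    **cnn_params,
) -> ConvNetClassifier:
    """Train ``runs`` classifiers with derived seeds; keep the best one.

    Each run trains on an inner split of the provided training data
    (``inner_fraction`` of the samples) and is scored by AUC on the held-back
    remainder; the highest-scoring model is returned (ties: lowest run
    index). With ``runs=1`` the single model is trained on all provided data.
    """
    from .metrics import auc

    X = ConvNetClassifier._as_tensor(X)
    y = np.asarray(y).ravel()
    if runs == 1:
        return ConvNetClassifier(random_state=random_state, **cnn_params).fit(X, y)

    rng = np.random.default_rng(random_state)
    n = X.shape[0]
    n_inner = int(np.floor(inner_fraction * n))
    for _ in range(100):
        perm = rng.permutation(n)
        tr, va = perm[:n_inner], perm[n_inner:]
        if len(set(y[tr])) == 2 and len(set(y[va])) == 2:
            break
    else:
        raise RuntimeError("could not draw an inner split with both classes")

    best = None
    for run in range(runs):
        seed = int(rng.integers(0, 2**31 - 1))
        clf = ConvNetClassifier(random_state=seed, **cnn_params).fit(X[tr], y[tr])
        score = auc(y[va], clf.decision_scores(X[va]))
        if best is None or score > best[0]:
            best = (score, run, clf)
    return best[2]
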