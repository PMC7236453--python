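"""Stationary (undecimated) wavelet decomposition of per-sample expression profiles.

Each sample's profile is treated as a 1-D signal over the ordered gene list.
The stationary wavelet transform (SWT, a.k.a. undecimated or à-trous
transform) keeps the signal length at every level, so coefficient positions
stay aligned with genes; only the approximation (low-frequency) bands
cA_1..cA_m are retained and stacked as input channels for the classifier.

The transform uses periodic signal extension internally (PyWavelets'
convention), which also makes it exactly shift-invariant; profiles are first
tail-padded to a multiple of 2^m by symmetric reflection and the
coefficients truncated back to the original length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin

#: the 12 candidate wavelet functions (4 families x 3 members)
WAVELET_FUNCTIONS = (
    "db1", "db3", "db5",
    "coif1", "coif3", "coif5",
    "bior3.1", "bior3.3", "bior3.5",
    "sym2", "sym4", "sym6",
)

DEFAULT_LEVELS = 3


@dataclass(frozen=True)
class WaveletSpec:
    """A wavelet family function plus a decomposition depth."""

    function: str = "db3"
    levels: int = DEFAULT_LEVELS

    def __post_init__(self):
        validate_wavelet(self.function)
        if self.levels < 1:
            raise ValueError("levels must be >= 1")


@dataclass
class PadRecord:
    original_length: int
    pad: int


def validate_wavelet(name: str) -> None:
    if name not in WAVELET_FUNCTIONS:
        raise ValueError(
            f"unknown wavelet function {name!r}; valid names: {', '.join(WAVELET_FUNCTIONS)}"
        )


def pad_profile(x: np.ndarray, levels: int = DEFAULT_LEVELS) -> tuple[np.ndarray, PadRecord]:
    """Extend a profile at the tail to the next multiple of 2^levels.

    Symmetric reflection is used for the appended values. Returns the padded
    vector and a record of the original length and pad amount so that
    coefficients can be truncated back.
    """
    x = np.asarray(x, dtype=float).ravel()
    p = x.size
    if p < 1:
        raise ValueError("empty profile")
    block = 2 ** levels
    pad = (-p) % block
    if pad == 0:
        return x.copy(), PadRecord(p, 0)
    # symmetric reflection off the tail, cycling if the profile is very short
    reflect = x[::-1]
    tail = np.resize(np.concatenate([reflect, x]), pad)
    return np.concatenate([x, tail]), PadRecord(p, pad)


def swt_approximations(x: np.ndarray, wavelet: WaveletSpec | str, levels: int | None = None) -> np.ndarray:
    """Stationary-transform approximation coefficients cA_1..cA_m of a padded profile.

    Returns an (m, len(x)) array, level 1 first. Detail coefficients are
    computed by the filter bank but discarded.
    """
    if isinstance(wavelet, WaveletSpec):
        name, m = wavelet.function, wavelet.levels
    else:
        name, m = wavelet, levels or DEFAULT_LEVELS
    validate_wavelet(name)
    x = np.asarray(x, dtype=float).ravel()
    if x.size % (2 ** m) != 0:
        raise ValueError("profile length must be a multiple of 2^levels; use pad_profile first")
    bands = pywt.swt(x, name, level=m, trim_approx=False)
    # pywt orders levels coarsest first; restack as cA_1..cA_m
    return np.stack([bands[m - 1 - j][0] for j in range(m)])


def decompose_cohort(expr_values: np.ndarray, wavelet: WaveletSpec | str = "db3", levels: int | None = None) -> tuple[np.ndarray, PadRecord]:
    """Decompose every sample of a genes x samples matrix.

    Returns a (n_samples, p, m) tensor of approximation coefficients
    truncated back to the original gene count p, plus the pad record.
    """
    if isinstance(wavelet, WaveletSpec):
        spec = wavelet
    else:
        spec = WaveletSpec(wavelet, levels or DEFAULT_LEVELS)
    vals = np.asarray(expr_values, dtype=float)
    if vals.ndim != 2:
        raise ValueError("expected a 2-D genes x samples matrix")
    p, n = vals.shape
    first, rec = pad_profile(vals[:, 0], spec.levels)
    out = np.empty((n, p, spec.levels))
    for i in range(n):
        padded, _ = pad_profile(vals[:, i], spec.levels)
        out[i] = swt_approximations(padded, spec)[:, :p].T
    return out, rec


class SWTTransformer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: samples x genes -> samples x genes x levels tensor.

    Note the input orientation follows sklearn (samples in rows); the output
    is 3-D, intended for :class:`waverisk.cnn.ConvNetClassifier`.
    """

    def __init__(self, wavelet: str = "db3", levels: int = DEFAULT_LEVELS):
        self.wavelet = wavelet
        self.levels = levels

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        validate_wavelet(self.wavelet)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        tensor, self.pad_record_ = decompose_cohort(X.T, WaveletSpec(self.wavelet, self.levels))
        return tensor


def select_wavelet(
    X_train: np.ndarray,
    y_train: np.ndarray,
    candidates=WAVELET_FUNCTIONS,
    levels: int = DEFAULT_LEVELS,
    inner_fraction: float = 0.7,
    random_state: int = 0,
    **cnn_kwargs,
) -> WaveletSpec:
    """Pick the wavelet whose SWT-CNN scores best on an inner validation split.

    One classifier per candidate is trained on ``inner_fraction`` of the
    training samples and scored by AUC on the remainder; ties are broken by
    candidate order. With a single candidate no models are trained.
    """
    candidates = list(candidates)
    for c in candidates:
        validate_wavelet(c)
    if len(candidates) == 1:
        return WaveletSpec(candidates[0], levels)

    from .cnn import ConvNetClassifier
    from .metrics import auc

    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    rng = np.random.default_rng(random_state)
    n = X_train.shape[0]
    n_inner = int(np.floor(inner_fraction * n))
    for _ in range(100):
        perm = rng.permutation(n)
        tr, va = perm[:n_inner], perm[n_inner:]
        if len(set(y_train[tr])) == 2 and len(set(y_train[va])) == 2:
            break
    else:
        raise RuntimeError("could not draw an inner split with both classes")

    best = None
    for name in candidates:
        tensor, _ = decompose_cohort(X_train.T, WaveletSpec(name, levels))
        clf = ConvNetClassifier(random_state=random_state, **cnn_kwargs)
        clf.fit(tensor[tr], y_train[tr])
        score = auc(y_train[va], clf.predict_proba(tensor[va])[:, 1])
        if best is None or score > best[0]:
            best = (score, name)
    return WaveletSpec(best[1], levels)
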