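"""Wavelet subband-entropy features and the feed-forward classifier.

Each of the four retained CSP components is decomposed with a level-3
Daubechies-3 DWT into subbands (A3, D3, D2, D1); the feature is the Shannon
entropy of the subband's normalized squared-coefficient distribution,

    p_i = w_i^2 / sum_j w_j^2,    H = -sum_i p_i ln p_i,

a 16-dimensional vector per trial (4 components x 4 subbands, natural log,
0 ln 0 := 0).  Entropy is low when a subband's energy concentrates in a few
coefficients (tonal, rhythmic activity) and approaches ln(n) for spread
(noise-like) energy, and is invariant to component sign and scale.

Classification uses a two-layer feed-forward network: one hidden layer of
logistic units and a softmax output trained on cross-entropy loss
(scikit-learn's MLPClassifier stands behind this surface).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.neural_network import MLPClassifier

from .wavelet import dwt_forward

__all__ = [
    "SUBBAND_ORDER",
    "subband_entropy_features",
    "feature_matrix",
    "ClassifierModel",
    "train_classifier",
    "predict",
]

log = logging.getLogger(__name__)

SUBBAND_ORDER = ("a3", "d3", "d2", "d1")
FEATURE_WAVELET = "db3"
FEATURE_LEVELS = 3


def _entropy(coeffs: np.ndarray, kind: str = "shannon") -> float:
    e = coeffs**2
    total = e.sum()
    if total <= 0:
        log.debug("all-zero subband: entropy set to 0 by convention")
        return 0.0
    p = e / total
    if kind == "shannon":
        nz = p[p > 0]
        return float(-(nz * np.log(nz)).sum())
    if kind == "log_energy":
        nz = e[e > 0]
        return float(np.sum(np.log(nz)))
    raise ValueError(f"unknown entropy kind {kind!r}")


def subband_entropy_features(
    X_retained: np.ndarray, kind: str = "shannon"
) -> np.ndarray:
    """16 subband entropies of a (4, P) spatially projected trial.

    Ordering: component-major, subband-minor —
    [c0:A3, c0:D3, c0:D2, c0:D1, c1:A3, ...].
    """
    X = np.atleast_2d(np.asarray(X_retained, dtype=float))
    if X.shape[1] < 16:
        raise ValueError("need at least 16 samples for a level-3 decomposition")
    feats = []
    for row in X:
        stack = dwt_forward(row, FEATURE_LEVELS, FEATURE_WAVELET)
        for name in SUBBAND_ORDER:
            feats.append(_entropy(stack.subband(name)[0], kind))
    return np.array(feats)


def feature_matrix(trials, bank, kind: str = "shannon") -> np.ndarray:
    """Stack per-trial features after spatial projection: (n_trials, 16)."""
    from .spatial_filter import project_and_retain

    return np.stack(
        [subband_entropy_features(project_and_retain(t.data, bank), kind) for t in trials]
    )


@dataclass
class ClassifierModel:
    """Trained two-layer network plus its training provenance."""

    network: MLPClassifier
    seed: int
    hidden: int
    zscore: bool
    feature_mean: np.ndarray | None = None
    feature_sd: np.ndarray | None = None

    def _prepare(self, F: np.ndarray) -> np.ndarray:
        F = np.atleast_2d(np.asarray(F, dtype=float))
        if F.shape[1] != self.network.n_features_in_:
            raise ValueError(
                f"feature dim {F.shape[1]} != {self.network.n_features_in_}"
            )
        if self.zscore:
            F = (F - self.feature_mean) / self.feature_sd
        return F

    def predict_proba(self, F: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(self._prepare(F))


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    hidden: int = 10,
    zscore: bool = False,
    max_iter: int = 500,
) -> ClassifierModel:
    """Train the two-layer feed-forward network (deterministic given seed).

    Logistic hidden units, softmax output, cross-entropy loss, L-BFGS
    optimization with a 1e-6 loss-plateau stop, at most ``max_iter`` epochs.
    Optional z-scoring uses training-set statistics only.
    """
    F = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need examples from at least two classes")
    if counts.min() < 2:
        raise ValueError("need at least 2 examples per class")
    mean = sd = None
    if zscore:
        mean = F.mean(axis=0)
        sd = F.std(axis=0)
        sd[sd == 0] = 1.0
        F = (F - mean) / sd
    net = MLPClassifier(
        hidden_layer_sizes=(hidden,),
        activation="logistic",
        solver="lbfgs",
        max_iter=max_iter,
        tol=1e-6,
        random_state=seed,
    )
    net.fit(F, y)
    return ClassifierModel(net, seed, hidden, zscore, mean, sd)


def predict(model: ClassifierModel, features: np.ndarray):
    """Predicted labels and class probabilities; ties break toward class 1.

    Returns (labels, probabilities) for a batch, or (label, proba_row) for a
    single feature vector.
    """
    single = np.asarray(features).ndim == 1
    proba = model.predict_proba(features)
    classes = model.network.classes_
    # np.argmax returns the first maximum: ties go to the lower class label
    labels = classes[np.argmax(proba, axis=1)]
    if single:
        return int(labels[0]), proba[0]
    return labels.astype(int), proba
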