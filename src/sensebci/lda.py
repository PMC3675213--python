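"""Fisher linear discriminant analysis on log-variance features.

Closed-form two-class LDA with pooled within-class covariance and equal
priors (the paradigm is class-balanced by design): w = S_p^{-1} (mu2 -
mu1), b = -w . (mu1 + mu2) / 2. A positive decision score predicts the
second class, negative the first; an exact zero ties to the first class
label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import CLASS_LABELS

_REG_SCALE = 1e-8
_COND_MAX = 1e12


@dataclass
class LDAModel:
    weights: np.ndarray
    bias: float
    class_labels: tuple[str, str]
    class_means: np.ndarray  # (2, n_features)
    pooled_covariance: np.ndarray

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]


def fit_lda(features: np.ndarray, labels: np.ndarray,
            class_labels: tuple[str, str] = CLASS_LABELS) -> LDAModel:
    """Fit the two-class discriminant.

    ``features`` is (n_trials x n_features); both classes must be
    present. The pooled covariance uses the unbiased pooled estimator
    (denominator n - 2) and receives a small diagonal ridge only when
    ill-conditioned.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n_trials x n_features) matching labels")
    masks = [y == c for c in class_labels]
    counts = [int(m.sum()) for m in masks]
    if min(counts) == 0:
        missing = class_labels[counts.index(0)]
        raise ValueError(f"class {missing!r} has no training trials")
    n, d = X.shape
    mus = np.stack([X[m].mean(axis=0) for m in masks])
    scatter = np.zeros((d, d))
    for m, mu in zip(masks, mus):
        R = X[m] - mu
        scatter += R.T @ R
    dof = max(n - 2, 1)
    Sp = scatter / dof
    Sp = 0.5 * (Sp + Sp.T)

    lam = np.linalg.eigvalsh(Sp)
    if lam[0] <= 0 or lam[-1] / max(lam[0], np.finfo(float).tiny) > _COND_MAX:
        Sp = Sp + _REG_SCALE * max(np.mean(np.diag(Sp)), np.finfo(float).tiny) * np.eye(d)
        lam = np.linalg.eigvalsh(Sp)
        if lam[0] <= 0:
            raise np.linalg.LinAlgError(
                "pooled within-class covariance is singular after regularization"
            )
    w = np.linalg.solve(Sp, mus[1] - mus[0])
    b = -float(w @ (mus[0] + mus[1]) / 2.0)
    return LDAModel(weights=w, bias=b, class_labels=tuple(class_labels),
                    class_means=mus, pooled_covariance=Sp)


def decision_scores(model: LDAModel, features: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"features have {X.shape[1]} dimensions, model expects {model.n_features}"
        )
    return X @ model.weights + model.bias


def predict(model: LDAModel, features: np.ndarray):
    """Hard labels and signed scores; score <= 0 predicts the first class."""
    scores = decision_scores(model, features)
    labels = np.where(scores > 0, model.class_labels[1], model.class_labels[0])
    return labels, scores
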