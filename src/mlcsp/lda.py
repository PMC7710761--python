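"""Gaussian linear discriminant analysis with a shared covariance.

All decoders in the package classify CSP log-variance features with this
model: class-conditional Gaussians with per-class means and one pooled
covariance, so decision surfaces are linear.  Prediction picks the class of
maximum posterior, i.e. minimum expected 0-1 cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["LDAModel", "fit_lda", "lda_scores", "predict_lda"]


@dataclass
class LDAModel:
    class_labels: np.ndarray
    means: np.ndarray  # (K, d)
    pooled_covariance: np.ndarray  # (d, d)
    priors: np.ndarray  # (K,)
    ridge: float

    def __post_init__(self) -> None:
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")
        # Cholesky factor cached for scoring
        self._chol = linalg.cho_factor(self.pooled_covariance, lower=True)

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)


def fit_lda(
    X: np.ndarray,
    y: np.ndarray,
    priors: np.ndarray | None = None,
    ridge: float = 1e-6,
) -> LDAModel:
    """Fit means, pooled within-class covariance and priors.

    The pooled covariance is the within-class scatter divided by ``n - K``,
    with a small ridge ``ridge * trace / d`` added for numerical stability
    (CSP features can be nearly collinear when classes separate sharply).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be (n, d) with d >= 1")
    classes = np.unique(y)
    n, d = X.shape
    if n < len(classes) + 1:
        raise ValueError("need at least n_classes + 1 samples")
    means = np.empty((len(classes), d))
    scatter = np.zeros((d, d))
    counts = np.empty(len(classes))
    for k, c in enumerate(classes):
        Xc = X[y == c]
        if len(Xc) < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
        means[k] = Xc.mean(axis=0)
        centered = Xc - means[k]
        scatter += centered.T @ centered
        counts[k] = len(Xc)
    pooled = scatter / (n - len(classes))
    pooled += ridge * np.trace(pooled) / d * np.eye(d)
    if priors is None:
        priors = counts / n
    priors = np.asarray(priors, dtype=float)
    return LDAModel(
        class_labels=classes, means=means, pooled_covariance=pooled,
        priors=priors, ridge=ridge,
    )


def lda_scores(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Posterior probabilities, rows summing to 1.

    Accepts a single feature vector or an (n, d) matrix; the constant and
    the shared quadratic term cancel in the normalization, leaving the
    linear discriminants inside a softmax.
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.means.shape[1]:
        raise ValueError("feature dimension mismatch")
    # log posterior up to a shared constant: x' S^-1 mu - mu' S^-1 mu / 2 + log prior
    solve = lambda B: linalg.cho_solve(model._chol, B)
    Sm = solve(model.means.T)  # (d, K)
    logp = X @ Sm - 0.5 * np.einsum("kd,dk->k", model.means, Sm)[None, :]
    logp += np.log(model.priors)[None, :]
    logp -= logp.max(axis=1, keepdims=True)
    post = np.exp(logp)
    post /= post.sum(axis=1, keepdims=True)
    return post[0] if single else post


def predict_lda(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Class labels of maximum posterior."""
    post = np.atleast_2d(lda_scores(model, X))
    return model.class_labels[post.argmax(axis=1)]
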