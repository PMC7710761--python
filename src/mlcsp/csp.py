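"""Common Spatial Patterns by generalized eigendecomposition.

Given the trace-normalized mean covariance matrices of two classes, CSP
finds spatial filters w solving ``sigma1 w = lambda sigma2 w``.  Filters are
sorted by descending eigenvalue; the first filters maximize class-1 variance
relative to class 2 and the last do the opposite, so the ``m`` first and
``m`` last filters carry the discriminative band power.  Features are the
log of the trace-normalized projected variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "CovariancePair",
    "CSPModel",
    "normalized_covariance",
    "mean_class_covariance",
    "trial_covariances",
    "fit_csp",
    "select_filters",
    "apply_filters",
    "csp_features",
    "features_from_covariances",
    "patterns",
]

#: ridge added to the denominator covariance before the decomposition;
#: common-average-referenced data is rank deficient by one.
RIDGE = 1e-8


@dataclass
class CovariancePair:
    """Trace-normalized mean covariances of the two classes."""

    sigma1: np.ndarray
    sigma2: np.ndarray
    n1: int
    n2: int

    def __post_init__(self) -> None:
        for name in ("sigma1", "sigma2"):
            s = np.asarray(getattr(self, name), dtype=float)
            if s.ndim != 2 or s.shape[0] != s.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(s, s.T, atol=1e-9 * max(1.0, np.abs(s).max())):
                raise ValueError(f"{name} is not symmetric")
            setattr(self, name, s)
        if self.sigma1.shape != self.sigma2.shape:
            raise ValueError("covariance dimension mismatch")


@dataclass
class CSPModel:
    """Fitted CSP decomposition.

    ``W`` holds one spatial filter per column (as many as channels), ordered
    by descending generalized eigenvalue and scaled so that
    ``w' (sigma1 + sigma2) w = 1``.  ``A`` is the stored inverse of ``W``
    (``W @ A`` is the identity); row ``j`` of ``A`` is the scalp pattern
    paired with filter ``j``.
    """

    W: np.ndarray
    eigenvalues: np.ndarray
    m: int
    A: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]

    @property
    def selected_indices(self) -> np.ndarray:
        c = self.n_channels
        return np.concatenate([np.arange(self.m), np.arange(c - self.m, c)])

    @property
    def W_sel(self) -> np.ndarray:
        return self.W[:, self.selected_indices]

    def pattern(self, j: int) -> np.ndarray:
        """Scalp projection of the component extracted by filter ``j``."""
        return self.A[j, :]


def normalized_covariance(trial: np.ndarray) -> np.ndarray:
    """``E E' / trace(E E')`` for one trial ``E`` of shape (channels, samples)."""
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2 or trial.shape[1] < 2:
        raise ValueError("trial must be (channels, samples) with at least 2 samples")
    cov = trial @ trial.T
    tr = np.trace(cov)
    if tr <= 0:
        raise ValueError("degenerate trial: zero total power")
    return cov / tr


def trial_covariances(data: np.ndarray) -> np.ndarray:
    """Per-trial trace-normalized covariances for a (trials, C, T) tensor."""
    data = np.asarray(data, dtype=float)
    covs = data @ data.transpose(0, 2, 1)
    traces = np.einsum("nii->n", covs)
    if np.any(traces <= 0):
        raise ValueError("degenerate trial: zero total power")
    return covs / traces[:, None, None]


def mean_class_covariance(trials) -> np.ndarray:
    """Arithmetic mean of the per-trial normalized covariances."""
    trials = list(trials)
    if not trials:
        raise ValueError("at least one trial required")
    return np.mean([normalized_covariance(t) for t in trials], axis=0)


def _condition(sigma: np.ndarray) -> np.ndarray:
    """Symmetrize and ridge-regularize before the decomposition."""
    sigma = 0.5 * (sigma + sigma.T)
    c = sigma.shape[0]
    return sigma + RIDGE * np.trace(sigma) / c * np.eye(c)


def fit_csp(cov: CovariancePair, m: int | None = None) -> CSPModel:
    """Solve ``sigma1 W = Lambda sigma2 W`` and package the filters.

    Eigenvalues come out sorted descending; each filter's sign is fixed so
    its largest-magnitude coefficient is positive (signs are arbitrary, a
    convention keeps results reproducible).  ``m`` defaults to 3 filter
    pairs, capped at half the channel count.
    """
    sigma1 = _condition(cov.sigma1)
    sigma2 = _condition(cov.sigma2)
    eigvals, eigvecs = linalg.eigh(sigma1, sigma2)
    order = np.argsort(eigvals, kind="stable")[::-1]
    eigvals = eigvals[order]
    W = eigvecs[:, order]
    # eigh normalizes w' sigma2 w = 1; rescale to w' (sigma1+sigma2) w = 1
    W = W / np.sqrt(1.0 + eigvals)[None, :]
    flip = np.sign(W[np.abs(W).argmax(axis=0), np.arange(W.shape[1])])
    flip[flip == 0] = 1.0
    W = W * flip[None, :]
    if m is None:
        m = min(3, W.shape[1] // 2)
    if 2 * m > W.shape[1]:
        raise ValueError(f"2m = {2 * m} filters requested but only {W.shape[1]} channels")
    A = np.linalg.inv(W)
    return CSPModel(W=W, eigenvalues=eigvals, m=m, A=A)


def select_filters(model: CSPModel, m: int | None = None) -> np.ndarray:
    """The first m and last m filter columns (extreme eigenvalues)."""
    m = model.m if m is None else m
    c = model.n_channels
    if 2 * m > c:
        raise ValueError(f"2m = {2 * m} exceeds the number of channels {c}")
    return model.W[:, np.concatenate([np.arange(m), np.arange(c - m, c)])]


def apply_filters(W_sel: np.ndarray, trial: np.ndarray) -> np.ndarray:
    """Project a (channels, samples) trial: ``Y = W_sel' E``."""
    if W_sel.shape[0] != trial.shape[0]:
        raise ValueError("filter/channel dimension mismatch")
    return W_sel.T @ trial


def csp_features(W_sel: np.ndarray, trial: np.ndarray) -> np.ndarray:
    """Log of the normalized projected variances of one trial.

    ``v = log(diag(W' E E' W) / trace(W' E E' W))``; entries are negative
    and ``sum(exp(v)) == 1`` by construction.
    """
    return features_from_covariances(W_sel, normalized_covariance(trial)[None])[0]


def features_from_covariances(W_sel: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Vectorized feature computation from (n, C, C) trial covariances.

    The trace normalization of the input covariances cancels in the feature
    ratio, so normalized and raw ``E E'`` give identical results.
    """
    proj = np.einsum("ik,nij,jk->nk", W_sel, covs, W_sel)
    total = proj.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("degenerate trial: zero projected power")
    # common-average-referenced data has one exactly null spatial direction;
    # a filter along it projects to zero power, so floor before the log
    proj = np.maximum(proj, 1e-12 * total)
    return np.log(proj / total)


def patterns(model: CSPModel) -> np.ndarray:
    """The stored inverse of the filter matrix (``W @ patterns == I``)."""
    return model.A
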