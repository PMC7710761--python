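"""Classic multiclass CSP extensions: pair-wise voting and one-vs-all.

Both decompose the 8-class problem into binary CSP+LDA classifiers on
6-dimensional feature vectors (3 filter pairs).  PW trains one member per
unordered class pair (28 members for 8 classes) and predicts by majority
vote; OVA trains one member per class against all others (8 members) and
predicts by the largest positive-class confidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .core import ALL_LABELS, EpochSet, TaskLabel
from .csp import (
    CovariancePair,
    CSPModel,
    features_from_covariances,
    fit_csp,
    select_filters,
    trial_covariances,
)
from .lda import LDAModel, fit_lda, lda_scores

__all__ = [
    "BinaryCSPClassifier",
    "EnsembleDecoder",
    "n_binary_problems",
    "fit_pw",
    "predict_pw",
    "fit_ova",
    "predict_ova",
]


@dataclass
class BinaryCSPClassifier:
    positive_labels: frozenset[TaskLabel]
    negative_labels: frozenset[TaskLabel]
    csp: CSPModel
    m: int
    lda: LDAModel
    n_train: int

    @property
    def W_sel(self) -> np.ndarray:
        return select_filters(self.csp, self.m)


@dataclass
class EnsembleDecoder:
    scheme: str  # "pw" | "ova"
    members: list[BinaryCSPClassifier]
    n_classes: int = 8


def n_binary_problems(K: int, scheme: str) -> int:
    """Number of binary classifiers: K(K-1)/2 for PW, K for OVA."""
    if K < 2:
        raise ValueError("need at least 2 classes")
    if scheme == "pw":
        return K * (K - 1) // 2
    if scheme == "ova":
        return K
    raise ValueError(f"unknown scheme {scheme!r}")


def _require_all_classes(y: np.ndarray) -> None:
    missing = sorted(set(range(8)) - set(np.unique(y)))
    if missing:
        names = ", ".join(ALL_LABELS[i].name for i in missing)
        raise ValueError(f"missing classes in the training set: {names}")


def _class_mean_covs(covs: np.ndarray, y: np.ndarray) -> dict[int, np.ndarray]:
    return {int(c): covs[y == c].mean(axis=0) for c in np.unique(y)}


def fit_pw(train: EpochSet, m: int = 3, covs: np.ndarray | None = None) -> EnsembleDecoder:
    """One CSP+LDA member per unordered class pair, trained on that pair only."""
    y = train.class_indices
    _require_all_classes(y)
    if covs is None:
        covs = trial_covariances(train.data)
    class_covs = _class_mean_covs(covs, y)
    members = []
    for a, b in combinations(range(8), 2):
        mask = (y == a) | (y == b)
        pair = CovariancePair(
            sigma1=class_covs[a], sigma2=class_covs[b],
            n1=int((y == a).sum()), n2=int((y == b).sum()),
        )
        model = fit_csp(pair, m=m)
        X = features_from_covariances(select_filters(model, m), covs[mask])
        lda = fit_lda(X, y[mask])
        members.append(
            BinaryCSPClassifier(
                positive_labels=frozenset({ALL_LABELS[a]}),
                negative_labels=frozenset({ALL_LABELS[b]}),
                csp=model, m=m, lda=lda, n_train=int(mask.sum()),
            )
        )
    return EnsembleDecoder("pw", members)


def predict_pw(
    decoder: EnsembleDecoder, epochs: EpochSet, covs: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Majority vote over the 28 members.

    Returns predicted class indices and the (n, 8) vote-count matrix.  Ties
    are broken deterministically by the summed LDA posterior each tied class
    collected across the members that involve it.
    """
    if decoder.scheme != "pw":
        raise ValueError("decoder was not fitted with the pair-wise scheme")
    if covs is None:
        covs = trial_covariances(epochs.data)
    n = covs.shape[0]
    votes = np.zeros((n, decoder.n_classes))
    posterior_sum = np.zeros((n, decoder.n_classes))
    for member in decoder.members:
        X = features_from_covariances(member.W_sel, covs)
        post = np.atleast_2d(lda_scores(member.lda, X))
        pred = member.lda.class_labels[post.argmax(axis=1)]
        for col, c in enumerate(member.lda.class_labels):
            votes[pred == c, c] += 1
            posterior_sum[:, c] += post[:, col]
    best = votes.max(axis=1, keepdims=True)
    tie_break = np.where(votes == best, posterior_sum, -np.inf)
    labels = tie_break.argmax(axis=1)
    return labels, votes


def fit_ova(train: EpochSet, m: int = 3, covs: np.ndarray | None = None) -> EnsembleDecoder:
    """One CSP+LDA member per class against the union of all others.

    Priors are left empirical (1/8 vs 7/8): each member sees far more
    negatives than positives and the posterior should reflect that.
    """
    y = train.class_indices
    _require_all_classes(y)
    if covs is None:
        covs = trial_covariances(train.data)
    members = []
    for c in range(8):
        mask_pos = y == c
        pair = CovariancePair(
            sigma1=covs[mask_pos].mean(axis=0),
            sigma2=covs[~mask_pos].mean(axis=0),
            n1=int(mask_pos.sum()), n2=int((~mask_pos).sum()),
        )
        model = fit_csp(pair, m=m)
        X = features_from_covariances(select_filters(model, m), covs)
        lda = fit_lda(X, mask_pos.astype(int))  # 1 = positive class
        members.append(
            BinaryCSPClassifier(
                positive_labels=frozenset({ALL_LABELS[c]}),
                negative_labels=frozenset(set(ALL_LABELS) - {ALL_LABELS[c]}),
                csp=model, m=m, lda=lda, n_train=len(y),
            )
        )
    return EnsembleDecoder("ova", members)


def predict_ova(
    decoder: EnsembleDecoder, epochs: EpochSet, covs: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Argmax of the per-member positive-class posteriors.

    Returns predicted class indices and the (n, 8) confidence matrix.
    """
    if decoder.scheme != "ova":
        raise ValueError("decoder was not fitted with the one-vs-all scheme")
    if covs is None:
        covs = trial_covariances(epochs.data)
    n = covs.shape[0]
    conf = np.empty((n, decoder.n_classes))
    for c, member in enumerate(decoder.members):
        X = features_from_covariances(member.W_sel, covs)
        post = np.atleast_2d(lda_scores(member.lda, X))
        pos_col = int(np.flatnonzero(member.lda.class_labels == 1)[0])
        conf[:, c] = post[:, pos_col]
    return conf.argmax(axis=1), conf
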