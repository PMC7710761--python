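"""Multilabel CSP decoders for the 8-class combined-MI problem.

Both methods replace the 8-class problem with three binary CSP problems,
one per body part, and feed the concatenated 18-dimensional feature vectors
(3 modules x 3 filter pairs x 2) to a single 8-class LDA.

MC2CMI groups, per body part, the four classes engaging it against the four
that do not, and trains on all 8 classes.  MC2SMI trains each module only on
that part's single MI versus rest — no combined-MI calibration data — and
synthesizes training vectors for every class by superposition: each module's
feature block is drawn from a single-MI trial if the class engages that part
and from a rest trial otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    ALL_LABELS,
    REST,
    SINGLE_MI_LABELS,
    BodyPart,
    EpochSet,
    TaskLabel,
    engages,
)
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
    "BinaryProblem",
    "MultilabelDecoder",
    "mc2cmi_problems",
    "mc2smi_problems",
    "fit_mc2cmi",
    "fit_mc2smi",
    "transform",
    "predict",
]


@dataclass(frozen=True)
class BinaryProblem:
    """A per-body-part two-class grouping of task labels."""

    part: BodyPart
    class1_labels: frozenset[TaskLabel]
    class2_labels: frozenset[TaskLabel]

    def __post_init__(self) -> None:
        if self.class1_labels & self.class2_labels:
            raise ValueError("class groupings must be disjoint")


def mc2cmi_problems() -> tuple[BinaryProblem, ...]:
    """Engaged-vs-not groupings over all 8 classes, one per body part."""
    problems = []
    for part in BodyPart:
        class1 = frozenset(lab for lab in ALL_LABELS if engages(lab, part))
        class2 = frozenset(lab for lab in ALL_LABELS if not engages(lab, part))
        problems.append(BinaryProblem(part, class1, class2))
    return tuple(problems)


def mc2smi_problems() -> tuple[BinaryProblem, ...]:
    """Single-MI-vs-rest groupings, one per body part."""
    return tuple(
        BinaryProblem(part, frozenset({SINGLE_MI_LABELS[part]}), frozenset({REST}))
        for part in BodyPart
    )


@dataclass
class MultilabelDecoder:
    """Three per-body-part CSP modules plus one 8-class LDA."""

    method: str  # "mc2cmi" | "mc2smi"
    problems: tuple[BinaryProblem, ...]
    models: tuple[CSPModel, ...]  # canonical body-part order
    m: int
    lda: LDAModel

    @property
    def n_features(self) -> int:
        return len(self.models) * 2 * self.m

    @property
    def filters(self) -> tuple[np.ndarray, ...]:
        return tuple(select_filters(mod, self.m) for mod in self.models)


def _class_indices(epochs: EpochSet) -> np.ndarray:
    return epochs.class_indices


def _mean_cov(covs: np.ndarray, mask: np.ndarray) -> np.ndarray:
    if not mask.any():
        raise ValueError("no trials available for one of the class groupings")
    return covs[mask].mean(axis=0)


def _fit_modules(
    problems: tuple[BinaryProblem, ...],
    covs: np.ndarray,
    y: np.ndarray,
    m: int,
) -> tuple[CSPModel, ...]:
    models = []
    for problem in problems:
        idx1 = {lab.class_index for lab in problem.class1_labels}
        idx2 = {lab.class_index for lab in problem.class2_labels}
        mask1 = np.isin(y, list(idx1))
        mask2 = np.isin(y, list(idx2))
        pair = CovariancePair(
            sigma1=_mean_cov(covs, mask1),
            sigma2=_mean_cov(covs, mask2),
            n1=int(mask1.sum()),
            n2=int(mask2.sum()),
        )
        models.append(fit_csp(pair, m=m))
    return tuple(models)


def _features(models: tuple[CSPModel, ...], m: int, covs: np.ndarray) -> np.ndarray:
    blocks = [features_from_covariances(select_filters(mod, m), covs) for mod in models]
    return np.concatenate(blocks, axis=1)


def _require_classes(y: np.ndarray, required: set[int], context: str) -> None:
    missing = sorted(required - set(np.unique(y)))
    if missing:
        names = ", ".join(ALL_LABELS[i].name for i in missing)
        raise ValueError(f"{context} requires trials of classes: {names}")


def fit_mc2cmi(train: EpochSet, m: int = 3, covs: np.ndarray | None = None) -> MultilabelDecoder:
    """Fit the combined-MI multilabel decoder on a fully labelled session."""
    y = _class_indices(train)
    _require_classes(y, set(range(8)), "MC2CMI")
    if covs is None:
        covs = trial_covariances(train.data)
    problems = mc2cmi_problems()
    models = _fit_modules(problems, covs, y, m)
    X = _features(models, m, covs)
    lda = fit_lda(X, y)
    return MultilabelDecoder("mc2cmi", problems, models, m, lda)


def fit_mc2smi(
    train: EpochSet,
    m: int = 3,
    synth_per_class: int | None = None,
    seed: int = 0,
    covs: np.ndarray | None = None,
) -> MultilabelDecoder:
    """Fit the single-MI multilabel decoder.

    Only rest and single-MI trials are used (combined-MI trials in ``train``
    are ignored).  The 8-class LDA is trained on synthesized vectors: for a
    class ``y``, module ``p``'s 6-dim block is taken from a randomly drawn
    single-MI trial of part ``p`` if ``y`` engages ``p``, else from a rest
    trial.  Donors are drawn without replacement until exhausted, then the
    pool is reshuffled.
    """
    y = _class_indices(train)
    required = {0} | {SINGLE_MI_LABELS[p].class_index for p in BodyPart}
    _require_classes(y, required, "MC2SMI")
    if covs is None:
        covs = trial_covariances(train.data)
    if synth_per_class is None:
        synth_per_class = int(np.bincount(y, minlength=8)[sorted(required)].min())
    problems = mc2smi_problems()
    models = _fit_modules(problems, covs, y, m)

    # per-module feature blocks of the donor trials
    donor_feats = {
        part: features_from_covariances(select_filters(models[part.value], m), covs)
        for part in BodyPart
    }
    pools = {c: np.flatnonzero(y == c) for c in required}
    rng = np.random.default_rng(seed)

    queues = {c: list(rng.permutation(pool)) for c, pool in pools.items()}

    def draw(c: int) -> int:
        if not queues[c]:
            queues[c] = list(rng.permutation(pools[c]))
        return queues[c].pop()

    X = np.empty((8 * synth_per_class, 6 * m))
    y_synth = np.repeat(np.arange(8), synth_per_class)
    row = 0
    for cls in range(8):
        label = ALL_LABELS[cls]
        for _ in range(synth_per_class):
            blocks = []
            for part in BodyPart:
                donor_class = (
                    SINGLE_MI_LABELS[part].class_index if engages(label, part) else 0
                )
                blocks.append(donor_feats[part][draw(donor_class)])
            X[row] = np.concatenate(blocks)
            row += 1
    lda = fit_lda(X, y_synth)
    return MultilabelDecoder("mc2smi", problems, models, m, lda)


def transform(
    decoder: MultilabelDecoder, epochs: EpochSet, covs: np.ndarray | None = None
) -> np.ndarray:
    """Module-major concatenated CSP features, one 18-dim row per trial."""
    if covs is None:
        covs = trial_covariances(epochs.data)
    if covs.shape[1] != decoder.models[0].n_channels:
        raise ValueError("channel count does not match the fitted decoder")
    return _features(decoder.models, decoder.m, covs)


def predict(
    decoder: MultilabelDecoder, epochs: EpochSet, covs: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted class indices and the (n, 8) LDA posterior matrix."""
    X = transform(decoder, epochs, covs)
    scores = np.atleast_2d(lda_scores(decoder.lda, X))
    labels = decoder.lda.class_labels[scores.argmax(axis=1)]
    return labels, scores
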