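"""Cross-validated comparison of the four decoders.

A session is split by a seeded stratified 10-fold plan (4 test trials per
class per fold); every method is fitted from scratch inside each fold on the
training trials only and scored on the held-out trials.  The report collects
per-fold accuracies, one-vs-rest ROC/AUC from the pooled test scores,
pairwise Wilcoxon rank-sum p-values and the binomial chance level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .baselines import fit_ova, fit_pw, predict_ova, predict_pw
from .core import EpochSet
from .csp import trial_covariances
from .multilabel import fit_mc2cmi, fit_mc2smi, predict as predict_ml

__all__ = [
    "FoldPlan",
    "EvaluationReport",
    "stratified_folds",
    "accuracy",
    "roc_ovr",
    "wilcoxon_rank_sum",
    "chance_level",
    "compare_methods",
    "run_benchmark",
    "METHODS",
]


@dataclass(frozen=True)
class FoldPlan:
    """Seeded stratified partition: test fold f holds per_class_test trials of every class."""

    n_folds: int
    per_class_test: int
    assignments: np.ndarray  # per-trial fold index
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def stratified_folds(
    labels: np.ndarray, n_folds: int = 10, per_class_test: int = 4, seed: int = 0
) -> FoldPlan:
    """Randomly assign, without replacement, per_class_test trials of each class to each fold."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    assignments = np.full(len(labels), -1, dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) != n_folds * per_class_test:
            raise ValueError(
                f"class {c} has {len(idx)} trials; need exactly "
                f"{n_folds} x {per_class_test}"
            )
        shuffled = rng.permutation(idx)
        for f in range(n_folds):
            assignments[shuffled[f * per_class_test : (f + 1) * per_class_test]] = f
    return FoldPlan(n_folds, per_class_test, assignments, seed)


def accuracy(predicted: np.ndarray, true: np.ndarray) -> float:
    """Percent agreement."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if len(predicted) == 0 or len(predicted) != len(true):
        raise ValueError("predictions and labels must be nonempty and equal length")
    return 100.0 * float(np.mean(predicted == true))


def roc_ovr(
    scores: np.ndarray, true: np.ndarray, n_classes: int = 8
) -> tuple[list[tuple[np.ndarray, np.ndarray]], np.ndarray]:
    """One-vs-rest ROC curve and AUC per class.

    AUC is the probability that a positive trial outranks a negative one
    (ties counted half), i.e. the normalized Mann-Whitney U statistic.
    """
    scores = np.asarray(scores, dtype=float)
    true = np.asarray(true)
    curves = []
    aucs = np.empty(n_classes)
    for c in range(n_classes):
        pos = (true == c).astype(int)
        if pos.sum() == 0 or pos.sum() == len(pos):
            raise ValueError(f"class {c} absent from the true labels")
        fpr, tpr, _ = roc_curve(pos, scores[:, c])
        curves.append((fpr, tpr))
        aucs[c] = roc_auc_score(pos, scores[:, c])
    return curves, aucs


def wilcoxon_rank_sum(sample_a, sample_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution when the combined sample is small (<= 20) and
    tie-free; normal approximation with tie correction otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def chance_level(n_classes: int = 8, n_trials: int = 40, alpha: float = 0.05) -> float:
    """Binomial significance threshold on accuracy, in percent.

    The smallest correct-trial count k whose binomial(n_trials, 1/n_classes)
    CDF reaches 1 - alpha, expressed as 100 * k / n_trials: accuracies above
    this cannot be explained by guessing at level alpha.
    """
    if n_trials < 1 or n_classes < 2 or not 0 < alpha < 1:
        raise ValueError("invalid chance-level parameters")
    k = int(stats.binom.ppf(1.0 - alpha, n_trials, 1.0 / n_classes))
    return 100.0 * k / n_trials


def _fit_and_predict(method, train, test, covs_train, covs_test, m, seed):
    if method == "mc2cmi":
        dec = fit_mc2cmi(train, m=m, covs=covs_train)
        return predict_ml(dec, test, covs=covs_test)
    if method == "mc2smi":
        dec = fit_mc2smi(train, m=m, seed=seed, covs=covs_train)
        return predict_ml(dec, test, covs=covs_test)
    if method == "pw":
        dec = fit_pw(train, m=m, covs=covs_train)
        return predict_pw(dec, test, covs=covs_test)
    if method == "ova":
        dec = fit_ova(train, m=m, covs=covs_train)
        return predict_ova(dec, test, covs=covs_test)
    raise ValueError(f"unknown method {method!r}")


METHODS = ("mc2cmi", "mc2smi", "pw", "ova")


@dataclass
class EvaluationReport:
    methods: tuple[str, ...]
    fold_accuracies: dict[str, np.ndarray]
    auc: dict[str, np.ndarray]  # per-class, one-vs-rest
    roc: dict[str, list]
    pairwise_p: dict[tuple[str, str], float]
    chance_level: float
    n_folds: int
    seed: int
    confusion_inputs: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False
    )

    def mean_accuracy(self, method: str) -> float:
        return float(self.fold_accuracies[method].mean())

    def sem_accuracy(self, method: str) -> float:
        acc = self.fold_accuracies[method]
        return float(acc.std(ddof=1) / np.sqrt(len(acc)))

    def macro_auc(self, method: str) -> float:
        return float(self.auc[method].mean())

    def to_dict(self) -> dict:
        return {
            "chance_level_percent": self.chance_level,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "methods": {
                m: {
                    "fold_accuracies_percent": self.fold_accuracies[m].tolist(),
                    "mean_accuracy_percent": self.mean_accuracy(m),
                    "sem_accuracy_percent": self.sem_accuracy(m),
                    "per_class_auc": self.auc[m].tolist(),
                    "macro_auc": self.macro_auc(m),
                }
                for m in self.methods
            },
            "pairwise_wilcoxon_p": {
                f"{a} vs {b}": p for (a, b), p in self.pairwise_p.items()
            },
        }

    def save(self, directory: str | Path) -> None:
        """Write report.json plus tidy accuracy / p-value / AUC tables."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        acc_rows = [
            {"method": m, "fold": f, "accuracy_percent": v}
            for m in self.methods
            for f, v in enumerate(self.fold_accuracies[m])
        ]
        pd.DataFrame(acc_rows).to_csv(directory / "accuracy.csv", index=False)
        p_rows = [
            {"method_a": a, "method_b": b, "p_value": p}
            for (a, b), p in self.pairwise_p.items()
        ]
        pd.DataFrame(p_rows).to_csv(directory / "pvalues.csv", index=False)
        auc_rows = [
            {"method": m, "class_index": c, "auc": v}
            for m in self.methods
            for c, v in enumerate(self.auc[m])
        ]
        pd.DataFrame(auc_rows).to_csv(directory / "auc.csv", index=False)


def compare_methods(
    session: EpochSet,
    methods: tuple[str, ...] = METHODS,
    folds: FoldPlan | None = None,
    m: int = 3,
) -> EvaluationReport:
    """Run the full cross-validated comparison on a preprocessed session.

    The same fold plan and the same band-passed data are shared by all
    methods; per-fold models never see the held-out trials.
    """
    y = session.class_indices
    if folds is None:
        folds = stratified_folds(y)
    covs = trial_covariances(session.data)

    fold_acc = {meth: np.empty(folds.n_folds) for meth in methods}
    pooled_scores = {meth: np.empty((len(y), 8)) for meth in methods}
    pooled_pred = {meth: np.empty(len(y), dtype=int) for meth in methods}
    for f in range(folds.n_folds):
        tr = folds.train_indices(f)
        te = folds.test_indices(f)
        train, test = session.subset(tr), session.subset(te)
        for meth in methods:
            try:
                pred, scores = _fit_and_predict(
                    meth, train, test, covs[tr], covs[te], m, seed=folds.seed + f
                )
            except Exception as exc:  # re-raise with fold context
                raise RuntimeError(f"method {meth!r} failed on fold {f}") from exc
            fold_acc[meth][f] = accuracy(pred, y[te])
            pooled_scores[meth][te] = scores
            pooled_pred[meth][te] = pred

    auc = {}
    roc = {}
    for meth in methods:
        curves, aucs = roc_ovr(pooled_scores[meth], y)
        roc[meth] = curves
        auc[meth] = aucs
    pairwise = {
        (a, b): wilcoxon_rank_sum(fold_acc[a], fold_acc[b])
        for a, b in combinations(methods, 2)
    }
    n_per_class = int(np.bincount(y).max())
    return EvaluationReport(
        methods=tuple(methods),
        fold_accuracies=fold_acc,
        auc=auc,
        roc=roc,
        pairwise_p=pairwise,
        chance_level=chance_level(8, n_per_class),
        n_folds=folds.n_folds,
        seed=folds.seed,
        confusion_inputs={meth: (y.copy(), pooled_pred[meth]) for meth in methods},
    )


def run_benchmark(
    seeds,
    methods: tuple[str, ...] = METHODS,
    trials_per_class: int = 40,
    n_folds: int = 10,
    per_class_test: int = 4,
) -> list[EvaluationReport]:
    """Simulate, preprocess and cross-validate one session per seed.

    This is the package's default decoding benchmark: default simulator
    settings, 8-30 Hz band-pass on the continuous recording, common average
    reference, 0.5-3.5 s analysis window, shared stratified folds.
    """
    from .core import ParadigmSpec
    from .pipeline import preprocessed_session
    from .simulate import SimulationConfig

    reports = []
    for seed in seeds:
        paradigm = ParadigmSpec(trials_per_class=trials_per_class)
        config = SimulationConfig(paradigm=paradigm, seed=int(seed))
        session = preprocessed_session(config)
        folds = stratified_folds(
            session.class_indices, n_folds, per_class_test, seed=int(seed)
        )
        reports.append(compare_methods(session, methods, folds))
    return reports
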