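"""Repeated random holdout validation of the phase classifiers.

The protocol mirrors the study's validation: split the per-segment feature
table uniformly at random into a training part (default 40 rows) and a
validation part (the remainder; 43 when the table has 83 rows), fit
everything — tertile boundaries, structure, CPTs — on the training rows
only, score accuracy on the validation rows, and repeat many times (default
1000) to obtain the accuracy distribution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone

logger = logging.getLogger(__name__)


def accuracy(predicted, true) -> float:
    """Fraction of matching labels."""
    predicted = np.asarray(predicted, dtype=object)
    true = np.asarray(true, dtype=object)
    if predicted.shape != true.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape} predictions vs {true.shape} labels"
        )
    if predicted.size == 0:
        raise ValueError("empty label vectors")
    return float(np.mean(predicted == true))


@dataclass
class EvaluationReport:
    """Per-repetition holdout accuracies plus the summary statistics."""

    accuracies: np.ndarray
    n_train: int
    n_test: int
    n_reps: int
    classifier: str
    seed: int
    confusion: dict = field(default_factory=dict)  # true -> {pred: count}

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if len(self.accuracies) != self.n_reps:
            raise ValueError("accuracy count does not match n_reps")
        if np.any((self.accuracies < 0) | (self.accuracies > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def min(self) -> float:
        return float(self.accuracies.min())

    @property
    def max(self) -> float:
        return float(self.accuracies.max())

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "seed": self.seed,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "n_reps": self.n_reps,
            "mean_accuracy": self.mean,
            "min_accuracy": self.min,
            "max_accuracy": self.max,
            "confusion": self.confusion,
            "accuracies": self.accuracies.tolist(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    def histogram(self, n_bins: int = 20, width: int = 50) -> str:
        """Textual histogram of the accuracy distribution."""
        counts, edges = np.histogram(self.accuracies, bins=n_bins, range=(0.0, 1.0))
        peak = counts.max() if counts.max() else 1
        lines = []
        for c, lo, hi in zip(counts, edges[:-1], edges[1:]):
            bar = "#" * int(round(width * c / peak))
            lines.append(f"{lo:4.2f}-{hi:4.2f} | {bar} {c}")
        return "\n".join(lines)


def _draw_split(
    n: int, n_train: int, labels: np.ndarray, seed: int, rep: int, max_retries: int
):
    """Uniform train/test split containing every label in the training part.

    A draw whose training rows miss an entire phase label is retried with a
    fresh derived seed, up to ``max_retries``.
    """
    all_labels = set(labels)
    for retry in range(max_retries + 1):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep, retry]))
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        if set(labels[train]) == all_labels:
            if retry:
                logger.info(
                    "holdout rep %d: %d retried draw(s) for full label coverage",
                    rep,
                    retry,
                )
            return train, test
    raise RuntimeError(
        f"could not draw a training split covering all labels in {max_retries} retries"
    )


def repeated_holdout(
    X,
    y,
    estimator,
    n_train: int = 40,
    n_reps: int = 1000,
    seed: int = 0,
    max_retries: int = 100,
    classifier_name: str | None = None,
) -> EvaluationReport:
    """Repeated random holdout of one estimator (or sklearn pipeline).

    The estimator is cloned and refit per repetition, so anything it learns —
    discretization boundaries, network structure, CPTs — is derived from the
    training rows only.
    """
    X = pd.DataFrame(X).reset_index(drop=True)
    y = np.asarray(y, dtype=object)
    n = len(X)
    if not 0 < n_train < n:
        raise ValueError(f"n_train must be in (0, {n}), got {n_train}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    accs = np.empty(n_reps)
    confusion: dict = {}
    for rep in range(n_reps):
        train, test = _draw_split(n, n_train, y, seed, rep, max_retries)
        est = clone(estimator)
        est.fit(X.iloc[train], y[train])
        pred = np.asarray(est.predict(X.iloc[test]), dtype=object)
        accs[rep] = accuracy(pred, y[test])
        for t, p in zip(y[test], pred):
            confusion.setdefault(str(t), {}).setdefault(str(p), 0)
            confusion[str(t)][str(p)] += 1
    return EvaluationReport(
        accuracies=accs,
        n_train=n_train,
        n_test=n - n_train,
        n_reps=n_reps,
        classifier=classifier_name or type(_final_step(estimator)).__name__,
        seed=seed,
        confusion=confusion,
    )


def _final_step(estimator):
    return estimator.steps[-1][1] if hasattr(estimator, "steps") else estimator


def compare_classifiers(
    X,
    y,
    estimators: dict,
    n_train: int = 40,
    n_reps: int = 1000,
    seed: int = 0,
    max_retries: int = 100,
) -> dict:
    """Run the same split sequence through several classifiers.

    Returns ``{"reports": {name: EvaluationReport}, "mean_difference":
    {(a, b): mean paired accuracy difference}}``.  Because every classifier
    sees the identical splits (same seed), per-repetition accuracies are
    paired.
    """
    if len(estimators) < 2:
        raise ValueError("need at least two classifier specs to compare")
    reports = {
        name: repeated_holdout(
            X,
            y,
            est,
            n_train=n_train,
            n_reps=n_reps,
            seed=seed,
            max_retries=max_retries,
            classifier_name=name,
        )
        for name, est in estimators.items()
    }
    names = list(reports)
    diffs = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            diffs[(a, b)] = float(
                np.mean(reports[a].accuracies - reports[b].accuracies)
            )
    return {"reports": reports, "mean_difference": diffs}
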