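"""Classifier adapters and the model grid.

Four classification techniques are supported — multinomial naive Bayes (nb),
L2-regularized logistic regression (lr), linear-kernel support vector machine
(svm), and random forest (rf) — each behind a uniform fit-and-score surface
that returns one relevance score per pool record, higher meaning more likely
relevant.  Probability-capable backends return class-1 probabilities; the SVM
returns its signed decision value, which is all a ranking needs.

Multinomial naive Bayes requires a non-negative feature matrix, so the
nb + d2v grid cell is infeasible: the full grid of 4 classifiers x 2 feature
extractors yields 7 usable models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import MultinomialNB
from sklearn.svm import SVC

from .balance import DRParams
from .features import FeatureMatrix

__all__ = [
    "ClassifierKind",
    "FeatureKind",
    "ClassifierSpec",
    "ModelConfig",
    "CompatibilityError",
    "FitError",
    "CLASSIFIER_KINDS",
    "FEATURE_KINDS",
    "check_compatibility",
    "enumerate_model_grid",
    "make_estimator",
    "fit_and_score",
]

ClassifierKind = Literal["nb", "lr", "svm", "rf"]
FeatureKind = Literal["tfidf", "d2v"]

CLASSIFIER_KINDS: tuple[str, ...] = ("nb", "lr", "svm", "rf")
FEATURE_KINDS: tuple[str, ...] = ("tfidf", "d2v")


class CompatibilityError(Exception):
    """The classifier cannot consume the given feature matrix."""


class FitError(Exception):
    """The training data cannot support a fit (e.g., one class only)."""


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; expected one of {CLASSIFIER_KINDS}")


@dataclass(frozen=True)
class ModelConfig:
    """One cell of the model grid plus simulation-level knobs."""

    classifier: ClassifierSpec
    feature_kind: str
    feature_params: Mapping[str, object] = field(default_factory=dict)
    balance: DRParams = DRParams()
    n_trials: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        if (self.classifier.kind, self.feature_kind) == ("nb", "d2v"):
            raise ValueError(
                "infeasible model: nb + d2v (multinomial naive Bayes needs non-negative features)"
            )


def check_compatibility(classifier_kind: str, feature_matrix: FeatureMatrix) -> bool:
    """False iff a multinomial-NB classifier meets a signed feature matrix."""
    return not (classifier_kind == "nb" and not feature_matrix.nonnegative)


def enumerate_model_grid(
    classifier_kinds: Iterable[str] = CLASSIFIER_KINDS,
    feature_kinds: Iterable[str] = FEATURE_KINDS,
) -> list[tuple[str, str]]:
    """Feasible (classifier, feature) pairs, classifier-major lexicographic."""
    return [
        (c, f)
        for c in sorted(set(classifier_kinds))
        for f in sorted(set(feature_kinds))
        if (c, f) != ("nb", "d2v")
    ]


def make_estimator(spec: ClassifierSpec):
    """Fresh scikit-learn estimator for a spec; seeded where it matters."""
    hp = dict(spec.hyperparameters)
    if spec.kind == "nb":
        return MultinomialNB(alpha=hp.pop("alpha", 1.0), **hp)
    if spec.kind == "lr":
        return LogisticRegression(
            C=hp.pop("C", 1.0), max_iter=hp.pop("max_iter", 1000), solver=hp.pop("solver", "lbfgs"), **hp
        )
    if spec.kind == "svm":
        return SVC(kernel=hp.pop("kernel", "linear"), C=hp.pop("C", 1.0), random_state=spec.seed, **hp)
    if spec.kind == "rf":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 100), random_state=spec.seed, **hp
        )
    raise ValueError(spec.kind)  # unreachable; guarded in __post_init__


def fit_and_score(
    spec: ClassifierSpec,
    features: FeatureMatrix,
    train_multiset: Sequence[int],
    train_labels: Sequence[int],
    pool: Sequence[int],
) -> np.ndarray:
    """Fit on the (rebalanced) training rows; return a score per pool index.

    Higher scores mean more likely relevant.  Deterministic given identical
    inputs and seed.
    """
    if not check_compatibility(spec.kind, features):
        raise CompatibilityError(
            f"classifier {spec.kind!r} is incompatible with {features.kind!r} features "
            "(signed feature matrix)"
        )
    y = np.asarray(train_labels, dtype=int)
    if np.unique(y).size < 2:
        raise FitError("training multiset must contain both classes")
    est = make_estimator(spec)
    X_train = features.rows(train_multiset)
    X_pool = features.rows(pool)
    est.fit(X_train, y)
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X_pool)[:, list(est.classes_).index(1)]
    return est.decision_function(X_pool)
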