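"""Classic AdaBoost over a pluggable base learner.

Serves two roles: a reference ensemble baseline, and the oracle the
imbalance-aware ensemble must reduce to on single-label (q = 1) problems.

Round arithmetic (weights already normalised to sum 1, so no extra 1/n):

* weighted error     ``eps = sum_j w_j * 1[pred_j != y_j]``
* round coefficient  ``sigma = 1/2 ln((1-eps)/eps)`` (plus ``ln(K-1)`` in the
  SAMME multi-class variant used when K > 2)
* weight update      correct samples x exp(-sigma), wrong x exp(+sigma),
  then renormalise to sum 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .elm import ELM, ordered_classes

__all__ = [
    "weighted_error",
    "round_coefficient",
    "update_sample_weights",
    "AdaBoost",
    "AdaBoostResults",
    "stump_learner",
    "elm_learner",
]

_CLIP = 1e-10


def weighted_error(pred: Sequence, truth: Sequence, weights: Sequence[float]) -> float:
    pred, truth = np.asarray(pred), np.asarray(truth)
    w = np.asarray(weights, dtype=float)
    if not (len(pred) == len(truth) == len(w)):
        raise ValueError("pred, truth and weights must have equal length")
    return float(np.sum(w * (pred != truth)))


def round_coefficient(error: float, n_classes: int = 2) -> float:
    """Importance weight of one round; the error is clipped away from {0, 1}."""
    eps = min(max(float(error), _CLIP), 1.0 - _CLIP)
    if n_classes > 2:  # SAMME multi-class coefficient
        return float(np.log((1.0 - eps) / eps) + np.log(n_classes - 1.0))
    return float(0.5 * np.log((1.0 - eps) / eps))


def update_sample_weights(
    weights: Sequence[float], coefficient: float, pred: Sequence, truth: Sequence
) -> np.ndarray:
    """Reweight: mistakes gain exp(+coef), correct lose exp(-coef); sums to 1."""
    w = np.asarray(weights, dtype=float)
    wrong = np.asarray(pred) != np.asarray(truth)
    w = w * np.exp(np.where(wrong, coefficient, -coefficient))
    return w / w.sum()


# -- base learners ----------------------------------------------------------

def stump_learner(seed: int):
    """Depth-1 decision tree (the textbook weak learner)."""
    from sklearn.tree import DecisionTreeClassifier

    return DecisionTreeClassifier(max_depth=1, random_state=seed)


def elm_learner(n_hidden: int = 100, penalty: float = 1.0, weighting: str | None = None):
    """Factory of ELM base learners with per-round seeds."""

    class _ElmBase:
        def __init__(self, seed: int):
            self.seed = seed

        def fit(self, X, y, sample_weight=None):
            model = ELM(X, y, n_hidden=n_hidden, penalty=penalty,
                        weighting=weighting, seed=self.seed)
            self.res_ = model.fit(sample_weight)
            return self

        def predict(self, X):
            return self.res_.predict(X)

    return _ElmBase


@dataclass
class BoostRound:
    learner: object
    coefficient: float
    error_rate: float


class AdaBoost:
    """AdaBoost model: sequential reweighted fits of a base learner.

    ``base`` is a callable ``base(seed) -> learner`` where the learner
    exposes ``fit(X, y, sample_weight)`` and ``predict(X)``.  Training stops
    early when a round is no better than chance (error >= 1/2 for two
    classes, >= 1 - 1/K under SAMME) or perfectly separates the data.
    """

    def __init__(self, X, y, n_rounds: int = 10,
                 base: Callable[[int], object] = stump_learner, seed: int = 0):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        if n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        self.n_rounds = int(n_rounds)
        self.base = base
        self.seed = int(seed)
        self.classes_ = ordered_classes(self.y)

    def fit(self) -> "AdaBoostResults":
        n, k = len(self.y), len(self.classes_)
        chance = 1.0 - 1.0 / k
        w = np.full(n, 1.0 / n)
        rounds: list[BoostRound] = []
        history = [w.copy()]
        for t in range(self.n_rounds):
            learner = self.base(self.seed + t)
            learner.fit(self.X, self.y, sample_weight=w * n)
            pred = learner.predict(self.X)
            eps = weighted_error(pred, self.y, w)
            if eps >= chance:
                if not rounds:
                    warnings.warn(
                        "base learner no better than chance on round 0; keeping it",
                        stacklevel=2,
                    )
                    rounds.append(BoostRound(learner, round_coefficient(eps, k), eps))
                break
            coef = round_coefficient(eps, k)
            rounds.append(BoostRound(learner, coef, eps))
            if eps <= _CLIP:
                break  # perfect fit; further rounds see degenerate weights
            w = update_sample_weights(w, coef, pred, self.y)
            history.append(w.copy())
        return AdaBoostResults(self, rounds, history)


class AdaBoostResults:
    def __init__(self, model: AdaBoost, rounds: list[BoostRound], weight_history):
        self.model = model
        self.rounds = rounds
        self.weight_history = weight_history

    @property
    def classes_(self) -> np.ndarray:
        return self.model.classes_

    def decision_function(self, X) -> np.ndarray:
        """Coefficient-weighted vote tally, n x K."""
        X = np.asarray(X, dtype=float)
        score = np.zeros((len(X), len(self.classes_)))
        for rnd in self.rounds:
            pred = rnd.learner.predict(X)
            for j, c in enumerate(self.classes_):
                score[:, j] += rnd.coefficient * (pred == c)
        return score

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def summary(self) -> str:
        lines = [
            "AdaBoost results",
            "================",
            f"rounds fitted: {len(self.rounds)} of {self.model.n_rounds} requested",
        ]
        for t, rnd in enumerate(self.rounds):
            lines.append(
                f"  round {t}: error={rnd.error_rate:.4f}  coefficient={rnd.coefficient:+.4f}"
            )
        acc = float(np.mean(self.predict(self.model.X) == self.model.y))
        lines.append(f"training accuracy: {acc:.4f}")
        return "\n".join(lines)
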