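"""Imbalance-aware boosted label-weighted ELM (IELM).

The ensemble marries AdaBoost with the label-weighted ELM.  The single-label
c-class task is one-hot binarised into q = c labels, each with a positive
(class members) and a negative (everyone else) side.  The sample-weight
distribution is an n x q matrix ``W`` organised in 2q blocks - one (label,
side) pair each - and every block is held at total mass 1/(2q), so the grand
total is always 1 and each label's positive and negative sides carry equal
cost no matter how few positives there are.

Per boosting round t:

1. one random hidden layer (seed + t) is shared by all labels;
2. each label's output column is a ridge solve with that label's current
   weight column on the diagonal (normalised to mean 1 so the penalty keeps
   its unweighted meaning) and label-weighted targets: positives get the
   original-class ratio ``N_major / N_class``, negatives -1;
3. per-(label, side) coefficients ``sigma_lj = 1/2 ln(correct mass / wrong
   mass)`` and the global round coefficient ``sigma_t`` (same form over all
   mass) are computed, log arguments clipped at 1e-10;
4. weights advance within each block - correct x exp(-sigma_lj), wrong x
   exp(+sigma_lj) - and the block is renormalised to 1/(2q).

Prediction: ``score_l(x) = sum_t sigma_t * sign(H_t(x) beta_l)``; the class is
the argmax over labels, exact ties resolving to the lowest class index.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .elm import (
    ELM,
    HiddenLayer,
    build_hidden_layer,
    ordered_classes,
    solve_output_weights,
)

__all__ = [
    "imbalance_ratio",
    "initial_weight_distribution",
    "label_class_error",
    "label_class_coefficient",
    "update_weight_distribution",
    "ensemble_coefficient",
    "IELM",
    "IELMResults",
]

_CLIP = 1e-10


def _check_label_matrix(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y)
    if Y.ndim != 2:
        raise ValueError("label matrix must be n x q")
    if not np.isin(Y, (0, 1)).all():
        raise ValueError("label matrix entries must be binary")
    return Y.astype(int)


def imbalance_ratio(Y: np.ndarray, j: int) -> float:
    """Majority/minority count ratio for label ``j`` (>= 1; 1 means balanced)."""
    Y = _check_label_matrix(Y)
    pos = int(Y[:, j].sum())
    neg = len(Y) - pos
    if pos == 0 or neg == 0:
        raise ValueError(f"label {j}: one side has no samples (pos={pos}, neg={neg})")
    return max(pos, neg) / min(pos, neg)


def initial_weight_distribution(Y: np.ndarray, use_sqrt: bool = True) -> np.ndarray:
    """Initial n x q weight distribution.

    The minority side of each label starts from raw weight sqrt(R_j) (or R_j
    when ``use_sqrt`` is off) against 1 for the majority side, then every
    (label, side) block is normalised to total mass 1/(2q).  Note the block
    normalisation means the raw factor only matters if the two sides were
    pooled; it is kept for fidelity to the construction and for the
    ``use_sqrt`` toggle.
    """
    Y = _check_label_matrix(Y)
    n, q = Y.shape
    W = np.zeros((n, q), dtype=float)
    for j in range(q):
        R = imbalance_ratio(Y, j)
        raw_minor = np.sqrt(R) if use_sqrt else R
        pos = Y[:, j] == 1
        npos = int(pos.sum())
        minority_is_pos = npos <= n - npos
        W[pos, j] = raw_minor if minority_is_pos else 1.0
        W[~pos, j] = 1.0 if minority_is_pos else raw_minor
        for block in (pos, ~pos):
            W[block, j] *= (1.0 / (2 * q)) / W[block, j].sum()
    return W


def _block_mask(Y: np.ndarray, l: int, side: int) -> np.ndarray:
    """Boolean mask of the (label l, side) block; side 1 = positive, 0 = negative."""
    return Y[:, l] == side


def label_class_error(
    correct: np.ndarray, Y: np.ndarray, W: np.ndarray, l: int, side: int
) -> float:
    """Total weight of block samples the base learner got wrong on label ``l``.

    ``correct`` is the n x q boolean matrix of per-label correctness.
    """
    Y = _check_label_matrix(Y)
    blk = _block_mask(Y, l, side)
    if not blk.any():
        raise ValueError(f"label {l}: side {side} block is empty")
    return float(W[blk & ~correct[:, l], l].sum())


def label_class_coefficient(
    correct: np.ndarray, Y: np.ndarray, W: np.ndarray, l: int, side: int
) -> float:
    """1/2 ln(correct block mass / wrong block mass), masses clipped at 1e-10."""
    Y = _check_label_matrix(Y)
    blk = _block_mask(Y, l, side)
    if not blk.any():
        raise ValueError(f"label {l}: side {side} block is empty")
    good = float(W[blk & correct[:, l], l].sum())
    bad = float(W[blk & ~correct[:, l], l].sum())
    return float(0.5 * np.log(max(good, _CLIP) / max(bad, _CLIP)))


def ensemble_coefficient(correct: np.ndarray, W: np.ndarray) -> float:
    """Round coefficient: 1/2 ln(total correct mass / total wrong mass)."""
    good = float((W * correct).sum())
    bad = float((W * ~correct).sum())
    return float(0.5 * np.log(max(good, _CLIP) / max(bad, _CLIP)))


def update_weight_distribution(
    W: np.ndarray, coefficients: np.ndarray, correct: np.ndarray, Y: np.ndarray
) -> np.ndarray:
    """Advance the distribution one round.

    ``coefficients`` is q x 2 (columns: positive side, negative side).  Within
    each block correct samples shrink by exp(-sigma_lj) and mistakes grow by
    exp(+sigma_lj); each block is renormalised to 1/(2q).
    """
    Y = _check_label_matrix(Y)
    n, q = Y.shape
    out = np.array(W, dtype=float, copy=True)
    for l in range(q):
        for side in (1, 0):
            blk = _block_mask(Y, l, side)
            sigma = coefficients[l, 1 - side]
            mult = np.where(correct[blk, l], np.exp(-sigma), np.exp(sigma))
            out[blk, l] *= mult
            out[blk, l] *= (1.0 / (2 * q)) / out[blk, l].sum()
    return out


@dataclass
class IELMRound:
    hidden: HiddenLayer
    beta: np.ndarray  # L x q
    coefficient: float  # global round weight sigma_t
    side_coefficients: np.ndarray  # q x 2 (positive, negative)


class IELM:
    """Imbalance-aware boosted LW-ELM model.

    Parameters
    ----------
    X : array-like, n x d
        Training features, preferably min-max scaled to [0, 1].
    y : sequence
        Single-label class assignments; one-hot binarised internally (q =
        number of classes).
    n_rounds : int
        Boosting rounds T.
    n_hidden, penalty : int, float
        Base-ELM hidden width and ridge penalty.
    scheme : {"ratio", "ratio_squared"}
        Label-weight inflation of positive targets.
    use_sqrt_ratio : bool
        Initialise minority raw weights from sqrt(R) (default) or R.
    seed : int
        Round t uses hidden-layer seed ``seed + t``.
    """

    def __init__(self, X, y, n_rounds: int = 10, n_hidden: int = 100,
                 penalty: float = 1.0, scheme: str = "ratio",
                 use_sqrt_ratio: bool = True, seed: int = 0):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be n x d with one label per row")
        if n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        self.n_rounds = int(n_rounds)
        self.n_hidden = int(n_hidden)
        self.penalty = float(penalty)
        if scheme not in ("ratio", "ratio_squared"):
            raise ValueError(f"unknown scheme {scheme!r}")
        self.scheme = scheme
        self.use_sqrt_ratio = bool(use_sqrt_ratio)
        self.seed = int(seed)
        self.classes_ = ordered_classes(self.y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")

    @classmethod
    def from_dataframe(cls, table, label_col: str = "label", **kwargs) -> "IELM":
        labelled = table.dropna(subset=[label_col])
        X = labelled.drop(columns=[label_col]).to_numpy(dtype=float)
        return cls(X, labelled[label_col].to_numpy(), **kwargs)

    def _one_hot(self) -> np.ndarray:
        Y = np.zeros((len(self.y), len(self.classes_)), dtype=int)
        for j, c in enumerate(self.classes_):
            Y[self.y == c, j] = 1
        return Y

    def _target_columns(self, Y: np.ndarray) -> np.ndarray:
        """n x q targets: positives get the class ratio (scheme), negatives -1."""
        counts = Y.sum(axis=0)
        ratios = counts.max() / counts
        if self.scheme == "ratio_squared":
            ratios = ratios**2
        return np.where(Y == 1, ratios[None, :], -1.0)

    def fit(self) -> "IELMResults":
        n, d = self.X.shape
        Y = self._one_hot()
        q = Y.shape[1]
        T = self._target_columns(Y)
        W = initial_weight_distribution(Y, use_sqrt=self.use_sqrt_ratio)
        history = [W.copy()]
        rounds: list[IELMRound] = []
        for t in range(self.n_rounds):
            hidden = build_hidden_layer(d, self.n_hidden, self.seed + t)
            H = hidden.transform(self.X)
            beta = np.empty((self.n_hidden, q))
            for l in range(q):
                w = W[:, l] * (n / W[:, l].sum())  # mean-1 diagonal costs
                beta[:, l] = solve_output_weights(
                    H, T[:, l][None, :], self.penalty, sample_weight=w
                )[:, 0]
            scores = H @ beta
            correct = (scores > 0) == (Y == 1)
            side_coefs = np.empty((q, 2))
            for l in range(q):
                for k, side in enumerate((1, 0)):
                    side_coefs[l, k] = label_class_coefficient(correct, Y, W, l, side)
            sigma_t = ensemble_coefficient(correct, W)
            rounds.append(IELMRound(hidden, beta, sigma_t, side_coefs))
            if correct.all():
                # every block is perfectly classified (all sigma_lj at their
                # clip ceilings); further rounds would see degenerate weights
                break
            if t + 1 < self.n_rounds:
                W = update_weight_distribution(W, side_coefs, correct, Y)
                history.append(W.copy())
        return IELMResults(self, rounds, history)


class IELMResults:
    """Fitted ensemble: per-round base ELMs, coefficients, weight history."""

    def __init__(self, model: IELM, rounds: list[IELMRound], weight_history):
        self.model = model
        self.rounds = rounds
        self.weight_history = weight_history

    @property
    def classes_(self) -> np.ndarray:
        return self.model.classes_

    def decision_function(self, X) -> np.ndarray:
        """n x q coefficient-weighted sign scores."""
        X = np.asarray(X, dtype=float)
        score = np.zeros((len(X), len(self.classes_)))
        for rnd in self.rounds:
            score += rnd.coefficient * np.sign(rnd.hidden.transform(X) @ rnd.beta)
        return score

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def summary(self) -> str:
        m = self.model
        pred = self.predict(m.X)
        acc = float(np.mean(pred == m.y))
        lines = [
            "IELM ensemble results",
            "=====================",
            f"n obs / features:   {m.X.shape[0]} / {m.X.shape[1]}",
            f"classes (q):        {', '.join(map(str, self.classes_))}",
            f"rounds fitted:      {len(self.rounds)} of {m.n_rounds} requested",
            f"hidden nodes (L):   {m.n_hidden}   penalty: {m.penalty}   seed: {m.seed}",
            f"target scheme:      {m.scheme} (sqrt ratio init: {m.use_sqrt_ratio})",
            f"training accuracy:  {acc:.4f}",
        ]
        for c in self.classes_:
            mask = m.y == c
            lines.append(
                f"  recall[{c}]: {float(np.mean(pred[mask] == c)):.4f}  (n={int(mask.sum())})"
            )
        lines.append("round coefficients:")
        for t, rnd in enumerate(self.rounds):
            lines.append(f"  t={t}: sigma={rnd.coefficient:+.4f}")
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        m = self.model
        return {
            "kind": "ielm",
            "classes": self.classes_.tolist(),
            "n_rounds": m.n_rounds,
            "n_hidden": m.n_hidden,
            "penalty": m.penalty,
            "scheme": m.scheme,
            "use_sqrt_ratio": m.use_sqrt_ratio,
            "seed": m.seed,
            "rounds": [
                {
                    "seed": r.hidden.seed,
                    "input_weights": r.hidden.input_weights.tolist(),
                    "biases": r.hidden.biases.tolist(),
                    "beta": r.beta.tolist(),
                    "coefficient": r.coefficient,
                    "side_coefficients": r.side_coefficients.tolist(),
                }
                for r in self.rounds
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "IELMResults":
        stub = IELM.__new__(IELM)
        stub.classes_ = np.asarray(d["classes"])
        stub.n_rounds = d["n_rounds"]
        stub.n_hidden = d["n_hidden"]
        stub.penalty = d["penalty"]
        stub.scheme = d["scheme"]
        stub.use_sqrt_ratio = d["use_sqrt_ratio"]
        stub.seed = d["seed"]
        rounds = [
            IELMRound(
                HiddenLayer(np.asarray(r["input_weights"]), np.asarray(r["biases"]),
                            seed=r["seed"]),
                np.asarray(r["beta"]),
                r["coefficient"],
                np.asarray(r["side_coefficients"]),
            )
            for r in d["rounds"]
        ]
        stub.X = np.empty((0, rounds[0].hidden.n_features))
        stub.y = np.empty(0)
        return cls(stub, rounds, [])

    @classmethod
    def load(cls, path: str | Path) -> "IELMResults":
        return cls.from_dict(json.loads(Path(path).read_text()))
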