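"""Extreme learning machines: plain, sample-weighted and label-weighted.

An ELM is a single-hidden-layer network whose hidden weights are random and
frozen; only the output weights ``beta`` are solved, in closed form, from the
ridge-regularised least-squares problem

    beta = (I/gamma + H' D H)^{-1} H' D T'

where ``H`` is the n x L hidden output matrix, ``gamma`` the penalty factor,
``D`` an optional diagonal per-sample cost matrix and ``T`` the m x n target
matrix.  Class imbalance can be addressed either through ``D`` (weighted ELM)
or through the targets: the label-weighted ELM (LW-ELM) raises the positive
target of class ``i`` from 1 to ``N_major / N_i`` (scheme ``"ratio"``) or its
square (``"ratio_squared"``), leaving off-class targets at -1, so the solver
tolerates more training error on minority classes at unchanged cost.

The module follows the Model/Results convention: :class:`ELM` holds data and
configuration, ``fit()`` returns an :class:`ELMResults` carrying the solved
weights, training diagnostics, ``predict`` and ``summary``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HiddenLayer",
    "build_hidden_layer",
    "ordered_classes",
    "label_weighted_targets",
    "solve_output_weights",
    "ELM",
    "ELMResults",
]

_SEVERITY = {"low": 0, "moderate": 1, "high": 2}


def ordered_classes(labels: Sequence) -> np.ndarray:
    """Distinct classes in canonical order.

    Stress labels sort by severity (low < moderate < high); anything else
    sorts naturally.  The argmax tie-break everywhere in the package is
    "lowest class index", so this order is part of the model contract.
    """
    uniq = list(pd.unique(np.asarray(labels)))
    if set(uniq) <= set(_SEVERITY):
        uniq.sort(key=_SEVERITY.__getitem__)
    else:
        uniq.sort()
    return np.asarray(uniq)


@dataclass(frozen=True)
class HiddenLayer:
    """Random frozen hidden layer: x -> sigmoid(x W' + b).

    Weights and biases are drawn uniformly on [-1, 1] from a generator seeded
    with ``seed``, so the layer is reproducible from (d, L, seed) alone.
    """

    input_weights: np.ndarray  # L x d
    biases: np.ndarray  # L
    seed: int
    activation: str = "sigmoid"

    @property
    def n_hidden(self) -> int:
        return len(self.biases)

    @property
    def n_features(self) -> int:
        return self.input_weights.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"X must be 2-D with {self.n_features} columns, got shape {X.shape}"
            )
        z = X @ self.input_weights.T + self.biases
        return 1.0 / (1.0 + np.exp(-z))


def build_hidden_layer(n_features: int, n_hidden: int, seed: int) -> HiddenLayer:
    if n_features < 1 or n_hidden < 1:
        raise ValueError("n_features and n_hidden must be >= 1")
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(n_hidden, n_features))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    return HiddenLayer(W, b, seed)


def label_weighted_targets(
    labels: Sequence, scheme: str = "ratio", classes: Sequence | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Label-weighted m x n target matrix.

    ``T[i, j] = (N_major/N_i)`` (or its square under ``"ratio_squared"``) when
    sample ``j`` belongs to class ``i``, else -1.  With ``scheme=None`` the
    positive entries are plain 1 (standard +/-1 coding).  Returns ``(T, classes)``.
    """
    labels = np.asarray(labels)
    cls = ordered_classes(labels) if classes is None else np.asarray(classes)
    if len(cls) < 2:
        raise ValueError("need at least 2 classes")
    counts = np.array([(labels == c).sum() for c in cls])
    if (counts == 0).any():
        empty = cls[counts == 0]
        raise ValueError(f"class(es) {list(empty)} have no samples")
    if scheme is None:
        pos = np.ones(len(cls))
    elif scheme == "ratio":
        pos = counts.max() / counts
    elif scheme == "ratio_squared":
        pos = (counts.max() / counts) ** 2
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    T = np.full((len(cls), len(labels)), -1.0)
    for i, c in enumerate(cls):
        T[i, labels == c] = pos[i]
    return T, cls


def solve_output_weights(
    H: np.ndarray,
    T: np.ndarray,
    penalty: float = 1.0,
    sample_weight: np.ndarray | None = None,
) -> np.ndarray:
    """Ridge solve for the L x m output weights.

    ``T`` is m x n (one row per output).  ``sample_weight`` is the diagonal of
    the n x n cost matrix; all-ones reduces exactly to the unweighted solve,
    and a zero weight removes a sample from the normal equations.
    """
    H = np.asarray(H, dtype=float)
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if penalty <= 0:
        raise ValueError("penalty must be > 0")
    if T.shape[1] != H.shape[0]:
        raise ValueError(f"T has {T.shape[1]} columns but H has {H.shape[0]} rows")
    L = H.shape[1]
    if sample_weight is None:
        A = np.eye(L) / penalty + H.T @ H
        B = H.T @ T.T
    else:
        w = np.asarray(sample_weight, dtype=float)
        if (w < 0).any():
            raise ValueError("sample weights must be nonnegative")
        if not (w > 0).any():
            raise ValueError("sample weights must not all be zero")
        A = np.eye(L) / penalty + H.T @ (H * w[:, None])
        B = H.T @ (T.T * w[:, None])
    try:
        return np.linalg.solve(A, B)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular ELM system (penalty={penalty}): {exc}")


class ELM:
    """Extreme learning machine classifier model.

    Parameters
    ----------
    X : array-like, n x d
        Training features (scale-sensitive: min-max scale to [0, 1] first).
    y : sequence of length n
        Class labels.
    n_hidden : int
        Hidden layer width L.
    penalty : float
        Ridge penalty factor gamma; large values approach the pseudo-inverse
        (interpolating) solution.
    weighting : {None, "ratio", "ratio_squared"}
        None trains a plain +/-1-target ELM; the other two train the
        label-weighted ELM with the corresponding minority target inflation.
    seed : int
        Seed of the random hidden layer.
    """

    def __init__(self, X, y, n_hidden: int = 100, penalty: float = 1.0,
                 weighting: str | None = None, seed: int = 0):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be n x d with one label per row")
        self.n_hidden = int(n_hidden)
        self.penalty = float(penalty)
        self.weighting = weighting
        self.seed = int(seed)
        self.classes_ = ordered_classes(self.y)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, label_col: str = "label", **kwargs) -> "ELM":
        labelled = table.dropna(subset=[label_col])
        X = labelled.drop(columns=[label_col]).to_numpy(dtype=float)
        return cls(X, labelled[label_col].to_numpy(), **kwargs)

    def fit(self, sample_weight: np.ndarray | None = None) -> "ELMResults":
        hidden = build_hidden_layer(self.X.shape[1], self.n_hidden, self.seed)
        H = hidden.transform(self.X)
        T, _ = label_weighted_targets(self.y, scheme=self.weighting, classes=self.classes_)
        beta = solve_output_weights(H, T, self.penalty, sample_weight)
        return ELMResults(self, hidden, beta)


class ELMResults:
    """Fitted ELM: hidden layer + solved output weights."""

    def __init__(self, model: ELM, hidden: HiddenLayer, beta: np.ndarray):
        self.model = model
        self.hidden = hidden
        self.beta = beta  # L x m

    @property
    def classes_(self) -> np.ndarray:
        return self.model.classes_

    def decision_function(self, X) -> np.ndarray:
        """Raw scores (n x m): one column per class, in class order."""
        return self.hidden.transform(np.asarray(X, dtype=float)) @ self.beta

    def predict(self, X) -> np.ndarray:
        """Argmax decoding; exact ties resolve to the lowest class index."""
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def summary(self) -> str:
        m = self.model
        pred = self.predict(m.X)
        acc = float(np.mean(pred == m.y))
        lines = [
            "ELM classification results",
            "==========================",
            f"scheme:            {'LW-ELM (' + m.weighting + ')' if m.weighting else 'plain ELM'}",
            f"n obs / features:  {m.X.shape[0]} / {m.X.shape[1]}",
            f"hidden nodes (L):  {m.n_hidden}   seed: {m.seed}",
            f"penalty (gamma):   {m.penalty}",
            f"classes:           {', '.join(map(str, self.classes_))}",
            f"training accuracy: {acc:.4f}",
        ]
        for c in self.classes_:
            mask = m.y == c
            lines.append(
                f"  recall[{c}]: {float(np.mean(pred[mask] == c)):.4f}  (n={int(mask.sum())})"
            )
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        m = self.model
        return {
            "kind": "elm",
            "n_hidden": m.n_hidden,
            "penalty": m.penalty,
            "weighting": m.weighting,
            "seed": self.hidden.seed,
            "activation": self.hidden.activation,
            "classes": self.classes_.tolist(),
            "input_weights": self.hidden.input_weights.tolist(),
            "biases": self.hidden.biases.tolist(),
            "beta": self.beta.tolist(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "ELMResults":
        hidden = HiddenLayer(
            np.asarray(d["input_weights"]), np.asarray(d["biases"]),
            seed=d["seed"], activation=d["activation"],
        )
        beta = np.asarray(d["beta"])
        # a stub model carrying the metadata needed for prediction
        stub = ELM.__new__(ELM)
        stub.n_hidden = d["n_hidden"]
        stub.penalty = d["penalty"]
        stub.weighting = d["weighting"]
        stub.seed = d["seed"]
        stub.classes_ = np.asarray(d["classes"])
        stub.X = np.empty((0, hidden.n_features))
        stub.y = np.empty(0)
        return cls(stub, hidden, beta)

    @classmethod
    def load(cls, path: str | Path) -> "ELMResults":
        return cls.from_dict(json.loads(Path(path).read_text()))
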