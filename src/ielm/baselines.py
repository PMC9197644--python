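"""Adapters around established classifiers used as comparison baselines.

These are benchmarks, not contributions: thin wrappers over scikit-learn with
a uniform ``fit(X, y) -> predict(X)`` surface and a seed.
"""

from __future__ import annotations

import numpy as np

from .elm import ELM
from .ensemble import IELM

__all__ = ["make_baseline", "BASELINE_NAMES"]

BASELINE_NAMES = ("svm", "linear_svm", "rf", "elm", "lw_elm", "ielm")


class _SkWrapper:
    def __init__(self, est):
        self.est = est

    def fit(self, X, y):
        self.est.fit(np.asarray(X, dtype=float), np.asarray(y))
        return self

    def predict(self, X):
        return self.est.predict(np.asarray(X, dtype=float))


class _ModelWrapper:
    def __init__(self, factory):
        self.factory = factory

    def fit(self, X, y):
        self.res_ = self.factory(X, y).fit()
        return self

    def predict(self, X):
        return self.res_.predict(X)


def make_baseline(name: str, seed: int = 0, **kwargs):
    """Build a named classifier with a uniform fit/predict surface.

    Names: ``svm`` (RBF), ``linear_svm``, ``rf`` (random forest), ``elm``,
    ``lw_elm`` (label-weighted ELM, ratio scheme) and ``ielm``.  Extra keyword
    arguments reach the underlying constructor.
    """
    if name == "svm":
        from sklearn.svm import SVC

        return _SkWrapper(SVC(kernel="rbf", random_state=seed, **kwargs))
    if name == "linear_svm":
        from sklearn.svm import LinearSVC

        return _SkWrapper(LinearSVC(random_state=seed, **kwargs))
    if name == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return _SkWrapper(RandomForestClassifier(random_state=seed, **kwargs))
    if name == "elm":
        return _ModelWrapper(lambda X, y: ELM(X, y, seed=seed, **kwargs))
    if name == "lw_elm":
        return _ModelWrapper(lambda X, y: ELM(X, y, weighting="ratio", seed=seed, **kwargs))
    if name == "ielm":
        return _ModelWrapper(lambda X, y: IELM(X, y, seed=seed, **kwargs))
    raise ValueError(f"unknown baseline {name!r}; expected one of {BASELINE_NAMES}")
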