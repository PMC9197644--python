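"""Accuracy-driven feature weighting and per-band feature fusion.

Each band gets four weights, one per feature, proportional to the
classification accuracy that feature achieves on its own:

    w_i = f_i / (f_1 + f_2 + f_3 + f_4),   0 <= w_i <= 1,  sum w_i = 1

The weighted combination is used two ways: the scalar band score
``F_band = sum_i w_i * P_i`` and, for classifier input, the element-wise
weighted 20-dimensional vector (the scalar per band would discard most of the
information).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import BAND_NAMES
from .features import FEATURE_NAMES

__all__ = [
    "FeatureWeights",
    "compute_feature_weights",
    "weight_table_from_accuracy_table",
    "combine_band_features",
    "round_half_up",
    "load_reference_accuracy_table",
]

_DATA_DIR = Path(__file__).parent / "data"


def round_half_up(x: float, decimals: int = 4) -> float:
    """Decimal half-up rounding (the convention of printed weight tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FeatureWeights:
    """Normalised per-feature weights for one band."""

    band: str
    weights: tuple[float, ...]  # aligned with FEATURE_NAMES
    source_accuracies: tuple[float, ...]

    def rounded(self, decimals: int = 4) -> tuple[float, ...]:
        return tuple(round_half_up(w, decimals) for w in self.weights)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.weights))


def compute_feature_weights(accuracies: Sequence[float], band: str) -> FeatureWeights:
    """Weights proportional to the four single-feature accuracies of a band."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.shape != (len(FEATURE_NAMES),):
        raise ValueError(f"expected {len(FEATURE_NAMES)} accuracies, got shape {acc.shape}")
    if (acc <= 0).any():
        raise ValueError("accuracies must be positive")
    w = acc / acc.sum()
    return FeatureWeights(band, tuple(float(v) for v in w), tuple(float(v) for v in acc))


def weight_table_from_accuracy_table(acc: pd.DataFrame) -> pd.DataFrame:
    """Column-wise weighting of a 4-feature x 5-band accuracy table.

    Rows must be the four features, columns the five bands (any order drawn
    from the canonical names).  Missing cells raise, naming the offender.
    """
    missing_rows = [f for f in FEATURE_NAMES if f not in acc.index]
    missing_cols = [b for b in BAND_NAMES if b not in acc.columns]
    if missing_rows or missing_cols:
        raise ValueError(
            f"accuracy table incomplete: missing rows {missing_rows}, columns {missing_cols}"
        )
    acc = acc.loc[list(FEATURE_NAMES), list(BAND_NAMES)]
    for band in BAND_NAMES:
        for feat in FEATURE_NAMES:
            if pd.isna(acc.at[feat, band]):
                raise ValueError(f"missing accuracy for ({feat}, {band})")
    out = {}
    for band in BAND_NAMES:
        out[band] = compute_feature_weights(acc[band].to_numpy(), band).weights
    return pd.DataFrame(out, index=list(FEATURE_NAMES))


def combine_band_features(
    values: Mapping[str, float] | pd.Series,
    weights: Mapping[str, FeatureWeights] | pd.DataFrame,
) -> tuple[dict[str, float], dict[str, float]]:
    """Fuse one 20-value feature vector with per-band weights.

    Returns ``(band_scores, weighted_vector)``: the five scalars
    ``F_band = sum_i w_i P_i`` and the 20 element-wise weighted values keyed by
    the original column names.
    """
    if isinstance(weights, pd.DataFrame):
        weights = {
            b: FeatureWeights(b, tuple(weights[b].loc[list(FEATURE_NAMES)]), (np.nan,) * 4)
            for b in weights.columns
        }
    missing = [b for b in BAND_NAMES if b not in weights]
    if missing:
        raise ValueError(f"missing weights for band(s) {missing}")
    band_scores: dict[str, float] = {}
    weighted: dict[str, float] = {}
    for band in BAND_NAMES:
        w = weights[band].as_dict()
        total = 0.0
        for feat in FEATURE_NAMES:
            key = f"{band}_{feat}"
            if key not in values:
                raise ValueError(f"feature vector lacks {key!r}")
            weighted[key] = w[feat] * float(values[key])
            total += weighted[key]
        band_scores[band] = total
    return band_scores, weighted


def apply_fusion(table: pd.DataFrame, weights: pd.DataFrame, mode: str = "weighted") -> pd.DataFrame:
    """Fuse a whole feature table.

    ``mode="weighted"`` keeps 20 element-wise weighted columns (default
    classifier input); ``mode="scalar"`` reduces to the five ``F_band``
    columns.  The label column, when present, is carried through.
    """
    if mode not in ("weighted", "scalar"):
        raise ValueError(f"unknown fusion mode {mode!r}")
    cols = [c for c in table.columns if c != "label"]
    rows = {}
    for idx, row in table[cols].iterrows():
        band_scores, weighted = combine_band_features(row, weights)
        rows[idx] = band_scores if mode == "scalar" else weighted
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = table.index.name
    if "label" in table.columns:
        out["label"] = table["label"]
    return out


def load_reference_accuracy_table() -> pd.DataFrame:
    """Bundled single-feature accuracy table (features x bands).

    Reference per-band classification accuracies of the four features from a
    published stress-classification experiment; the worked fusion example and
    the ``weights`` CLI command run on it.
    """
    df = pd.read_csv(_DATA_DIR / "reference_feature_accuracy.csv", index_col=0)
    return df
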