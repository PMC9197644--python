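"""Nonlinear per-band features and feature-table assembly.

Four features are computed for every rhythm band of a segment:

* ``hurst``       - Hurst exponent by rescaled-range (R/S) analysis with the
  Anis-Lloyd-Peters small-sample correction.  ~0.5 for uncorrelated noise,
  >0.5 for persistent signals.
* ``fluctuation`` - fluctuation (volatility) index: the mean absolute first
  difference ``(1/(N-1)) * sum |x[i+1]-x[i]|``.
* ``sampen``      - sample entropy: ``-ln(A/B)`` where B counts pairs of
  length-``m`` templates within Chebyshev distance ``r*SD`` and A the same for
  length ``m+1``, self-matches excluded.
* ``permen``      - permutation entropy of ordinal patterns, normalised to
  [0, 1] by ``ln(order!)``.

A feature table is a DataFrame with one row per segment, 20 feature columns
named ``<band>_<feature>`` (band-major, feature-minor order) and a ``label``
column.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import gammaln

from .bands import BAND_NAMES, RawSegment, decompose_bands, preprocess

__all__ = [
    "FEATURE_NAMES",
    "feature_columns",
    "hurst_exponent",
    "fluctuation_index",
    "sample_entropy",
    "permutation_entropy",
    "extract_features",
    "extract_feature_table",
    "scale_feature_tables",
]

#: Feature short names, in canonical order (P1..P4).
FEATURE_NAMES: tuple[str, ...] = ("hurst", "fluctuation", "sampen", "permen")


def feature_columns() -> list[str]:
    """The 20 feature-table column names, band-major then feature-minor."""
    return [f"{b}_{f}" for b in BAND_NAMES for f in FEATURE_NAMES]


# ---------------------------------------------------------------------------
# Hurst exponent (corrected R/S)
# ---------------------------------------------------------------------------

def _rs_statistic(x: np.ndarray, window: int) -> float:
    """Mean rescaled range over non-overlapping windows of the given size."""
    nseg = len(x) // window
    xs = x[: nseg * window].reshape(nseg, window)
    xs = xs - xs.mean(axis=1, keepdims=True)
    z = np.cumsum(xs, axis=1)
    rng = z.max(axis=1) - z.min(axis=1)
    sd = xs.std(axis=1)
    ok = sd > 0
    if not ok.any():
        return np.nan
    return float(np.mean(rng[ok] / sd[ok]))


def _expected_rs(window: int) -> float:
    # Anis-Lloyd expectation of R/S for iid Gaussian data, with the
    # Peters finite-sample factor (w - 1/2)/w; gammaln keeps it stable.
    w = window
    front = math.exp(gammaln(0.5 * (w - 1)) - gammaln(0.5 * w)) / math.sqrt(math.pi)
    i = np.arange(1, w)
    return (w - 0.5) / w * front * float(np.sum(np.sqrt((w - i) / i)))


def hurst_exponent(x: Sequence[float], n_windows: int = 12) -> float:
    """Corrected rescaled-range estimate of the Hurst exponent.

    Window sizes are log-spaced between 10 and ``n//2``.  The least-squares
    slope of ``log(R/S)`` against ``log(window)`` is re-centred by the slope
    the Anis-Lloyd-Peters expectation predicts for uncorrelated data, which
    removes the well-known upward small-sample bias of plain R/S:

    ``H = 1/2 + slope(log R/S) - slope(log E[R/S | H=1/2])``
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 100:
        raise ValueError(f"need >= 100 samples for R/S analysis, got {len(x)}")
    if x.std() == 0:
        raise ValueError("zero variance: Hurst exponent undefined for a constant sequence")
    windows = np.unique(
        np.floor(np.logspace(np.log10(10), np.log10(len(x) // 2), n_windows)).astype(int)
    )
    rs = np.array([_rs_statistic(x, w) for w in windows])
    keep = np.isfinite(rs) & (rs > 0)
    windows, rs = windows[keep], rs[keep]
    if len(windows) < 4:
        raise ValueError("too few usable window sizes for R/S regression")
    ers = np.array([_expected_rs(w) for w in windows])
    lw = np.log(windows)
    slope = np.polyfit(lw, np.log(rs), 1)[0]
    null_slope = np.polyfit(lw, np.log(ers), 1)[0]
    return float(0.5 + slope - null_slope)


# ---------------------------------------------------------------------------
# Fluctuation index
# ---------------------------------------------------------------------------

def fluctuation_index(x: Sequence[float]) -> float:
    """Mean absolute first difference of the sequence."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    return float(np.mean(np.abs(np.diff(x))))


# ---------------------------------------------------------------------------
# Sample entropy
# ---------------------------------------------------------------------------

def _template_pairs(x: np.ndarray, length: int, n_templates: int, radius: float) -> int:
    """Unordered pairs of length-``length`` templates within Chebyshev ``radius``."""
    emb = np.lib.stride_tricks.sliding_window_view(x, length)[:n_templates]
    tree = cKDTree(emb)
    counted = tree.count_neighbors(tree, radius, p=np.inf)  # ordered, incl. self
    return (int(counted) - n_templates) // 2


def sample_entropy(x: Sequence[float], m: int = 2, r: float = 0.2) -> float:
    """Sample entropy with tolerance ``r`` expressed as a fraction of the SD.

    Returns 0.0 for a constant sequence (every template matches, by
    convention) and ``inf`` when no (m+1)-template pair matches.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 50:
        raise ValueError(f"need >= 50 samples, got {len(x)}")
    if m < 1:
        raise ValueError("embedding dimension m must be >= 1")
    if r <= 0:
        raise ValueError("tolerance fraction r must be > 0")
    sd = x.std()
    if sd == 0:
        return 0.0
    radius = r * sd
    n_templates = len(x) - m  # same template count at both lengths
    b = _template_pairs(x, m, n_templates, radius)
    a = _template_pairs(x, m + 1, n_templates, radius)
    if a == 0 or b == 0:
        return math.inf
    return float(-math.log(a / b))


# ---------------------------------------------------------------------------
# Permutation entropy
# ---------------------------------------------------------------------------

def permutation_entropy(x: Sequence[float], order: int = 3, delay: int = 1) -> float:
    """Normalised permutation entropy in [0, 1].

    Ordinal patterns of the given order (ties broken by position, as argsort
    does) are counted over all delay-embedded windows; the Shannon entropy of
    their relative frequencies is divided by ``ln(order!)``.
    """
    x = np.asarray(x, dtype=float)
    if not 3 <= order <= 7:
        raise ValueError("order must be in 3..7")
    if delay < 1:
        raise ValueError("delay must be >= 1")
    if len(x) < order * delay + 10:
        raise ValueError(f"sequence too short for order={order}, delay={delay}")
    span = (order - 1) * delay
    idx = np.arange(len(x) - span)[:, None] + np.arange(order)[None, :] * delay
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    # encode each pattern as an integer in factorial-free base `order`
    codes = (patterns * order ** np.arange(order)).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    return h / math.log(math.factorial(order))


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def extract_features(
    seg: RawSegment,
    *,
    sampen_m: int = 2,
    sampen_r: float = 0.2,
    permen_order: int = 3,
    permen_delay: int = 1,
    preprocessed: bool = False,
) -> dict[str, float]:
    """All 20 band-by-feature values for one segment.

    The segment is preprocessed (detrend + clip) and band-decomposed first
    unless ``preprocessed`` says that already happened.
    """
    if not preprocessed:
        seg = preprocess(seg)
    if seg.samples.std() == 0:
        raise ValueError(f"segment {seg.segment_id!r}: zero variance")
    bands = decompose_bands(seg)
    values: dict[str, float] = {}
    for bname in BAND_NAMES:
        bx = bands[bname].samples
        values[f"{bname}_hurst"] = hurst_exponent(bx)
        values[f"{bname}_fluctuation"] = fluctuation_index(bx)
        values[f"{bname}_sampen"] = sample_entropy(bx, m=sampen_m, r=sampen_r)
        values[f"{bname}_permen"] = permutation_entropy(
            bx, order=permen_order, delay=permen_delay
        )
    return values


def extract_feature_table(segments: Iterable[RawSegment], **feature_kwargs) -> pd.DataFrame:
    """Feature table for a collection of segments.

    Segments whose extraction fails (constant signal, too short, non-finite
    feature) are dropped with a warning naming the segment and reason; the
    remaining rows keep the input order.
    """
    rows = {}
    labels = {}
    for seg in segments:
        try:
            vals = extract_features(seg, **feature_kwargs)
        except (ValueError, FloatingPointError) as exc:
            warnings.warn(f"segment {seg.segment_id!r} dropped: {exc}", stacklevel=2)
            continue
        if not all(np.isfinite(v) for v in vals.values()):
            warnings.warn(
                f"segment {seg.segment_id!r} dropped: non-finite feature value", stacklevel=2
            )
            continue
        rows[seg.segment_id] = vals
        labels[seg.segment_id] = seg.label
    table = pd.DataFrame.from_dict(rows, orient="index", columns=feature_columns())
    table.index.name = "segment_id"
    table["label"] = pd.Series(labels, dtype=object)
    return table


def scale_feature_tables(
    train: pd.DataFrame, *others: pd.DataFrame
) -> tuple[pd.DataFrame, ...]:
    """Min-max scale feature columns to [0, 1], fitted on the training table only.

    Other tables (e.g. a test split) are transformed with the training bounds
    and clipped into [0, 1].  The ``label`` column is carried through.
    """
    from sklearn.preprocessing import MinMaxScaler

    cols = [c for c in train.columns if c != "label"]
    scaler = MinMaxScaler().fit(train[cols])

    def apply(df: pd.DataFrame, clip: bool) -> pd.DataFrame:
        out = df.copy()
        scaled = scaler.transform(df[cols])
        if clip:
            scaled = np.clip(scaled, 0.0, 1.0)
        out[cols] = scaled
        return out

    return (apply(train, clip=False), *(apply(df, clip=True) for df in others))
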