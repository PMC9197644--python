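"""Synthetic EEG segments and feature datasets.

No public recording accompanies the stress-classification task this package
implements, so everything downstream is exercised on synthetic data with the
statistical structure the features and classifiers consume:

* three stress classes with the imbalanced mix observed in practice -
  defaults (low, moderate, high) = (0.42, 0.46, 0.12);
* band-limited oscillatory power whose per-band amplitudes depend on class
  (beta/gamma activity grows and alpha shrinks with stress, following the
  usual reading of the rhythm bands);
* a fractional-Gaussian-noise floor whose Hurst exponent depends on class, so
  the long-range-dependence feature is informative.

The generator emulates only this statistical structure - not eye blinks,
spindles, mains hum or any physiology.  Everything is reproducible
bit-exactly from its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import BAND_NAMES, CLASS_LABELS, RawSegment, get_band, bandpass
from .features import feature_columns

__all__ = [
    "SyntheticConfig",
    "fgn",
    "generate_segments",
    "generate_feature_dataset",
    "split_table",
]


def fgn(n: int, hurst: float, seed_or_rng) -> np.ndarray:
    """Fractional Gaussian noise by circulant embedding (exact covariance).

    Unit-variance stationary increments of fractional Brownian motion with
    the given Hurst parameter; H = 0.5 is white noise.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"Hurst parameter must be in (0, 1), got {hurst}")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    k = np.arange(n)
    acov = 0.5 * ((k + 1) ** (2 * hurst) - 2.0 * k ** (2.0 * hurst)
                  + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([acov, acov[-2:0:-1]])  # circulant first row, length 2n-2
    lam = np.clip(np.fft.fft(row).real, 0.0, None)
    m = len(row)
    w = (rng.standard_normal(m) + 1j * rng.standard_normal(m)) / np.sqrt(2.0)
    x = np.sqrt(2.0 / m) * np.real(np.fft.fft(np.sqrt(lam) * w))
    return x[:n]


# Per-class band RMS amplitudes (microvolts).  Stress raises beta/gamma power
# and suppresses alpha; delta/theta stay near baseline.
_DEFAULT_AMPLITUDES: dict[str, dict[str, float]] = {
    "low": {"delta": 8.0, "theta": 6.0, "alpha": 10.0, "beta": 4.0, "gamma": 2.0},
    "moderate": {"delta": 8.0, "theta": 6.5, "alpha": 8.0, "beta": 6.0, "gamma": 3.0},
    "high": {"delta": 7.0, "theta": 7.0, "alpha": 5.0, "beta": 9.0, "gamma": 5.0},
}

# Broadband-noise persistence per class: calmer states drift more slowly.
_DEFAULT_HURST: dict[str, float] = {"low": 0.75, "moderate": 0.65, "high": 0.55}


@dataclass
class SyntheticConfig:
    """Configuration of the segment generator.

    ``class_proportions`` follows the canonical class order (low, moderate,
    high); ``segments_per_subject`` groups consecutive segments under one
    subject id for subject-wise splitting.
    """

    n_segments: int = 120
    class_proportions: tuple[float, float, float] = (0.42, 0.46, 0.12)
    sampling_rate: float = 256.0
    duration_s: float = 10.0
    band_amplitudes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: _DEFAULT_AMPLITUDES
    )
    hurst_by_class: Mapping[str, float] = field(default_factory=lambda: _DEFAULT_HURST)
    noise_sd: float = 2.0
    segments_per_subject: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 10:
            raise ValueError("n_segments must be >= 10")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        for cls in CLASS_LABELS:
            amps = self.band_amplitudes[cls]
            if any(amps[b] < 0 for b in BAND_NAMES):
                raise ValueError(f"negative band amplitude for class {cls!r}")


def _band_noise(n: int, band_name: str, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise."""
    x = bandpass(rng.standard_normal(n), get_band(band_name), fs)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_segments(config: SyntheticConfig) -> list[RawSegment]:
    """Draw labelled synthetic segments per the configuration.

    Each segment is the sum of five class-amplitude band-limited noise
    processes plus ``noise_sd`` x fGn with the class's Hurst target.  Labels
    are drawn i.i.d. from the class proportions.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.sampling_rate))
    labels = rng.choice(CLASS_LABELS, size=config.n_segments, p=config.class_proportions)
    segments = []
    for i, label in enumerate(labels):
        label = str(label)
        amps = config.band_amplitudes[label]
        if all(amps[b] == 0 for b in BAND_NAMES):
            import warnings

            warnings.warn(f"class {label!r} has all-zero band amplitudes", stacklevel=2)
        x = np.zeros(n)
        for bname in BAND_NAMES:
            x = x + amps[bname] * _band_noise(n, bname, config.sampling_rate, rng)
        x = x + config.noise_sd * fgn(n, config.hurst_by_class[label], rng)
        segments.append(
            RawSegment(
                segment_id=f"seg{i:04d}",
                samples=x,
                sampling_rate=config.sampling_rate,
                subject_id=f"subj{i // config.segments_per_subject:03d}",
                label=str(label),
            )
        )
    return segments


def generate_feature_dataset(
    n: int,
    proportions: Sequence[float] = (0.42, 0.46, 0.12),
    separation: float = 1.5,
    seed: int = 0,
    n_features: int = 20,
) -> pd.DataFrame:
    """Direct classifier fixture: Gaussian class clusters in feature space.

    Class means are unit vectors (drawn once from the seed) scaled by
    ``separation``; within-class covariance is the identity.  Columns carry
    the canonical band-by-feature names when ``n_features`` is 20.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((len(CLASS_LABELS), n_features))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    counts = rng.multinomial(n, np.asarray(proportions, dtype=float))
    X, y = [], []
    for c, cnt in enumerate(counts):
        X.append(separation * dirs[c] + rng.standard_normal((cnt, n_features)))
        y.extend([CLASS_LABELS[c]] * cnt)
    X = np.vstack(X)
    y = np.asarray(y, dtype=object)
    order = rng.permutation(n)
    cols = feature_columns() if n_features == 20 else [f"x{i}" for i in range(n_features)]
    table = pd.DataFrame(X[order], columns=cols)
    table.index = [f"seg{i:04d}" for i in range(n)]
    table.index.name = "segment_id"
    table["label"] = y[order]
    return table


def split_table(
    table: pd.DataFrame, test_fraction: float = 0.3, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split of a feature table (70/30 by default)."""
    from sklearn.model_selection import train_test_split

    idx_train, idx_test = train_test_split(
        np.arange(len(table)),
        test_size=test_fraction,
        random_state=seed,
        stratify=table["label"].to_numpy(),
    )
    return table.iloc[np.sort(idx_train)], table.iloc[np.sort(idx_test)]
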