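"""EEG segments and rhythm-band decomposition.

A recording is handled as single-channel labelled segments (:class:`RawSegment`).
Segments are stored as plain delimited text: one sample per line in microvolts,
preceded by a comment header ``# fs=<sampling_rate>``.  Labels live in a separate
two-column table ``segment_id,label`` with labels in ``{low, moderate, high}``.

The five clinical rhythm bands are fixed:

=======  ============
band     range (Hz)
=======  ============
delta    [0.5, 4)
theta    [4, 7]
alpha    [8, 15]
beta     [16, 31]
gamma    [32, 45]
=======  ============

Band decomposition applies the two-pass (forward-backward) response of an
elliptic band-pass (order 8, 0.01 dB passband ripple, 60 dB stopband) in the
frequency domain, which is exactly zero-phase.  Zero phase matters because
ordinal-pattern features downstream are sensitive to phase distortion; the
sharp elliptic edges keep the summed band energies within a few percent of the
broadband [0.5, 45] Hz energy despite the gaps the band table leaves at
7-8, 15-16 and 31-32 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "BANDS",
    "CLASS_LABELS",
    "Band",
    "RawSegment",
    "BandSignal",
    "read_segments",
    "write_segments",
    "read_labels",
    "preprocess",
    "decompose_bands",
]

#: Stress classes in severity order; all class indexing in the package follows it.
CLASS_LABELS: tuple[str, ...] = ("low", "moderate", "high")

#: Minimum sampling rate able to represent the gamma band upper edge (2 x 45 Hz).
MIN_SAMPLING_RATE = 90.0


@dataclass(frozen=True)
class Band:
    """One rhythm band with its passband edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise ValueError(f"band {self.name}: low_hz must be < high_hz")


#: The five rhythm bands, in canonical (frequency-ascending) order.
BANDS: tuple[Band, ...] = (
    Band("delta", 0.5, 4.0),
    Band("theta", 4.0, 7.0),
    Band("alpha", 8.0, 15.0),
    Band("beta", 16.0, 31.0),
    Band("gamma", 32.0, 45.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in BANDS)
_BAND_BY_NAME = {b.name: b for b in BANDS}


def get_band(name: str) -> Band:
    try:
        return _BAND_BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown band {name!r}; expected one of {BAND_NAMES}") from None


@dataclass
class RawSegment:
    """One labelled single-channel EEG segment.

    Parameters
    ----------
    segment_id : str
        Unique identifier (the file stem for on-disk segments).
    samples : ndarray
        Signal in microvolts, one value per time step.
    sampling_rate : float
        Sampling rate in Hz; must cover the gamma band (>= 90 Hz).
    subject_id : str, optional
        Grouping key for subject-wise splits; empty when unknown.
    label : str or None
        Stress class in ``{low, moderate, high}``, or None when unlabelled.
    """

    segment_id: str
    samples: np.ndarray
    sampling_rate: float
    subject_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.sampling_rate < MIN_SAMPLING_RATE:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz < {MIN_SAMPLING_RATE} Hz "
                "cannot represent the gamma band (32-45 Hz)"
            )
        if len(self.samples) < 2 * self.sampling_rate:
            raise ValueError(
                f"segment {self.segment_id!r}: need >= 2 s of signal "
                f"({int(2 * self.sampling_rate)} samples), got {len(self.samples)}"
            )
        if self.label is not None and self.label not in CLASS_LABELS:
            raise ValueError(f"label {self.label!r} not in {CLASS_LABELS}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass
class BandSignal:
    """A segment restricted to one rhythm band (same length as the source)."""

    segment_id: str
    band: Band
    samples: np.ndarray
    sampling_rate: float


def read_labels(label_path: str | Path) -> dict[str, str]:
    """Read a two-column ``segment_id,label`` table (comma or whitespace delimited)."""
    labels: dict[str, str] = {}
    for lineno, line in enumerate(Path(label_path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p for p in line.replace(",", " ").split() if p]
        if len(parts) != 2:
            raise ValueError(f"{label_path}:{lineno}: expected 'segment_id,label', got {line!r}")
        seg_id, label = parts
        if seg_id == "segment_id":  # optional header row
            continue
        if label not in CLASS_LABELS:
            raise ValueError(f"{label_path}:{lineno}: label {label!r} not in {CLASS_LABELS}")
        labels[seg_id] = label
    return labels


def _read_one_segment(path: Path) -> tuple[np.ndarray, float, str]:
    fs = None
    subject = ""
    values: list[float] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("fs="):
                fs = float(body[3:])
            elif body.startswith("subject="):
                subject = body[8:]
            continue
        try:
            values.append(float(line))
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric sample {line!r}") from None
    if fs is None:
        raise ValueError(f"{path}: missing sampling rate header '# fs=<Hz>'")
    if not values:
        raise ValueError(f"{path}: no samples")
    return np.asarray(values), fs, subject


def read_segments(
    path: str | Path, label_path: str | Path | None = None
) -> list[RawSegment]:
    """Read segments from a file or a directory of segment files.

    Labels, when given, are joined by segment id; label rows naming an unknown
    segment are skipped with a warning, and segments without a label row carry
    ``label=None``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    files = sorted(path.glob("*.txt")) if path.is_dir() else [path]
    if not files:
        raise ValueError(f"{path}: no segment files (*.txt)")

    labels = read_labels(label_path) if label_path is not None else {}
    seen_ids = set()
    segments = []
    for f in files:
        samples, fs, subject = _read_one_segment(f)
        seg_id = f.stem
        seen_ids.add(seg_id)
        segments.append(
            RawSegment(seg_id, samples, fs, subject_id=subject, label=labels.get(seg_id))
        )
    for orphan in sorted(set(labels) - seen_ids):
        warnings.warn(f"label for unknown segment {orphan!r} skipped", stacklevel=2)
    return segments


def write_segments(segments: Iterable[RawSegment], directory: str | Path) -> list[Path]:
    """Write segments as one text file each; returns the written paths.

    The format round-trips to full precision (repr-exact floats).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for seg in segments:
        lines = [f"# fs={float(seg.sampling_rate)!r}"]
        if seg.subject_id:
            lines.append(f"# subject={seg.subject_id}")
        lines.extend(repr(float(v)) for v in seg.samples)
        p = directory / f"{seg.segment_id}.txt"
        p.write_text("\n".join(lines) + "\n")
        paths.append(p)
    return paths


def write_label_table(segments: Iterable[RawSegment], path: str | Path) -> Path:
    path = Path(path)
    rows = ["segment_id,label"]
    rows += [f"{s.segment_id},{s.label}" for s in segments if s.label is not None]
    path.write_text("\n".join(rows) + "\n")
    return path


def preprocess(seg: RawSegment, clip_sd: float = 5.0) -> RawSegment:
    """Denoise a segment: remove mean and linear trend, clip extreme excursions.

    Amplitudes beyond ``clip_sd`` standard deviations of the detrended signal
    are clipped to that bound (a cheap artifact guard for spikes).  An
    all-constant signal is returned unchanged with a warning.
    """
    x = seg.samples
    if np.ptp(x) == 0.0:
        warnings.warn(f"segment {seg.segment_id!r}: constant signal left unchanged", stacklevel=2)
        return replace(seg, samples=x.copy())
    y = sps.detrend(x, type="linear")
    sd = y.std()
    y = np.clip(y, -clip_sd * sd, clip_sd * sd)
    return replace(seg, samples=y)


def _band_sos(band: Band, fs: float) -> np.ndarray:
    return sps.ellip(
        8, 0.01, 60.0, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos"
    )


def bandpass(x: np.ndarray, band: Band, fs: float) -> np.ndarray:
    """Zero-phase band-pass of ``x``; output has the same length as the input.

    The two-pass (forward-backward) magnitude response |H(w)|^2 of the
    elliptic design is applied in the frequency domain.  This is the circular
    equivalent of forward-backward filtering but free of the edge transients
    a recursive pass leaves on finite segments - the slow delta-band poles
    would otherwise ring across a substantial part of a 10 s segment and
    distort the band's energy.
    """
    x = np.asarray(x, dtype=float)
    if fs < 2 * band.high_hz:
        raise ValueError(
            f"sampling rate {fs} Hz too low for band {band.name} "
            f"(upper edge {band.high_hz} Hz needs fs >= {2 * band.high_hz} Hz)"
        )
    n = len(x)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    _, H = sps.sosfreqz(_band_sos(band, fs), worN=2.0 * np.pi * freqs / fs)
    return np.fft.irfft(np.fft.rfft(x) * np.abs(H) ** 2, n=n)


def decompose_bands(seg: RawSegment) -> dict[str, BandSignal]:
    """Split a (preprocessed) segment into the five rhythm bands.

    Returns a mapping band name -> :class:`BandSignal`, in canonical band order.
    """
    out: dict[str, BandSignal] = {}
    for band in BANDS:
        out[band.name] = BandSignal(
            segment_id=seg.segment_id,
            band=band,
            samples=bandpass(seg.samples, band, seg.sampling_rate),
            sampling_rate=seg.sampling_rate,
        )
    return out
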