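"""Sliding-window feature extraction.

Each trial's imagery segment is cut into windows of ``window_s`` seconds
displaced by ``slide_s`` seconds.  Per window the features are the alpha/mu
(8-12 Hz) and beta (15-25 Hz) band powers of each electrode (C3, Cz, C4),
optionally followed by an inter-electrode interaction value per pair
(C3-Cz, C4-Cz, C3-C4): either the Pearson correlation or the generalized
(dot-product) Jaccard distance of the raw windowed samples.

The generalized Jaccard index of two real vectors is

    J(A, B) = A.B / (|A|^2 + |B|^2 - A.B),

bounded in [-1/3, 1] (the extremes at B = -A and B = A), and the Jaccard
distance is JD = 1 - J = |A - B|^2 / (|A|^2 + |B|^2 - A.B), in [0, 4/3].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .synth import CHANNELS, Trial

__all__ = [
    "WindowSpec",
    "BandDefinition",
    "FeatureSequence",
    "DEFAULT_BANDS",
    "ELECTRODE_PAIRS",
    "slide_windows",
    "band_power",
    "PowerScaler",
    "pearson",
    "jaccard_index",
    "jaccard_distance",
    "extract_features",
    "flatten_for_static",
    "features_to_frame",
]

# pair order fixed: C3-Cz, C4-Cz, C3-C4 (indices into CHANNELS)
ELECTRODE_PAIRS: tuple[tuple[int, int], ...] = ((0, 1), (2, 1), (0, 2))
INTERACTION_MODES = ("none", "correlation", "jaccard")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in seconds.

    Sample counts are rounded to the nearest whole sample (e.g. a 0.125 s
    slide at 250 Hz becomes 31 samples).
    """

    window_s: float
    slide_s: float

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.slide_s <= 0:
            raise ValueError(
                f"window_s and slide_s must be positive, got {self.window_s}, {self.slide_s}"
            )

    def to_samples(self, fs: float) -> tuple[int, int]:
        k = int(round(self.window_s * fs))
        step = int(round(self.slide_s * fs))
        if k < 2 or step < 1:
            raise ValueError(f"window {self.window_s}s / slide {self.slide_s}s too small at fs={fs}")
        return k, step


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(f"band {self.name}: need 0 < low < high, got [{self.low_hz}, {self.high_hz}]")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 15.0, 25.0),
)


def slide_windows(n_samples: int, window_spec: WindowSpec, fs: float) -> list[tuple[int, int]]:
    """Half-open sample ranges [i, i+k) stepping by the slide; no partial windows."""
    k, step = window_spec.to_samples(fs)
    if k > n_samples:
        raise ValueError(f"window of {k} samples exceeds segment of {n_samples} samples")
    return [(i, i + k) for i in range(0, n_samples - k + 1, step)]


def band_power(segment: np.ndarray, band: BandDefinition, fs: float) -> float:
    """Band-limited power of a single-channel segment.

    Welch periodogram (Hann window, 50% overlap, segment-length-adaptive
    ``nperseg``) integrated over the band, so short 0.5 s windows reduce to
    a single tapered periodogram while long segments get averaging.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1 or segment.size < 2:
        raise ValueError("segment must be a 1-D array of length >= 2")
    if band.high_hz >= fs / 2:
        raise ValueError(f"band {band.name} [{band.low_hz}, {band.high_hz}] exceeds Nyquist {fs / 2}")
    nperseg = min(segment.size, int(2 * fs))
    freqs, psd = sp_signal.welch(segment, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    mask = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    if mask.sum() >= 2:
        power = float(np.trapezoid(psd[mask], freqs[mask]))
    else:  # resolution coarser than the band: fall back to bin sum
        power = float(psd[mask].sum() * (freqs[1] - freqs[0]))
    return max(power, 0.0)


class PowerScaler:
    """Bring band powers 'to an order of magnitude 10'.

    A single power-of-ten factor is fitted so the maximum training-set
    power lands in [1, 10); the same factor is applied to test data, which
    may therefore exceed 10.  All-zero training input degenerates to the
    identity (with a warning).
    """

    def __init__(self) -> None:
        self.factor_: float | None = None

    def fit(self, values: np.ndarray) -> "PowerScaler":
        values = np.asarray(values, dtype=float)
        if np.any(values < 0):
            raise ValueError("band powers must be non-negative")
        vmax = float(values.max()) if values.size else 0.0
        if vmax <= 0:
            warnings.warn("all-zero powers; scaling factor set to 1", RuntimeWarning)
            self.factor_ = 1.0
        else:
            self.factor_ = 10.0 ** (-math.floor(math.log10(vmax)))
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.factor_ is None:
            raise RuntimeError("PowerScaler not fitted")
        return np.asarray(values, dtype=float) * self.factor_

    def fit_transform(self, values: np.ndarray) -> np.ndarray:
        return self.fit(values).transform(values)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation E[xy]/(sigma_x sigma_y) after per-window demeaning.

    A zero-variance input yields 0 with a warning rather than an error:
    degenerate flat windows must not abort a cross-validation fold.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("inputs must share a length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.mean(xc * xc))
    sy = np.sqrt(np.mean(yc * yc))
    if sx == 0 or sy == 0:
        warnings.warn("zero-variance window in Pearson correlation; returning 0", RuntimeWarning)
        return 0.0
    return float(np.clip(np.mean(xc * yc) / (sx * sy), -1.0, 1.0))


def _jaccard_denominator(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("inputs must share shape")
    dot = float(a @ b)
    denom = float(a @ a) + float(b @ b) - dot
    if denom == 0.0:
        raise ValueError("Jaccard measure undefined: both inputs are zero")
    return dot, denom


def jaccard_index(a: np.ndarray, b: np.ndarray) -> float:
    """Generalized Jaccard index J = A.B / (|A|^2 + |B|^2 - A.B), in [-1/3, 1]."""
    dot, denom = _jaccard_denominator(a, b)
    return dot / denom


def jaccard_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Generalized Jaccard distance JD = |A-B|^2 / (|A|^2 + |B|^2 - A.B) = 1 - J."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _, denom = _jaccard_denominator(a, b)
    diff = a - b
    return float(diff @ diff) / denom


@dataclass
class FeatureSequence:
    """Ordered per-window feature vectors for one trial."""

    values: np.ndarray  # (n_windows, n_features)
    feature_names: tuple[str, ...]
    interaction_mode: str
    label: str
    subject_id: str
    session_id: int
    trial_index: int
    window_s: float
    slide_s: float

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def flatten(self) -> np.ndarray:
        return self.values.reshape(-1)

    def with_values(self, values: np.ndarray) -> "FeatureSequence":
        return replace(self, values=values)


def extract_features(
    trial: Trial,
    window_spec: WindowSpec,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    interaction_mode: str = "none",
) -> FeatureSequence:
    """Per-window band powers, optionally followed by interaction features.

    Feature order per window: C3/Cz/C4 x band (alpha, beta), then - when an
    interaction mode is requested - one value per electrode pair (C3-Cz,
    C4-Cz, C3-C4).  Interactions are computed on the raw windowed samples
    of each electrode, not on band powers or envelopes.  Band powers are
    returned unscaled; scaling is a train-fold-fitted step (PowerScaler).
    """
    if interaction_mode not in INTERACTION_MODES:
        raise ValueError(f"interaction_mode must be one of {INTERACTION_MODES}, got {interaction_mode!r}")
    ranges = slide_windows(trial.signal.shape[1], window_spec, trial.fs)

    names = [f"{ch}_{band.name}" for ch in CHANNELS for band in bands]
    if interaction_mode != "none":
        names += [f"{CHANNELS[i]}_{CHANNELS[j]}_{interaction_mode}" for i, j in ELECTRODE_PAIRS]

    rows = np.empty((len(ranges), len(names)))
    for w, (lo, hi) in enumerate(ranges):
        win = trial.signal[:, lo:hi]
        col = 0
        for ci in range(len(CHANNELS)):
            for band in bands:
                rows[w, col] = band_power(win[ci], band, trial.fs)
                col += 1
        if interaction_mode == "correlation":
            for i, j in ELECTRODE_PAIRS:
                rows[w, col] = pearson(win[i], win[j])
                col += 1
        elif interaction_mode == "jaccard":
            for i, j in ELECTRODE_PAIRS:
                rows[w, col] = jaccard_distance(win[i], win[j])
                col += 1

    return FeatureSequence(
        values=rows,
        feature_names=tuple(names),
        interaction_mode=interaction_mode,
        label=trial.label,
        subject_id=trial.subject_id,
        session_id=trial.session_id,
        trial_index=trial.trial_index,
        window_s=window_spec.window_s,
        slide_s=window_spec.slide_s,
    )


def flatten_for_static(seq: FeatureSequence) -> np.ndarray:
    """Concatenate per-window vectors in window order (for the static LDA model)."""
    if seq.n_windows == 0:
        raise ValueError("empty feature sequence")
    return seq.flatten()


def features_to_frame(seqs: list[FeatureSequence]) -> pd.DataFrame:
    """One row per trial-window, metadata columns plus named features."""
    records = []
    for seq in seqs:
        for w in range(seq.n_windows):
            rec = {
                "subject": seq.subject_id,
                "session": seq.session_id,
                "trial": seq.trial_index,
                "label": seq.label,
                "window": w,
                "window_s": seq.window_s,
                "slide_s": seq.slide_s,
                "interaction_mode": seq.interaction_mode,
            }
            rec.update(dict(zip(seq.feature_names, seq.values[w])))
            records.append(rec)
    return pd.DataFrame.from_records(records)
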